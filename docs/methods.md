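# Methods

This note documents the models and procedures the package implements, the
assumptions behind them, and the choices made where the design was open.

## Study design being modelled

The package analyses a two-period resampling of an avian hybrid zone: two
parental species (internally "species 1", the black-capped-like northern
form, and "species 0", the Carolina-like southern form) meet along a SW–NE
interface; transects of sampling sites cross the interface; each site is
visited in two sampling periods decades apart. Biallelic SNPs from
reduced-representation (RAD-style) sequencing, per-sample coordinates, and
yearly climate rasters are the inputs. The questions are: how far has the
ancestry cline's centre moved between periods, which loci resist
introgression, are those loci clustered on particular chromosomes (notably
Z), and do regional differences in warming rates mirror differences in
zone movement.

## Genotypes and filtering

Genotypes are counted copies of the species-1-associated allele (0/1/2)
with a missing mask. Three filters reproduce standard RAD marker
selection:

- one variable site per RAD locus (lowest position; ties by input order —
  the choice rule is a convention, the source tools do not specify one);
- singleton removal, defined on allele copies: a locus whose minor allele
  occurs exactly once (i.e. one heterozygote) is dropped;
- a presence filter keeping loci called in ≥ 90% of individuals (the
  threshold used before genomic-cline fitting).

Missing calls are excluded from both numerator and denominator of all
allele counts. All filters only drop columns; they never alter calls, and
each is idempotent.

## Ancestry estimation

Two estimators, both reporting q = species-1 ancestry:

**ML hybrid index.** Given parental panel allele frequencies p0, p1
(pseudocount-smoothed, default 0.5, so boundary frequencies cannot send
the likelihood to −∞), each individual's genotypes are modelled as
g_l ~ Binomial(2, h·p1_l + (1−h)·p0_l), independent across loci
(free recombination between RAD markers; missing-at-random dropout).
The 1-D likelihood is maximised on a 10⁻³ grid and polished by bounded
scalar optimisation; 95% CIs are profile-likelihood intervals at a
log-likelihood drop of 1.92 (χ²₁). A flat likelihood (p0 = p1
everywhere) returns q = 0.5 with a full-width CI and a degeneracy flag.

**K = 2 admixture (EM).** When no reference panels exist, component
frequencies f0, f1 are estimated jointly with q by a generalised EM:
the q-step maximises each individual's likelihood exactly (vectorised
grid at 5·10⁻⁴ with parabolic refinement, keeping the better of old and
new values so the objective cannot decrease); the f-step is a standard
EM update from expected allele-origin counts with a Beta pseudocount
prior. The monotone objective is the penalised log-likelihood (MAP-EM)
and is asserted non-decreasing at every iteration. Label switching is
resolved by anchor panels when available, otherwise by the individual
with the highest PC1 score; five seeded restarts guard against local
optima.

PCA (column-mean-centred, mean-imputed, covariance eigendecomposition) is
kept strictly as verification of the ancestry gradient, mirroring the
common practice of cross-checking model-based assignments against a
model-free ordination.

**Diagnostic loci and heterozygosity.** Loci with a raw fixed difference
(|p1 − p0| = 1 on unsmoothed panel frequencies, ≥ 5 individuals per
panel) form the diagnostic panel; interspecific heterozygosity H is the
fraction of panel loci heterozygous per individual. Under neutral
admixture E[H | h] = 2h(1 − h): ~1 in F1s, ~0 in parentals — the
triangle-plot companion to q.

**Classification.** pure1 if q ≥ 0.99, pure0 if q ≤ 0.01, hybrid if
max(q, 1−q) ≤ 0.95 (boundary inclusive); individuals between the two
rules are "backcross-like". The two thresholds follow the assignment
conventions used for parental reference panels (≥ 99%) and hybrid calls
(≤ 95%).

## Transect projection and geographic clines

Coordinates are projected to a local equirectangular plane about a
baseline anchor (km east = Δlon·111.320·cos lat₀, km north =
Δlat·110.574); the transect coordinate x is the signed perpendicular
distance from the SW–NE baseline (bearing 45° by default), positive on
the NW side. Over a ≤ 100 km study extent the approximation agrees with
haversine distances to < 1%.

The geographic cline is the conventional sigmoid

    p(x) = pmin + (pmax − pmin) / (1 + exp(−4 (x − c) / w)),

with centre c and width w = inverse of maximum slope (the factor 4 makes
w the standard cline width). Ancestry values are fitted by bounded least
squares — appropriate because q is a bounded mean over thousands of loci
with near-Gaussian residuals — with a quantile-grid multi-start.
Uncertainty comes from a nonparametric bootstrap over individuals
(percentile CIs, default 1000 resamples; resamples are warm-started at
the point estimate, and degenerate resample fits are dropped). Movement
between periods is Δc = c₂ − c₁ along the perpendicular axis only
(movement is assumed strictly NW), its rate Δc/interval, and its CI
comes from independently resampling the two periods' bootstrap centre
distributions. Period contrasts of scalar summaries use Welch's t
(Satterthwaite df), Mann–Whitney U (exact for small tie-free samples,
tie-corrected normal approximation otherwise) or a pooled two-proportion
z-test. An inverse-distance-weighted ancestry surface (power 2,
exact-hit rule, clipped to [0, 1]) is provided for visual QC only.

## Bayesian genomic clines

Per-locus deviation from the genome-wide admixture gradient follows the
cline function

    Φ(h; α, β) = h + 2h(1−h)(α + β(2h−1)),  clamped to [0, 1],

the probability that an allele copy at the locus is of species-1 ancestry
in an individual with hybrid index h. α > 0 shifts ancestry toward
species 1; β > 0 steepens the locus cline (restricted introgression,
excess ancestry-based LD); β < 0 flattens it. Φ is anchored at
Φ(0) = 0, Φ(1) = 1 for all (α, β) — asserted on posterior draws.

The likelihood uses called genotypes: π = Φ·p1 + (1−Φ)·p0 and
g ~ Binomial(2, π) with smoothed parental frequencies (a per-genotype
error hook exists, default 0). Hybrid indices are plugged in from the
ancestry module rather than sampled jointly: with thousands of loci ĥ is
precise, and fixing it makes loci conditionally independent, so a
random-walk Metropolis chain on (α, β) runs for every locus in parallel
(vectorised). Priors are Normal(0, 1²) on both parameters — a fixed-sd
simplification of hierarchical cline priors, whose settings the original
analyses do not state. Proposal scales adapt toward a 0.2–0.5 acceptance
rate during burnin only, then freeze (preserving detailed balance in the
sampling phase). Chain defaults mirror the original analysis (50,000
post-burnin states thinned by 5 after 25,000 burnin); the pipeline
default is a 5,000 + 2,500 reduced chain, which the convergence check
(posterior-median agreement between an independent second chain, tol 0.1)
shows is sufficient at these data sizes. Identifiability note: β's
leverage on Φ is bounded by max|2h(1−h)(2h−1)| ≈ 0.096 per unit β, so β
posteriors are intrinsically ~2.5× wider than α's at equal sample size.

**Outlier rule.** For each parameter independently, a locus is an outlier
iff its 95% equal-tail posterior interval excludes 0 AND its posterior
median falls in the top (bottom) 1% of all loci's medians. Quantiles are
taken across all loci genome-wide (not within chromosomes). Categories
(+α, −α, +β, −β) combine freely; for chromosome-composition tests they
collapse to {+α only, −α only, +β only, −β only, multi, none}.

## Genome scans

Per-chromosome G-tests compare observed outlier-category counts with
expectations from genome-wide proportions: G = 2 Σ O ln(O/E) with
0·ln 0 ≡ 0, df = (categories with E > 0) − 1, χ² upper-tail p, no
small-count correction by default (a Williams-correction option is
exposed). Runs of consecutive positive-β outliers use adjacency in the
position-sorted marker list (not base-pair distance — appropriate for
sparse RAD markers), never span chromosome boundaries, and require ≥ 3
loci. The permutation null shuffles flags genome-wide while preserving
each chromosome's locus count;
p = (1 + #{permutations with max run ≥ cutoff}) / (1 + n_perm). Note this
p is the null probability of the run event itself, so it grows with the
number of flagged loci.

## Climate trends

Yearly rasters (ESRI ASCII grid interchange; nodata-aware) are averaged
over 5-year windows at each end of the study interval; the per-year rate
is (end-window mean − start-window mean) / interval, with the interval
counted between window end years (2016 − 1980 = 36). Regional summaries
average cells within 0.5° (Euclidean in degrees, matching the buffer's
definition) of the sampling sites, unweighted by latitude over the ≤ 1°
extents involved. The two-region contrast is 100·(mean_A − mean_B)/mean_B.

## Synthetic data generator

The generator inverts the inference chain's own generative model, so
parameter recovery is a well-posed test:

1. parental frequencies: divergent loci p1 ~ U(0.95, 1), p0 ~ U(0, 0.05)
   (yielding diagnostic loci), shared loci p0 = p1 ~ U(0.05, 0.95);
2. sites at exact transect distances (coordinates produced by inverting
   the projection); per period t, a true sigmoid cline p_t(x);
3. individual hybrid indices h ~ Beta(ν·p, ν·(1−p)) with concentration
   ν = 50 — chosen to give realistic between-individual scatter (sd
   ≈ 0.06 at p = 0.5) rather than deterministic site values;
4. per locus, each allele copy is species-1 with probability
   Φ(h; α*, β*), then drawn from that species' frequency — free
   recombination between loci, matching the cline likelihood;
5. per-call missingness (default 10%, RAD-like).

Default conditions mirror the study design: 30 sites spanning ±40 km,
2 individuals/site/period (~60 per period), two periods 36 years apart,
planted centre shift 5.66 km NW, width 10 km, 2000 loci (half divergent)
on six chromosomes including Z, 20 planted +β loci (β* = 1) containing a
4-locus consecutive run on Z. The climate generator plants linear trends
(west 0.02, east 0.03 °C/yr — a 50% contrast) plus i.i.d. spatial noise
on two disjoint rectangular regions, nodata elsewhere.

What the generator does *not* emulate — linkage within and between RAD
loci, genotyping error, spatially structured missingness, selection
through time, drift/demography — bounds what passing tests show: they
demonstrate correct inference under the model's own assumptions, not
robustness to their violation on real data.

## Problem sizes and numerical choices

The shipped test and acceptance configurations use scaled-down designs
chosen to keep full runs on a single CPU short while preserving the
study's structure: cline-shift recovery uses 1000 fully divergent loci
and ~60 individuals/period over 8–20 seeded replicates with 400
bootstrap resamples; genomic-cline calibration uses 2000 loci, ~150
admixed individuals and the reduced 5,000 + 2,500 chain; permutation
tests use 10,000 shuffles. Optimisers use box constraints with seeded
multi-starts; the EM stops at a penalised log-likelihood gain < 10⁻⁶;
bootstrap resamples with degenerate fits (constant q or < 4 distinct x)
are dropped and counted. All randomness flows from explicit seeds; equal
config + seed reproduces byte-identical outputs.

## Known limitations

- Fixing ĥ in the genomic-cline likelihood ignores hybrid-index
  uncertainty; at hundreds of informative loci this is negligible, at few
  loci it would understate posterior widths.
- Called genotypes replace read-based genotype uncertainty; low-coverage
  data would need the error-rate hook or external genotype likelihoods.
- The equirectangular projection and degree-based buffers are only
  appropriate for study extents of a few hundred km at mid-latitudes.
- β outliers are intrinsically harder to detect than α outliers (see
  identifiability note); power statements are specific to the simulated
  frequency divergence and h distribution.
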