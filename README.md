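# hybridzone

Tools for temporal hybrid-zone analysis with biallelic SNPs: did the
contact zone between two hybridising species move between sampling
periods, which loci resist introgression, and do regional climate trends
track the movement?

The package was built around the design of two-period resamplings of the
black-capped × Carolina chickadee (*Poecile atricapillus* × *P.
carolinensis*) contact zone — decades-apart cohorts sampled along a
transect crossing a SW–NE interface — but every component is generic to
two-taxon hybrid zones genotyped at biallelic markers.

## What it computes

- **Ancestry** — per-individual admixture proportion q by a
  maximum-likelihood hybrid index (given parental reference panels,
  g ~ Binomial(2, q·p1 + (1−q)·p0)) or a K=2 EM admixture estimator
  (panels unknown), verified by PCA; diagnostic fixed-difference panels
  and interspecific heterozygosity H for triangle plots; pure/hybrid
  classification at the ≥99% / ≤95% assignment thresholds.
- **Geographic clines** — samples projected to a signed perpendicular
  distance x from the interface baseline; sigmoid cline
  p(x) = pmin + (pmax−pmin)/(1+exp(−4(x−c)/w)) fitted per period by
  bounded least squares with bootstrap CIs; movement Δc = c₂ − c₁ (km,
  positive NW) and its per-year rate; Welch/Mann–Whitney/two-proportion
  period comparisons; IDW ancestry surfaces for QC.
- **Genomic clines** — per-locus Bayesian (α, β) clines,
  Φ(h) = h + 2h(1−h)(α + β(2h−1)), fitted by vectorised random-walk
  Metropolis with called-genotype likelihoods; outliers flagged where the
  95% posterior interval excludes 0 *and* the median is in the top/bottom
  1% of loci; +β loci are candidate barriers to introgression.
- **Genome scans** — per-chromosome G-tests of outlier composition;
  runs of ≥3 consecutive +β loci (inversion-like signals, e.g. on Z) with
  a permutation null.
- **Climate trends** — 5-year window means of yearly rasters, per-year
  rates of change, 0.5° site buffers, and two-region percent contrasts.
- **Synthetic data** — a generator that inverts the full model (true
  clines, Beta-distributed hybrid indices, per-locus (α*, β*) effects,
  RAD-style missingness, planted outlier runs, trending climate rasters)
  so every stage has a parameter-recovery test.

## Worked example

Recover a planted 5.66 km cline-centre shift from simulated two-period
genotypes (`examples/03_cline_movement.py`):

```python
from hybridzone import ancestry, synthetic_data as synth
from hybridzone import geographic_cline as geo

cfg = synth.cline_shift_config(seed=3, delta_c_km=5.66)
ds = synth.simulate_hybrid_zone(cfg)
freqs = ancestry.parental_allele_frequencies(
    ds.genotypes, ds.samples.panel_ids("ref0"), ds.samples.panel_ids("ref1"))
est = ancestry.hybrid_index_ml(ds.genotypes, freqs)
meta = ds.samples.aligned_to(list(est["individual"]))
est = est.assign(x_km=geo.project_to_transect(meta, cfg.baseline),
                 period=meta["period"])
```

Fitting both periods and differencing the centres prints:

```
historical: centre  -0.22 km [-0.90, 0.39], width 9.7 km
modern:     centre   5.57 km [4.85, 5.99], width 10.5 km
estimated shift: 5.79 km NW over 36 yr (truth 5.66), 95% CI [4.88, 6.62]
rate: 0.161 km/yr
```

The two centres are the inflection points of the per-period ancestry
clines; their difference estimates how far the zone moved toward the
north-west, and the bootstrap CI covers the planted truth. The other
`examples/` scripts walk through ancestry estimation, genomic-cline
outlier scans (`04` recovers 19/20 planted +β loci and the 4-locus Z run
at permutation p ≈ 0.002), and the regional climate contrast (planted
50%, recovered 50.6%).

A full pipeline (simulate → filter → ancestry → clines → scans → climate
→ report) runs behind one seeded command:

```bash
hybridzone all --seed 1 --outdir run1
```

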