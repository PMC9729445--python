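"""Per-locus Bayesian genomic clines (alpha, beta) with outlier calls.

The genomic cline maps an individual's genome-wide hybrid index h (species-1
ancestry proportion) to the probability that a given allele copy at locus l
is of species-1 ancestry:

    Phi(h; alpha, beta) = h + 2 h (1 - h) (alpha + beta (2h - 1)),  clamped to [0, 1]

alpha shifts locus ancestry toward species 1 (alpha > 0) or species 0;
beta steepens (beta > 0, restricted introgression / excess ancestry-based
linkage disequilibrium) or flattens (beta < 0) the locus-specific cline.
Phi is anchored at Phi(0) = 0 and Phi(1) = 1 for any (alpha, beta).

With parental allele frequencies p0, p1 the counted-allele probability is
pi = Phi p1 + (1 - Phi) p0 and called genotypes are Binomial(2, pi).
Hybrid indices are treated as fixed (plugged in from the ancestry module),
which renders loci conditionally independent, so a random-walk Metropolis
chain is run for every locus in parallel (vectorised across loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hybridzone.genotype_io import MISSING, GenotypeMatrix


@dataclass
class GenomicClineFit:
    """Posterior summaries and thinned samples per locus."""

    summary: pd.DataFrame  # locus, chrom, pos, alpha_med/lo/hi, beta_med/lo/hi, accept_rate
    alpha_samples: np.ndarray  # (n_samples, n_loci)
    beta_samples: np.ndarray
    iterations: int
    burnin: int
    thin: int
    seed: int | None


def phi(h, alpha, beta):
    """Genomic cline function, clamped to [0, 1].

    Accepts scalars or broadcastable arrays; errors if h is outside [0, 1].
    """
    h = np.asarray(h, float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hybrid index h must lie in [0, 1]")
    val = h + 2.0 * h * (1.0 - h) * (alpha + beta * (2.0 * h - 1.0))
    return np.clip(val, 0.0, 1.0)


def locus_log_likelihood(genotypes, h, alpha, beta, p0, p1) -> float:
    """Log-likelihood of one locus's called genotypes given (alpha, beta).

    ``genotypes``: array over individuals in {0,1,2}, MISSING (-1) ignored.
    ``p0``, ``p1`` must be smoothed strictly inside (0, 1).  Includes the
    binomial coefficient (log 2 for heterozygotes).
    """
    g = np.asarray(genotypes)
    h = np.asarray(h, float)
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError("p0 and p1 must be strictly inside (0, 1) (smoothed)")
    obs = g != MISSING
    if not obs.any():
        return 0.0
    g = g[obs].astype(float)
    ph = phi(h[obs], alpha, beta)
    pi = ph * p1 + (1.0 - ph) * p0
    ll = g * np.log(pi) + (2.0 - g) * np.log1p(-pi) + np.where(g == 1, np.log(2.0), 0.0)
    return float(ll.sum())


def _loglik_matrix(G, obs, h, alpha, beta, p0, p1):
    """Vectorised log-likelihood for all loci at once.

    G: (n_ind, n_loci) float genotypes with 0 where missing; obs: bool mask;
    alpha, beta, p0, p1: (n_loci,).  Returns (n_loci,) log-likelihoods
    (binomial coefficients omitted — constant in (alpha, beta)).
    """
    hh = h[:, None]
    val = hh + 2.0 * hh * (1.0 - hh) * (alpha[None, :] + beta[None, :] * (2.0 * hh - 1.0))
    np.clip(val, 0.0, 1.0, out=val)
    pi = val * p1[None, :] + (1.0 - val) * p0[None, :]
    ll = G * np.log(pi) + (2.0 - G) * np.log1p(-pi)
    ll[~obs] = 0.0
    return ll.sum(axis=0)


def fit_genomic_clines_mcmc(
    gm: GenotypeMatrix,
    h,
    p0,
    p1,
    iterations: int = 50000,
    burnin: int = 25000,
    thin: int = 5,
    proposal_sd: float = 0.2,
    prior_sd: float = 1.0,
    seed: int | None = None,
    ci: float = 0.95,
) -> GenomicClineFit:
    """Random-walk Metropolis over (alpha, beta) for every locus.

    Independent Normal(0, prior_sd^2) priors on alpha and beta.  Proposals
    are joint Gaussian steps; the per-locus proposal scale is adapted
    during burnin toward a 0.2-0.5 acceptance rate and then frozen.
    ``iterations`` counts post-burnin states; every ``thin``-th is stored.
    Deterministic given ``seed``.
    """
    h = np.asarray(h, float)
    n_adm = int(np.sum((h > 0.01) & (h < 0.99)))
    if n_adm == 0:
        raise ValueError("no admixed individuals (0.01 < h < 0.99); clines unidentifiable")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    if np.any((p0 <= 0) | (p0 >= 1)) or np.any((p1 <= 0) | (p1 >= 1)):
        raise ValueError("parental frequencies must be smoothed strictly inside (0,1)")
    L = gm.n_loci
    obs = ~gm.missing_mask
    G = gm.values.astype(float)
    G[~obs] = 0.0

    rng = np.random.default_rng(seed)
    alpha = np.zeros(L)
    beta = np.zeros(L)
    scale = np.full(L, proposal_sd)
    cur_ll = _loglik_matrix(G, obs, h, alpha, beta, p0, p1)
    cur_lp = cur_ll - (alpha**2 + beta**2) / (2.0 * prior_sd**2)

    n_keep = iterations // thin
    a_samp = np.empty((n_keep, L))
    b_samp = np.empty((n_keep, L))
    accept_post = np.zeros(L)
    k = 0
    adapt_block = 250
    block_acc = np.zeros(L)
    total = burnin + iterations
    for it in range(total):
        prop_a = alpha + rng.normal(0.0, scale, L)
        prop_b = beta + rng.normal(0.0, scale, L)
        ll = _loglik_matrix(G, obs, h, prop_a, prop_b, p0, p1)
        lp = ll - (prop_a**2 + prop_b**2) / (2.0 * prior_sd**2)
        acc = np.log(rng.random(L)) < (lp - cur_lp)
        alpha[acc] = prop_a[acc]
        beta[acc] = prop_b[acc]
        cur_lp[acc] = lp[acc]
        if it < burnin:
            block_acc += acc
            if (it + 1) % adapt_block == 0:
                rate = block_acc / adapt_block
                scale *= np.where(rate < 0.2, 0.7, np.where(rate > 0.5, 1.4, 1.0))
                block_acc[:] = 0.0
        else:
            accept_post += acc
            if (it - burnin) % thin == 0:
                a_samp[k] = alpha
                b_samp[k] = beta
                k += 1
    a_samp = a_samp[:k]
    b_samp = b_samp[:k]

    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    summary = pd.DataFrame(
        {
            "locus": np.arange(L),
            "chrom": gm.locus_meta["chrom"].to_numpy(),
            "pos": gm.locus_meta["pos"].to_numpy(),
            "alpha_med": np.median(a_samp, axis=0),
            "alpha_lo": np.quantile(a_samp, lo_q, axis=0),
            "alpha_hi": np.quantile(a_samp, hi_q, axis=0),
            "beta_med": np.median(b_samp, axis=0),
            "beta_lo": np.quantile(b_samp, lo_q, axis=0),
            "beta_hi": np.quantile(b_samp, hi_q, axis=0),
            "accept_rate": accept_post / iterations,
        }
    )
    return GenomicClineFit(summary, a_samp, b_samp, iterations, burnin, thin, seed)


def check_convergence(
    fit_long: GenomicClineFit,
    fit_short: GenomicClineFit,
    tol_median: float = 0.1,
    min_samples: int = 50,
) -> pd.DataFrame:
    """Compare posterior medians of two independently run chains per locus.

    Returns a frame with per-locus |delta median| for alpha and beta and a
    ``pass`` flag; chains with fewer than ``min_samples`` stored states are
    flagged unreliable wholesale.
    """
    s1, s2 = fit_long.summary, fit_short.summary
    if len(s1) != len(s2) or not np.array_equal(s1["locus"], s2["locus"]):
        raise ValueError("convergence check requires fits over identical loci")
    d_alpha = np.abs(s1["alpha_med"].to_numpy() - s2["alpha_med"].to_numpy())
    d_beta = np.abs(s1["beta_med"].to_numpy() - s2["beta_med"].to_numpy())
    unreliable = (
        fit_long.alpha_samples.shape[0] < min_samples
        or fit_short.alpha_samples.shape[0] < min_samples
    )
    ok = (d_alpha <= tol_median) & (d_beta <= tol_median) & (not unreliable)
    return pd.DataFrame(
        {
            "locus": s1["locus"],
            "delta_alpha_med": d_alpha,
            "delta_beta_med": d_beta,
            "pass": ok,
            "unreliable": unreliable,
        }
    )


def classify_outliers(fit: GenomicClineFit, ci: float = 0.95, tail: float = 0.01) -> pd.DataFrame:
    """Flag outlier loci by the joint credible-interval + 1%-tail rule.

    A locus is a positive (negative) outlier for a parameter iff its
    ``ci`` equal-tail posterior interval excludes 0 AND its posterior median
    lies in the top (bottom) ``tail`` fraction of all loci's medians for
    that parameter.  Categories combine freely (+alpha and +beta may both
    fire).  Returns the summary frame augmented with flag columns and an
    ``outlier`` boolean.
    """
    if not 0 < tail < 0.5:
        raise ValueError(f"tail must be in (0, 0.5), got {tail}")
    s = fit.summary.copy()
    if len(s) < 100:
        raise ValueError("need >= 100 loci for meaningful tail quantiles")
    for par in ("alpha", "beta"):
        med = s[f"{par}_med"].to_numpy()
        lo = s[f"{par}_lo"].to_numpy()
        hi = s[f"{par}_hi"].to_numpy()
        excl0 = (lo > 0) | (hi < 0)
        upper = np.quantile(med, 1 - tail)
        lower = np.quantile(med, tail)
        s[f"pos_{par}"] = excl0 & (med >= upper) & (med > 0)
        s[f"neg_{par}"] = excl0 & (med <= lower) & (med < 0)
    s["outlier"] = s[["pos_alpha", "neg_alpha", "pos_beta", "neg_beta"]].any(axis=1)
    return s


def outlier_category_labels(outliers: pd.DataFrame) -> pd.Series:
    """Collapse flag columns into the G-test category labels.

    Categories: '+a', '-a', '+b', '-b' for single-flag loci, 'multi' for
    combinations, 'none' for non-outliers.
    """
    flags = outliers[["pos_alpha", "neg_alpha", "pos_beta", "neg_beta"]].to_numpy(bool)
    names = np.array(["+a", "-a", "+b", "-b"])
    counts = flags.sum(axis=1)
    labels = np.where(counts == 0, "none", "multi")
    single = counts == 1
    labels = labels.astype(object)
    labels[single] = names[flags[single].argmax(axis=1)]
    return pd.Series(labels, index=outliers.index, name="category")
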