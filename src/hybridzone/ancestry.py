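"""Admixture-proportion estimation, PCA verification and hybrid diagnostics.

Two ancestry estimators are provided, both oriented so that q is the
species-1 (black-capped-like) ancestry proportion:

- :func:`hybrid_index_ml` — maximum-likelihood hybrid index given parental
  allele frequencies: maximise over h in [0,1] the sum over loci of
  log Binomial(g | 2, h p1 + (1-h) p0), with profile-likelihood CIs.
- :func:`admixture_em` — K=2 admixture estimation with unknown component
  frequencies, alternating exact per-individual optimisation of q with
  EM re-estimation of the component frequencies (a generalised EM whose
  log-likelihood never decreases).

PCA (:func:`genotype_pca`) serves as an independent verification of the
ancestry gradient.  Diagnostic panels of fixed-difference SNPs support
interspecific heterozygosity, the classic triangle-plot companion to q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from hybridzone.genotype_io import MISSING, GenotypeMatrix

_CHI2_95_HALF = 1.92  # chi^2_1 95% cutoff / 2, profile-likelihood drop


@dataclass
class ParentalFreqs:
    """Per-locus parental panel frequencies of the counted allele.

    ``p0``/``p1`` are pseudocount-smoothed; ``raw0``/``raw1`` unsmoothed;
    ``n0``/``n1`` are non-missing allele-copy counts per panel.  Loci with
    zero non-missing calls in a panel carry NaN raw frequency and are
    flagged in ``defined``.
    """

    p0: np.ndarray
    p1: np.ndarray
    raw0: np.ndarray
    raw1: np.ndarray
    n0: np.ndarray
    n1: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return (self.n0 > 0) & (self.n1 > 0)


def parental_allele_frequencies(
    gm: GenotypeMatrix,
    panel0: list[str],
    panel1: list[str],
    pseudocount: float = 0.5,
) -> ParentalFreqs:
    """Smoothed allele frequencies in the two parental reference panels.

    smoothed p = (allele count + pseudocount) / (copies + 2 * pseudocount).
    """
    if not panel0 or not panel1:
        raise ValueError("parental panels must be non-empty")
    if set(panel0) & set(panel1):
        raise ValueError("parental panels must be disjoint")
    idx = {ind: i for i, ind in enumerate(gm.individuals)}
    missing = [p for p in list(panel0) + list(panel1) if p not in idx]
    if missing:
        raise ValueError(f"panel individuals absent from genotypes: {missing}")

    def freqs(panel):
        sub = gm.values[[idx[p] for p in panel], :]
        obs = sub != MISSING
        alt = np.where(obs, sub, 0).sum(axis=0).astype(float)
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(n > 0, alt / n, np.nan)
        smooth = (alt + pseudocount) / (n + 2.0 * pseudocount)
        return smooth, raw, n

    p0, raw0, n0 = freqs(panel0)
    p1, raw1, n1 = freqs(panel1)
    return ParentalFreqs(p0, p1, raw0, raw1, n0, n1)


# ---------------------------------------------------------------------------
# ML hybrid index


def _individual_loglik(g, obs, p0, p1, h):
    """Log-likelihood of one individual's genotypes at hybrid index h."""
    pi = h * p1 + (1.0 - h) * p0
    ll = g * np.log(pi) + (2.0 - g) * np.log1p(-pi)
    return float(ll[obs].sum())


def hybrid_index_ml(
    gm: GenotypeMatrix,
    freqs: ParentalFreqs,
    grid_step: float = 1e-3,
) -> pd.DataFrame:
    """Per-individual ML hybrid index with 95% profile-likelihood CIs.

    Likelihood: g_l ~ Binomial(2, h p1_l + (1-h) p0_l) over non-missing
    loci with defined parental frequencies.  The optimum is located on a
    fine grid and polished by bounded scalar optimisation (the likelihood
    is unimodal in practice; the grid guards against flat stretches).

    Returns a frame with columns individual, q, lo, hi, method, degenerate,
    n_loci.  Individuals with no usable loci get NaN and degenerate=True.
    """
    use = freqs.defined
    p0 = freqs.p0[use]
    p1 = freqs.p1[use]
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # (n_grid, n_loci) log terms computed once
    pi_grid = grid[:, None] * p1 + (1.0 - grid[:, None]) * p0
    log_pi = np.log(pi_grid)
    log_1mpi = np.log1p(-pi_grid)
    rows = []
    for i, ind in enumerate(gm.individuals):
        g_all = gm.values[i, use]
        obs = g_all != MISSING
        n_loci = int(obs.sum())
        if n_loci == 0:
            rows.append((ind, np.nan, np.nan, np.nan, "hybrid_index_ml", True, 0))
            continue
        g = g_all[obs].astype(float)
        ll_grid = log_pi[:, obs] @ g + log_1mpi[:, obs] @ (2.0 - g)
        k = int(np.argmax(ll_grid))
        if np.ptp(ll_grid) < 1e-9:  # flat likelihood (p0 == p1 everywhere)
            rows.append((ind, 0.5, 0.0, 1.0, "hybrid_index_ml", True, n_loci))
            continue
        lo_b = grid[max(k - 1, 0)]
        hi_b = grid[min(k + 1, grid.size - 1)]
        p0o, p1o = p0[obs], p1[obs]

        def nll(h):
            return -_individual_loglik(g, slice(None), p0o, p1o, h)

        res = optimize.minimize_scalar(nll, bounds=(lo_b, hi_b), method="bounded",
                                       options={"xatol": 1e-7})
        q_hat = float(res.x) if -res.fun >= ll_grid[k] else float(grid[k])
        ll_max = max(-res.fun, float(ll_grid[k]))
        cut = ll_max - _CHI2_95_HALF

        def drop(h):
            return -nll(h) - cut

        lo = 0.0
        if drop(0.0) < 0:
            lo = float(optimize.brentq(drop, 0.0, q_hat, xtol=1e-7)) if q_hat > 0 else 0.0
        hi = 1.0
        if drop(1.0) < 0:
            hi = float(optimize.brentq(drop, q_hat, 1.0, xtol=1e-7)) if q_hat < 1 else 1.0
        rows.append((ind, q_hat, lo, hi, "hybrid_index_ml", False, n_loci))
    return pd.DataFrame(
        rows, columns=["individual", "q", "lo", "hi", "method", "degenerate", "n_loci"]
    )


# ---------------------------------------------------------------------------
# K=2 admixture (EM)


def _q_step(G, obs, f0, f1, q, grid):
    """Vectorised per-individual maximisation of q on a grid + refinement.

    Never decreases any individual's log-likelihood (the better of old and
    new q is kept).
    """
    Gf = np.where(obs, G, 0.0).astype(float)
    G2 = np.where(obs, 2.0 - G, 0.0)
    pi = grid[:, None] * f1 + (1.0 - grid[:, None]) * f0  # (n_grid, L)
    log_pi = np.log(pi)
    log_1mpi = np.log1p(-pi)
    ll = Gf @ log_pi.T + G2 @ log_1mpi.T  # (N, n_grid)
    k = ll.argmax(axis=1)
    # parabolic refinement on the three surrounding grid points
    km = np.clip(k - 1, 0, grid.size - 1)
    kp = np.clip(k + 1, 0, grid.size - 1)
    y0 = ll[np.arange(len(k)), km]
    y1 = ll[np.arange(len(k)), k]
    y2 = ll[np.arange(len(k)), kp]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    step = grid[1] - grid[0]
    q_new = np.clip(grid[k] + np.clip(shift, -1, 1) * step, 0.0, 1.0)

    def ll_of(qv):
        piq = qv[:, None] * f1 + (1.0 - qv[:, None]) * f0
        return (Gf * np.log(piq) + G2 * np.log1p(-piq)).sum(axis=1)

    ll_new = ll_of(q_new)
    ll_old = ll_of(q)
    better = ll_new >= ll_old
    return np.where(better, q_new, q), np.where(better, ll_new, ll_old)


def admixture_em(
    gm: GenotypeMatrix,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    anchors: tuple[list[str], list[str]] | None = None,
    n_starts: int = 5,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K=2 maximum-likelihood admixture via generalised EM.

    Alternates (i) exact per-individual optimisation of q under
    g ~ Binomial(2, q f1 + (1-q) f0) and (ii) EM re-estimation of the
    component frequencies f0, f1 from expected allele-origin counts.  The
    observed-data log-likelihood is asserted non-decreasing every
    iteration.  ``n_starts`` seeded restarts; the best final likelihood is
    kept.  Label orientation is fixed so the anchor panel-1 individuals (or
    the individual with the highest PC1 score when no anchors are given)
    average q > 0.5.

    Returns (estimates frame, component frequency frame).  The estimates
    frame carries a ``converged`` flag (False when max_iter was hit).
    """
    N, L = gm.n_individuals, gm.n_loci
    if N < 2 or L < 2:
        raise ValueError("need >= 2 individuals and >= 2 loci")
    obs = ~gm.missing_mask
    G = gm.values.astype(float)
    G[~obs] = 0.0
    Gf = np.where(obs, G, 0.0)
    G2 = np.where(obs, 2.0 - G, 0.0)
    grid = np.linspace(0.0, 1.0, 2001)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_starts):
        q = rng.uniform(0.05, 0.95, N)
        f0 = np.clip(rng.uniform(0.1, 0.9, L), 1e-3, 1 - 1e-3)
        f1 = np.clip(f0 + rng.normal(0, 0.3, L), 1e-3, 1 - 1e-3)
        prev_obj = -np.inf
        converged = False
        for _it in range(max_iter):
            q, ll_i = _q_step(G, obs, f0, f1, q, grid)
            # Beta(1+pc, 1+pc) log-prior on the frequencies: the M-step below
            # maximises this penalised objective, making MAP-EM monotone
            pen = pseudocount * float(
                (np.log(f0) + np.log1p(-f0) + np.log(f1) + np.log1p(-f1)).sum()
            )
            # EM update of f0, f1 from expected origin-specific allele counts
            qc = q[:, None]
            denom1 = qc * f1 + (1 - qc) * f0
            denom0_allele0 = qc * (1 - f1) + (1 - qc) * (1 - f0)
            w1_alt = qc * f1 / denom1          # P(origin 1 | allele = counted)
            w1_ref = qc * (1 - f1) / denom0_allele0
            e1_alt = (Gf * w1_alt).sum(axis=0)
            e1_ref = (G2 * w1_ref).sum(axis=0)
            e0_alt = (Gf * (1 - w1_alt)).sum(axis=0)
            e0_ref = (G2 * (1 - w1_ref)).sum(axis=0)
            f1 = (e1_alt + pseudocount) / (e1_alt + e1_ref + 2 * pseudocount)
            f0 = (e0_alt + pseudocount) / (e0_alt + e0_ref + 2 * pseudocount)
            f1 = np.clip(f1, 1e-6, 1 - 1e-6)
            f0 = np.clip(f0, 1e-6, 1 - 1e-6)
            ll = float(ll_i.sum())
            obj = ll + pen
            if obj < prev_obj - 1e-8 * (1.0 + abs(prev_obj)):
                raise AssertionError(
                    f"EM objective decreased: {prev_obj} -> {obj}"
                )
            if obj - prev_obj < tol:
                converged = True
                break
            prev_obj = obj
        if best is None or ll > best[0]:
            best = (ll, q.copy(), f0.copy(), f1.copy(), converged)

    ll, q, f0, f1, converged = best

    # orientation: species 1 = anchors' panel1, else highest-PC1 individual
    flip = False
    if anchors is not None:
        _, panel1 = anchors
        idx = {ind: i for i, ind in enumerate(gm.individuals)}
        sel = [idx[p] for p in panel1 if p in idx]
        if not sel:
            raise ValueError("anchor panel1 has no individuals in the genotype matrix")
        flip = q[sel].mean() < 0.5
    else:
        scores = genotype_pca(gm, n_components=1, orient_with=None)
        top = int(np.argmax(scores[:, 0]))
        flip = q[top] < 0.5
    if flip:
        q = 1.0 - q
        f0, f1 = f1, f0

    est = pd.DataFrame(
        {
            "individual": gm.individuals,
            "q": q,
            "lo": np.nan,
            "hi": np.nan,
            "method": "admixture_em",
            "converged": converged,
        }
    )
    comp = pd.DataFrame({"locus": np.arange(L), "f0": f0, "f1": f1})
    return est, comp


# ---------------------------------------------------------------------------
# PCA verification


def genotype_pca(
    gm: GenotypeMatrix,
    n_components: int = 2,
    scale: bool = False,
    orient_with: np.ndarray | None = None,
) -> np.ndarray:
    """Principal-component scores of the genotype matrix.

    Columns are mean-centred; missing calls imputed with the column mean;
    optional 1/sqrt(p(1-p)) scaling.  Scores come from eigendecomposition
    of the individual covariance.  When ``orient_with`` (e.g. q estimates)
    is given, PC1's sign is chosen so it correlates positively with it.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals for PCA")
    X = gm.values.astype(float)
    miss = gm.missing_mask
    with np.errstate(invalid="ignore"):
        col_mean = np.where(miss, np.nan, X).astype(float)
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(miss, col_mean[None, :], X)
    X = X - col_mean[None, :]
    if scale:
        p = col_mean / 2.0
        denom = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        X = X / denom[None, :]
    if np.allclose(X, 0):
        raise ValueError("zero-variance genotype matrix")
    cov = X @ X.T / max(gm.n_loci - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_components]
    scores = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))[None, :]
    if orient_with is not None:
        r = np.corrcoef(scores[:, 0], np.asarray(orient_with, float))[0, 1]
        if np.isfinite(r) and r < 0:
            scores[:, 0] = -scores[:, 0]
    return scores


# ---------------------------------------------------------------------------
# Diagnostic panel & heterozygosity


def diagnostic_panel(
    gm: GenotypeMatrix,
    panel0: list[str],
    panel1: list[str],
    min_n: int = 5,
) -> pd.DataFrame:
    """Loci fixed for alternative alleles between the parental panels.

    Requires raw (unsmoothed) frequency difference |p1 - p0| = 1 with at
    least ``min_n`` non-missing individuals per panel.  Records per-locus
    orientation: +1 when the counted allele is the species-1 allele.
    Returns an empty frame (with a warning log) when nothing qualifies.
    """
    import logging

    freqs = parental_allele_frequencies(gm, panel0, panel1, pseudocount=0.0)
    enough = (freqs.n0 >= 2 * min_n) & (freqs.n1 >= 2 * min_n)
    with np.errstate(invalid="ignore"):
        fixed = enough & (np.abs(freqs.raw1 - freqs.raw0) == 1.0)
    idx = np.flatnonzero(fixed)
    orientation = np.where(freqs.raw1[idx] == 1.0, 1, -1)
    if idx.size == 0:
        logging.getLogger(__name__).warning("diagnostic_panel: no fixed-difference loci")
    return pd.DataFrame(
        {
            "locus": idx,
            "chrom": gm.locus_meta["chrom"].to_numpy()[idx],
            "pos": gm.locus_meta["pos"].to_numpy()[idx],
            "orientation": orientation,
        }
    )


def interspecific_heterozygosity(gm: GenotypeMatrix, panel: pd.DataFrame) -> pd.Series:
    """Fraction of diagnostic loci heterozygous per individual.

    H = (# panel loci with genotype 1) / (# non-missing panel loci); NaN
    for individuals missing every panel locus.
    """
    if len(panel) == 0:
        raise ValueError("diagnostic panel is empty")
    cols = panel["locus"].to_numpy()
    sub = gm.values[:, cols]
    obs = sub != MISSING
    het = (sub == 1) & obs
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        H = np.where(n_obs > 0, het.sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    return pd.Series(H, index=gm.individuals, name="H")


def classify_individuals(
    estimates: pd.DataFrame,
    pure_threshold: float = 0.99,
    hybrid_threshold: float = 0.95,
) -> pd.DataFrame:
    """Label individuals pure0 / pure1 / hybrid / backcross-like from q.

    pure1 if q >= pure_threshold; pure0 if q <= 1 - pure_threshold;
    hybrid if max(q, 1-q) <= hybrid_threshold (boundary inclusive);
    otherwise backcross-like (intermediate assignment, neither rule).
    """
    for name, t in (("pure_threshold", pure_threshold), ("hybrid_threshold", hybrid_threshold)):
        if not 0.5 < t <= 1.0:
            raise ValueError(f"{name} must be in (0.5, 1], got {t}")
    if hybrid_threshold > pure_threshold:
        raise ValueError("hybrid_threshold must not exceed pure_threshold")
    q = estimates["q"].to_numpy(float)
    label = np.full(len(q), "backcross-like", dtype=object)
    label[np.maximum(q, 1 - q) <= hybrid_threshold] = "hybrid"
    label[q >= pure_threshold] = "pure1"
    label[q <= 1 - pure_threshold] = "pure0"
    label[np.isnan(q)] = "undefined"
    out = estimates.copy()
    out["class"] = label
    return out
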