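"""Chromosome-level outlier composition and consecutive-outlier runs.

Two scans follow the genomic cline analysis:

- G-tests of whether each chromosome's outlier-category composition departs
  from the genome-wide composition (G = 2 sum O ln(O/E), df = k - 1, chi^2
  upper tail), with chromosomes ordered by G;
- detection of runs of >= 3 consecutive positive-beta outlier loci
  ("consecutive" = adjacent in the position-sorted marker list on one
  chromosome), with a permutation null that shuffles flags genome-wide
  while preserving each chromosome's locus count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def chromosome_composition_test(
    categories: pd.Series,
    chrom: pd.Series | np.ndarray,
    williams_correction: bool = False,
) -> pd.DataFrame:
    """Per-chromosome G-test against the genome-wide category composition.

    ``categories`` holds one label per locus (e.g. '+b', 'none', 'multi');
    ``chrom`` the chromosome per locus.  Expected counts are genome-wide
    category proportions times the chromosome's locus count; zero observed
    cells contribute 0 (0 ln 0 = 0).  df = (# categories with E > 0) - 1.
    Results are sorted by G descending.
    """
    cats = pd.Series(np.asarray(categories, dtype=object))
    chrom = pd.Series(np.asarray(chrom, dtype=object))
    if chrom.nunique() < 2:
        raise ValueError("need >= 2 chromosomes for composition tests")
    levels = sorted(cats.unique())
    total = len(cats)
    genome_prop = cats.value_counts(normalize=True).reindex(levels).fillna(0.0)
    rows = []
    for c, idx in cats.groupby(chrom).groups.items():
        n = len(idx)
        if n == 0:
            logger.warning("chromosome %s has 0 loci; skipped", c)
            continue
        obs = cats.loc[idx].value_counts().reindex(levels).fillna(0.0).to_numpy()
        exp = genome_prop.to_numpy() * n
        use = exp > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs[use] > 0, obs[use] * np.log(obs[use] / exp[use]), 0.0)
        g = 2.0 * terms.sum()
        df = int(use.sum()) - 1
        if williams_correction and df > 0:
            qcorr = 1.0 + (len(levels) ** 2 - 1) / (6.0 * n * df)
            g = g / qcorr
        p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
        rows.append((c, n, g, df, p))
    out = pd.DataFrame(rows, columns=["chrom", "n_loci", "G", "df", "p"])
    out["significant"] = out["p"] < 0.05
    return out.sort_values("G", ascending=False).reset_index(drop=True)


@dataclass
class OutlierRun:
    chrom: str
    start_locus: int  # index into the position-sorted locus table
    end_locus: int  # inclusive
    start_pos: int
    end_pos: int
    length: int


def _sorted_order(meta: pd.DataFrame) -> np.ndarray:
    return np.lexsort((meta["pos"].to_numpy(), meta["chrom"].astype(str).to_numpy()))


def find_outlier_runs(
    flags: np.ndarray,
    meta: pd.DataFrame,
    min_run: int = 3,
) -> list[OutlierRun]:
    """Maximal runs of >= min_run consecutive flagged loci per chromosome.

    ``flags`` is boolean per locus, aligned with ``meta`` (chrom, pos).
    Loci are sorted by (chromosome, position) internally; runs never span
    chromosome boundaries.  Locus indices in the result refer to the
    original (input) order.
    """
    flags = np.asarray(flags, bool)
    order = _sorted_order(meta)
    runs: list[OutlierRun] = []
    chrom_sorted = meta["chrom"].astype(str).to_numpy()[order]
    pos_sorted = meta["pos"].to_numpy()[order]
    flag_sorted = flags[order]
    start = None
    for i in range(len(order) + 1):
        boundary = (
            i == len(order)
            or not flag_sorted[i]
            or (i > 0 and chrom_sorted[i] != chrom_sorted[i - 1])
        )
        if start is not None and boundary:
            length = i - start
            if length >= min_run:
                runs.append(
                    OutlierRun(
                        chrom=chrom_sorted[start],
                        start_locus=int(order[start]),
                        end_locus=int(order[i - 1]),
                        start_pos=int(pos_sorted[start]),
                        end_pos=int(pos_sorted[i - 1]),
                        length=length,
                    )
                )
            start = None
        if i < len(order) and flag_sorted[i] and start is None:
            start = i
    return runs


def _max_run_per_chrom(flag_sorted: np.ndarray, chrom_bounds: list[tuple[int, int]]) -> int:
    best = 0
    for a, b in chrom_bounds:
        seg = flag_sorted[a:b]
        if not seg.any():
            continue
        # run lengths via change points
        d = np.diff(np.concatenate(([0], seg.view(np.int8), [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        best = max(best, int((ends - starts).max()))
    return best


def run_permutation_test(
    flags: np.ndarray,
    meta: pd.DataFrame,
    min_run: int = 3,
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for observing any run of >= min_run flags.

    Flag positions are shuffled genome-wide (each chromosome keeps its
    locus count; flags may land on any chromosome), matching a null of
    outliers randomly distributed across the data set.
    p = (1 + # permutations with max run >= min_run) / (1 + n_perm).
    """
    flags = np.asarray(flags, bool)
    if flags.sum() == 0:
        raise ValueError("no flagged loci")
    if flags.sum() < min_run:
        return 1.0  # no permutation can reach the cutoff
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    order = _sorted_order(meta)
    chrom_sorted = meta["chrom"].astype(str).to_numpy()[order]
    # contiguous [a, b) blocks per chromosome in sorted order
    bounds = []
    a = 0
    for i in range(1, len(chrom_sorted) + 1):
        if i == len(chrom_sorted) or chrom_sorted[i] != chrom_sorted[i - 1]:
            bounds.append((a, i))
            a = i
    flag_sorted = flags[order].copy()
    if flags.all():
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    work = flag_sorted.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _max_run_per_chrom(work, bounds) >= min_run:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def exact_run_probability(n_loci: int, n_flags: int, min_run: int) -> float:
    """Exhaustive probability of a run >= min_run on a single chromosome.

    Enumerates all C(n_loci, n_flags) placements; oracle-grade, only for
    tiny cases.
    """
    from math import comb

    idx = range(n_loci)
    hits = 0
    total = 0
    for placement in combinations(idx, n_flags):
        total += 1
        run = best = 1
        for a, b in zip(placement, placement[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        if best >= min_run:
            hits += 1
    assert total == comb(n_loci, n_flags)
    return hits / total
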