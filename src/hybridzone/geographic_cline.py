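"""Transect projection, sigmoid geographic cline fitting and zone movement.

The cline model is the conventional sigmoid

    p(x) = pmin + (pmax - pmin) / (1 + exp(-4 (x - c) / w))

where ``c`` is the centre (inflection, km along the axis perpendicular to
the hybrid-zone interface) and ``w`` the width, defined as the inverse of
the maximum slope (hence the factor 4).  Ancestry proportions per
individual are regressed on p(x) by bounded least squares; uncertainty
comes from a nonparametric bootstrap over individuals.  Movement between
two sampling periods is the difference of fitted centres, positive toward
the north-west side of the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hybridzone.genotype_io import SampleTable

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320


@dataclass
class TransectBaseline:
    """A line through ``anchor`` with compass bearing ``bearing_deg``.

    The default bearing of 45 degrees runs SW-NE; signed perpendicular
    distances are positive on the NW side of that line.
    """

    anchor_lon: float
    anchor_lat: float
    bearing_deg: float = 45.0

    def __post_init__(self) -> None:
        if not 0 <= self.bearing_deg < 360:
            raise ValueError(f"bearing must be in [0, 360), got {self.bearing_deg}")


@dataclass
class GeographicCline:
    pmin: float
    pmax: float
    centre_km: float
    width_km: float
    residual_sd: float
    n: int
    period: str = ""
    degenerate: bool = False
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    boot_samples: pd.DataFrame | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return sigmoid_cline(np.asarray(x, float), self.pmin, self.pmax, self.centre_km, self.width_km)


@dataclass
class ClineShift:
    delta_c_km: float
    interval_years: float
    rate_km_per_yr: float
    ci: tuple[float, float] | None = None


def sigmoid_cline(x, pmin, pmax, c, w):
    """Evaluate the sigmoid cline p(x)."""
    z = np.clip(-4.0 * (np.asarray(x, float) - c) / w, -700.0, 700.0)
    return pmin + (pmax - pmin) / (1.0 + np.exp(z))


def local_km_coordinates(lon, lat, baseline: TransectBaseline) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular (east_km, north_km) offsets about the anchor."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    east = (lon - baseline.anchor_lon) * KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(baseline.anchor_lat))
    north = (lat - baseline.anchor_lat) * KM_PER_DEG_LAT
    return east, north


def project_to_transect(samples: SampleTable | pd.DataFrame, baseline: TransectBaseline) -> np.ndarray:
    """Signed perpendicular distance (km) of each sample from the baseline.

    Positive on the NW side of a SW-NE line (left of the bearing vector).
    """
    table = samples.table if isinstance(samples, SampleTable) else samples
    east, north = local_km_coordinates(table["lon"].to_numpy(), table["lat"].to_numpy(), baseline)
    theta = np.deg2rad(baseline.bearing_deg)
    # z-component of (direction x position): direction = (sin θ, cos θ)
    return np.sin(theta) * north - np.cos(theta) * east


def invert_transect_position(x_km, along_km, baseline: TransectBaseline) -> tuple[np.ndarray, np.ndarray]:
    """Place points at perpendicular distance ``x_km`` / along-line offset
    ``along_km`` from the anchor, returning (lon, lat).

    Exact inverse of :func:`project_to_transect` under the equirectangular
    approximation; used by the simulator so true transect distances are
    exact by construction.
    """
    x_km = np.asarray(x_km, float)
    along_km = np.asarray(along_km, float)
    theta = np.deg2rad(baseline.bearing_deg)
    d_e, d_n = np.sin(theta), np.cos(theta)  # along-line unit vector
    n_e, n_n = -np.cos(theta), np.sin(theta)  # left normal (positive side)
    east = along_km * d_e + x_km * n_e
    north = along_km * d_n + x_km * n_n
    lon = baseline.anchor_lon + east / (KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(baseline.anchor_lat)))
    lat = baseline.anchor_lat + north / KM_PER_DEG_LAT
    return lon, lat


# ---------------------------------------------------------------------------
# Fitting


def _fit_once(x, q, p0, bounds) -> tuple[np.ndarray, float]:
    def resid(theta):
        return sigmoid_cline(x, *theta) - q

    res = optimize.least_squares(resid, p0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
    return res.x, float(np.sum(res.fun**2))


def fit_geographic_cline(
    x,
    q,
    restarts: int = 20,
    seed: int | None = None,
    period: str = "",
    init: np.ndarray | None = None,
) -> GeographicCline:
    """Bounded least-squares fit of the sigmoid cline to ancestry values.

    Multi-start: centres are seeded on a quantile grid of ``x`` (plus
    random jitter), widths on a log-spaced grid; the best SSE wins.
    ``init`` short-circuits the multi-start with a single warm start
    (used by the bootstrap).
    """
    x = np.asarray(x, float)
    q = np.asarray(q, float)
    if x.size < 8:
        raise ValueError(f"need >= 8 individuals to fit a cline, got {x.size}")
    if np.ptp(q) < 1e-12:
        cl = GeographicCline(float(q[0]), float(q[0]), float(np.median(x)), np.ptp(x) or 1.0,
                             0.0, x.size, period, degenerate=True)
        return cl
    rng = np.random.default_rng(seed)
    span = np.ptp(x)
    pad = 0.5 * span
    lo = [0.0, 0.0, x.min() - pad, 1e-3]
    hi = [1.0, 1.0, x.max() + pad, 10.0 * span]
    bounds = (lo, hi)

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.clip(init, lo, hi))
    else:
        qlo, qhi = np.quantile(q, [0.05, 0.95])
        c_grid = np.quantile(x, np.linspace(0.1, 0.9, max(restarts // 4, 3)))
        w_grid = span * np.array([0.1, 0.3, 1.0])
        for c0 in c_grid:
            for w0 in w_grid:
                starts.append(np.array([qlo, qhi, c0, w0]))
        while len(starts) < restarts:
            starts.append(
                np.array([qlo, qhi, rng.uniform(x.min(), x.max()), span * rng.uniform(0.05, 2.0)])
            )

    best, best_sse = None, np.inf
    for p0 in starts:
        try:
            theta, sse = _fit_once(x, q, p0, bounds)
        except Exception:
            continue
        if sse < best_sse - 1e-14:
            best, best_sse = theta, sse
    if best is None:
        raise RuntimeError("cline fit failed from every start")
    pmin, pmax, c, w = best
    degenerate = (pmax - pmin) < 1e-6
    resid_sd = float(np.sqrt(best_sse / max(x.size - 4, 1)))
    return GeographicCline(float(pmin), float(pmax), float(c), float(w),
                           resid_sd, x.size, period, degenerate=degenerate)


def bootstrap_cline(
    x,
    q,
    n_boot: int = 1000,
    seed: int | None = None,
    fit: GeographicCline | None = None,
) -> GeographicCline:
    """Percentile bootstrap CIs for (pmin, pmax, centre, width).

    Individuals are resampled with replacement; each resample is refit with
    a warm start at the point estimate.  Degenerate resample fits are
    dropped (and counted in ``ci['n_dropped']``-free attribute; reported
    via the returned frame's length).
    """
    x = np.asarray(x, float)
    q = np.asarray(q, float)
    if fit is None:
        fit = fit_geographic_cline(x, q, seed=seed)
    if fit.degenerate:
        raise ValueError("cannot bootstrap a degenerate cline fit")
    rng = np.random.default_rng(seed)
    init = np.array([fit.pmin, fit.pmax, fit.centre_km, fit.width_km])
    rows = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        xb, qb = x[idx], q[idx]
        if np.ptp(qb) < 1e-12 or np.unique(xb).size < 4:
            continue
        try:
            bfit = fit_geographic_cline(xb, qb, init=init)
        except Exception:
            continue
        if not bfit.degenerate:
            rows.append((bfit.pmin, bfit.pmax, bfit.centre_km, bfit.width_km))
    boot = pd.DataFrame(rows, columns=["pmin", "pmax", "centre_km", "width_km"])
    ci = {
        col: tuple(np.percentile(boot[col], [2.5, 97.5])) if len(boot) else (np.nan, np.nan)
        for col in boot.columns
    }
    fit.ci = ci
    fit.boot_samples = boot
    return fit


def estimate_movement(
    cline1: GeographicCline,
    cline2: GeographicCline,
    interval_years: float,
    seed: int | None = None,
) -> ClineShift:
    """Cline-centre shift between two periods and its per-year rate.

    Δc = c(period 2) - c(period 1), positive toward the NW.  When both fits
    carry bootstrap samples, a Δc CI is formed by independently resampling
    the two bootstrap centre distributions.
    """
    if cline1.degenerate or cline2.degenerate:
        raise ValueError("movement undefined for degenerate cline fits")
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    delta = cline2.centre_km - cline1.centre_km
    ci = None
    if cline1.boot_samples is not None and cline2.boot_samples is not None:
        rng = np.random.default_rng(seed)
        c1 = cline1.boot_samples["centre_km"].to_numpy()
        c2 = cline2.boot_samples["centre_km"].to_numpy()
        n = 10000
        draws = c2[rng.integers(0, c2.size, n)] - c1[rng.integers(0, c1.size, n)]
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
    return ClineShift(float(delta), float(interval_years), float(delta / interval_years), ci)


# ---------------------------------------------------------------------------
# Two-sample comparisons


def compare_periods(values1, values2, test: str = "welch_t") -> tuple[float, float]:
    """Two-sided two-sample test between sampling periods.

    ``welch_t``: unequal-variance t with Satterthwaite df.
    ``mann_whitney``: U statistic, normal approximation with tie correction.
    ``two_proportion``: inputs are (successes, trials) pairs; pooled z-test.
    Returns (statistic, p).
    """
    if test == "two_proportion":
        (s1, n1), (s2, n2) = values1, values2
        if n1 <= 0 or n2 <= 0:
            raise ValueError("empty group in two_proportion test")
        p1, p2 = s1 / n1, s2 / n2
        pool = (s1 + s2) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        if se == 0:
            return 0.0, 1.0
        z = (p1 - p2) / se
        return float(z), float(2 * stats.norm.sf(abs(z)))
    a = np.asarray(values1, float)
    b = np.asarray(values2, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if test == "welch_t":
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            return 0.0, 1.0
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if test == "mann_whitney":
        # exact null distribution for small tie-free samples, otherwise the
        # tie-corrected normal approximation
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return float(u), float(p)
    raise ValueError(f"unknown test {test!r}")


def interpolate_ancestry_surface(
    samples: SampleTable | pd.DataFrame,
    q,
    grid_lon: np.ndarray,
    grid_lat: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Inverse-distance-weighted ancestry surface on a lon/lat grid.

    A grid node coincident with a sample takes that sample's value exactly;
    values are clipped to [0, 1].  QC/visualisation only — movement is
    quantified by the cline fits.
    """
    table = samples.table if isinstance(samples, SampleTable) else samples
    q = np.asarray(q, float)
    if len(table) < 3:
        raise ValueError("need >= 3 samples for interpolation")
    glon, glat = np.meshgrid(np.asarray(grid_lon, float), np.asarray(grid_lat, float))
    if glon.size == 0:
        raise ValueError("degenerate grid spec")
    d2 = (glon[..., None] - table["lon"].to_numpy()) ** 2 + (
        glat[..., None] - table["lat"].to_numpy()
    ) ** 2
    dist = np.sqrt(d2)
    out = np.empty(glon.shape)
    exact = dist.min(axis=-1) == 0.0
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    denom = w.sum(axis=-1)
    denom[denom == 0] = 1.0
    out = (w * q).sum(axis=-1) / denom
    nearest = dist.argmin(axis=-1)
    out[exact] = q[nearest[exact]]
    return np.clip(out, 0.0, 1.0)
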