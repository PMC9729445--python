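"""Synthetic hybrid-zone datasets under the inference modules' own model.

The generator inverts the analysis chain's generative assumptions so that
every downstream stage has a parameter-recovery target with known truth:

1. Parental allele frequencies: a ``divergence`` fraction of loci get
   near-fixed differences (p1 ~ U(0.95, 1), p0 ~ U(0, 0.05)); the rest are
   shared (p0 = p1 ~ U(0.05, 0.95)).
2. Each sampling site sits at an exact transect distance x (coordinates are
   produced by inverting the transect projection), and each period t has a
   true sigmoid ancestry cline p_t(x) with its own centre.
3. Individual hybrid indices are drawn h ~ Beta(nu p_t(x), nu (1 - p_t(x)))
   so cline fits see realistic scatter (concentration nu, default 50).
4. Per locus, each of the two allele copies is of species-1 ancestry with
   probability Phi(h; alpha*, beta*) (the genomic cline function), then the
   allele is drawn from that species' parental frequency.  Free
   recombination between RAD loci.
5. RAD-style missingness is applied per call.

Defaults mirror the study design: ~30 transect sites spanning the
interface, two periods 36 years apart, a planted centre shift of 5.66 km
to the NW, cline width 10 km, 2000 loci (half divergent) across six
chromosomes including Z, and 20 planted positive-beta outliers
(beta* = 1) containing a 4-locus consecutive run on Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridzone import genotype_io
from hybridzone.genotype_io import MISSING, GenotypeMatrix, SampleTable
from hybridzone.climate_trends import ClimateGrid, write_ascii_grid, read_ascii_grid
from hybridzone.genomic_cline import phi
from hybridzone.geographic_cline import (
    TransectBaseline,
    invert_transect_position,
    project_to_transect,
    sigmoid_cline,
)


class SimConfigError(ValueError):
    """A SimConfig field violates its invariant (names the field)."""


@dataclass
class SimConfig:
    """Full specification of one synthetic hybrid-zone dataset."""

    n_loci: int = 2000
    chrom_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("1", 500), ("2", 400), ("3", 300), ("4", 250), ("5", 250), ("Z", 300)
        ]
    )
    site_positions: list[tuple[str, float, float]] | None = None  # (site, lon, lat)
    n_per_site_per_period: int = 2
    periods: list[tuple[str, int]] = field(
        default_factory=lambda: [("historical", 1980), ("modern", 2016)]
    )
    # (pmin, pmax, centre period 1 km, centre period 2 km, width km)
    cline_truth: tuple[float, float, float, float, float] = (0.0, 1.0, 0.0, 5.66, 10.0)
    divergence: float = 0.5
    outlier_truth: list[tuple[int, float, float]] = field(default_factory=list)
    h_concentration: float = 50.0
    missing_rate: float = 0.1
    seed: int = 0
    baseline: TransectBaseline = field(
        default_factory=lambda: TransectBaseline(-94.0, 38.2, 45.0)
    )

    def __post_init__(self) -> None:
        if sum(n for _, n in self.chrom_plan) != self.n_loci:
            raise SimConfigError(
                "chrom_plan: locus counts sum to "
                f"{sum(n for _, n in self.chrom_plan)}, expected n_loci={self.n_loci}"
            )
        pmin, pmax, _, _, w = self.cline_truth
        if not (0 <= pmin < pmax <= 1):
            raise SimConfigError(f"cline_truth: need 0 <= pmin < pmax <= 1, got {pmin}, {pmax}")
        if w <= 0:
            raise SimConfigError(f"cline_truth: width must be > 0, got {w}")
        if self.h_concentration <= 0:
            raise SimConfigError(f"h_concentration: must be > 0, got {self.h_concentration}")
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError(f"missing_rate: must be in [0, 1), got {self.missing_rate}")
        if not 0 <= self.divergence <= 1:
            raise SimConfigError(f"divergence: must be in [0, 1], got {self.divergence}")
        if len(self.periods) != 2:
            raise SimConfigError("periods: exactly two (label, anchor year) pairs required")
        for idx, a, b in self.outlier_truth:
            if not 0 <= idx < self.n_loci:
                raise SimConfigError(f"outlier_truth: locus index {idx} out of range")
        if self.site_positions is None:
            self.site_positions = default_site_positions(self.baseline)

    @property
    def interval_years(self) -> int:
        return self.periods[1][1] - self.periods[0][1]


def default_site_positions(
    baseline: TransectBaseline,
    n_sites: int = 30,
    x_min: float = -40.0,
    x_max: float = 40.0,
) -> list[tuple[str, float, float]]:
    """Transect sites at exact perpendicular distances, SW-NE staggered.

    Distances are inverted through the transect projection so that the
    projected x of each site reproduces the requested value exactly.
    """
    x = np.linspace(x_min, x_max, n_sites)
    along = np.linspace(-8.0, 8.0, n_sites)  # scatter along the interface
    lon, lat = invert_transect_position(x, along, baseline)
    return [(f"site{i + 1:02d}", float(lo), float(la)) for i, (lo, la) in enumerate(zip(lon, lat))]


def planted_beta_outliers(
    config_chrom_plan: list[tuple[str, int]],
    n_outliers: int = 20,
    beta_star: float = 1.0,
    run_length: int = 4,
    run_chrom: str = "Z",
    seed: int = 7,
) -> list[tuple[int, float, float]]:
    """Plant positive-beta outliers including one consecutive run on Z.

    Returns (locus index, alpha*, beta*) triples: ``run_length`` loci
    adjacent in position order on ``run_chrom`` plus scattered singles
    elsewhere (never adjacent to each other).
    """
    chrom_of = np.concatenate(
        [np.full(n, c, dtype=object) for c, n in config_chrom_plan]
    )
    n_loci = chrom_of.size
    z_idx = np.flatnonzero(chrom_of == run_chrom)
    if z_idx.size < run_length:
        raise SimConfigError(f"chrom_plan: fewer than {run_length} loci on {run_chrom}")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, z_idx.size - run_length + 1))
    run = list(z_idx[start : start + run_length])
    chosen = set(run)
    candidates = [i for i in range(n_loci) if chrom_of[i] != run_chrom]
    rng.shuffle(candidates)
    for i in candidates:
        if len(chosen) >= n_outliers:
            break
        if (i - 1) in chosen or (i + 1) in chosen:
            continue
        chosen.add(i)
    return [(int(i), 0.0, float(beta_star)) for i in sorted(chosen)]


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-design defaults with planted positive-beta outliers.

    30 transect sites x 2 individuals/site/period (~60 per period), 2000
    loci (half divergent) across six chromosomes, planted centre shift
    5.66 km, width 10 km, 20 planted +beta loci (beta* = 1) including a
    4-locus consecutive run on Z, 10% missingness.
    """
    plan = overrides.pop(
        "chrom_plan",
        [("1", 500), ("2", 400), ("3", 300), ("4", 250), ("5", 250), ("Z", 300)],
    )
    outliers = overrides.pop("outlier_truth", planted_beta_outliers(plan))
    n_loci = sum(n for _, n in plan)
    return SimConfig(
        n_loci=n_loci, chrom_plan=plan, outlier_truth=outliers, seed=seed, **overrides
    )


def cline_shift_config(seed: int = 0, delta_c_km: float = 5.66) -> SimConfig:
    """Cline-shift recovery design: 1000 fully divergent loci, no planted
    locus effects, 30 sites x 2 individuals/site/period."""
    return SimConfig(
        seed=seed,
        n_loci=1000,
        chrom_plan=[("1", 1000)],
        divergence=1.0,
        missing_rate=0.0,
        cline_truth=(0.0, 1.0, 0.0, delta_c_km, 10.0),
    )


def genomic_cline_study_config(seed: int = 0) -> SimConfig:
    """Genomic-cline calibration design: 2000 loci, ~150 admixed
    individuals concentrated near the zone centre, planted +beta loci with
    a 4-locus run on Z, flanked by parental reference sites."""
    plan = [("1", 500), ("2", 400), ("3", 300), ("4", 250), ("5", 250), ("Z", 300)]
    bl = TransectBaseline(-94.0, 38.2, 45.0)
    inner = default_site_positions(bl, n_sites=28, x_min=-8.0, x_max=8.0)
    left = default_site_positions(bl, n_sites=8, x_min=-45.0, x_max=-38.0)
    right = default_site_positions(bl, n_sites=8, x_min=38.0, x_max=45.0)
    sites = (
        [(f"adm{i:02d}", lon, lat) for i, (_, lon, lat) in enumerate(inner)]
        + [(f"ref0_{i}", lon, lat) for i, (_, lon, lat) in enumerate(left)]
        + [(f"ref1_{i}", lon, lat) for i, (_, lon, lat) in enumerate(right)]
    )
    return SimConfig(
        seed=seed,
        n_loci=2000,
        chrom_plan=plan,
        site_positions=sites,
        n_per_site_per_period=3,
        outlier_truth=planted_beta_outliers(plan),
        missing_rate=0.0,
        divergence=0.5,
        baseline=bl,
    )


@dataclass
class SimulatedDataset:
    """Genotypes + metadata + the full truth table behind them."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    truth_individuals: pd.DataFrame  # individual, site, period, x_km, true_h
    truth_loci: pd.DataFrame  # locus, chrom, pos, rad_locus, p0, p1, alpha, beta
    truth_clines: pd.DataFrame  # period, pmin, pmax, centre_km, width_km
    config: SimConfig


def _locus_metadata(config: SimConfig) -> pd.DataFrame:
    chroms, positions, rads = [], [], []
    locus_id = 0
    for chrom, n in config.chrom_plan:
        pos = 1000 * (1 + np.arange(n))  # strictly increasing within chromosome
        chroms.extend([chrom] * n)
        positions.extend(pos.tolist())
        rads.extend([f"L{locus_id + k:05d}" for k in range(n)])
        locus_id += n
    return pd.DataFrame({"chrom": chroms, "pos": positions, "rad_locus": rads})


def simulate_hybrid_zone(config: SimConfig) -> SimulatedDataset:
    """Draw a complete dataset under the generative model described above.

    Deterministic given ``config.seed`` (identical config => identical
    output, byte-identical once written).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    meta = _locus_metadata(config)

    # parental frequencies
    n_div = int(round(config.divergence * L))
    forced = [i for i, _, _ in config.outlier_truth]
    div_idx = set(forced)
    pool = [i for i in range(L) if i not in div_idx]
    rng.shuffle(pool)
    for i in pool:
        if len(div_idx) >= max(n_div, len(forced)):
            break
        div_idx.add(i)
    is_div = np.zeros(L, bool)
    is_div[list(div_idx)] = True
    p0 = np.empty(L)
    p1 = np.empty(L)
    shared = rng.uniform(0.05, 0.95, L)
    p0[:] = shared
    p1[:] = shared
    p1[is_div] = rng.uniform(0.95, 1.0, is_div.sum())
    p0[is_div] = rng.uniform(0.0, 0.05, is_div.sum())

    alpha_star = np.zeros(L)
    beta_star = np.zeros(L)
    for i, a, b in config.outlier_truth:
        alpha_star[i] = a
        beta_star[i] = b

    pmin, pmax, c1, c2, w = config.cline_truth
    centres = {config.periods[0][0]: c1, config.periods[1][0]: c2}

    sites = pd.DataFrame(config.site_positions, columns=["site", "lon", "lat"])
    site_x = project_to_transect(sites, config.baseline)

    rows, truth_rows = [], []
    h_list = []
    for period, _year in config.periods:
        c = centres[period]
        for s, (site, lon, lat) in enumerate(zip(sites["site"], sites["lon"], sites["lat"])):
            x = float(site_x[s])
            p_exp = float(sigmoid_cline(x, pmin, pmax, c, w))
            for k in range(config.n_per_site_per_period):
                ind = f"{period}_{site}_{k + 1}"
                if p_exp <= 0.0:
                    h = 0.0
                elif p_exp >= 1.0:
                    h = 1.0
                else:
                    h = float(
                        rng.beta(
                            config.h_concentration * p_exp,
                            config.h_concentration * (1.0 - p_exp),
                        )
                    )
                panel = ""
                if p_exp >= 0.999:
                    panel = "ref1"
                elif p_exp <= 0.001:
                    panel = "ref0"
                rows.append((ind, site, lon, lat, period, panel))
                truth_rows.append((ind, site, period, x, h))
                h_list.append(h)

    samples = SampleTable(
        pd.DataFrame(rows, columns=["individual", "site", "lon", "lat", "period", "panel"])
    )
    truth_ind = pd.DataFrame(
        truth_rows, columns=["individual", "site", "period", "x_km", "true_h"]
    )
    h = np.array(h_list)
    N = h.size

    # allele-copy ancestries then alleles, vectorised over individuals x loci
    ph = phi(h[:, None], alpha_star[None, :], beta_star[None, :])
    k1 = rng.binomial(2, ph)  # copies of species-1 ancestry
    alt = rng.binomial(k1, p1[None, :]) + rng.binomial(2 - k1, p0[None, :])
    values = alt.astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random((N, L)) < config.missing_rate
        values[miss] = MISSING

    gm = GenotypeMatrix(values=values, individuals=list(truth_ind["individual"]), locus_meta=meta)
    truth_loci = meta.copy()
    truth_loci.insert(0, "locus", np.arange(L))
    truth_loci["p0"] = p0
    truth_loci["p1"] = p1
    truth_loci["alpha"] = alpha_star
    truth_loci["beta"] = beta_star
    truth_loci["divergent"] = is_div
    truth_clines = pd.DataFrame(
        {
            "period": [p for p, _ in config.periods],
            "anchor_year": [y for _, y in config.periods],
            "pmin": pmin,
            "pmax": pmax,
            "centre_km": [c1, c2],
            "width_km": w,
        }
    )
    return SimulatedDataset(gm, samples, truth_ind, truth_loci, truth_clines, config)


def multisite_fixture(config: SimConfig, max_sites_per_locus: int = 3) -> GenotypeMatrix:
    """Variant genotype matrix with 1-3 variable sites per RAD locus.

    Extra sites at a locus are independent re-draws at nearby positions,
    sharing the RAD locus id, so the one-site-per-locus filter has real
    work to do.  Intended for filter fixtures, not inference tests.
    """
    ds = simulate_hybrid_zone(config)
    rng = np.random.default_rng(config.seed + 1)
    n_sites = rng.integers(1, max_sites_per_locus + 1, ds.genotypes.n_loci)
    cols, meta_rows = [], []
    for j in range(ds.genotypes.n_loci):
        base = ds.genotypes.locus_meta.iloc[j]
        for s in range(int(n_sites[j])):
            if s == 0:
                cols.append(ds.genotypes.values[:, j])
            else:
                p = ds.truth_loci["p1"].iloc[j]
                cols.append(rng.binomial(2, p, ds.genotypes.n_individuals).astype(np.int8))
            meta_rows.append((base["chrom"], int(base["pos"]) + 10 * s, base["rad_locus"]))
    values = np.column_stack(cols)
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "rad_locus"])
    return GenotypeMatrix(values=values, individuals=ds.genotypes.individuals, locus_meta=meta)


# ---------------------------------------------------------------------------
# Climate simulation


@dataclass
class RegionSpec:
    """A rectangular region (cell-index slices) with linear trends."""

    name: str
    rows: tuple[int, int]  # half-open row range
    cols: tuple[int, int]
    temp_base: float = 12.0
    temp_rate: float = 0.02  # degC / yr
    precip_base: float = 1000.0
    precip_rate: float = 1.0  # mm / yr


@dataclass
class ClimateSimConfig:
    grid_shape: tuple[int, int] = (40, 40)
    cell_size: float = 0.05
    origin: tuple[float, float] = (-95.0, 37.5)  # (xllcorner, yllcorner)
    regions: list[RegionSpec] | None = None  # default: west/east halves
    noise_sd: float = 0.05
    years: tuple[int, int] = (1976, 2016)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            nr, nc = self.grid_shape
            self.regions = [
                RegionSpec("west", (0, nr), (0, int(0.45 * nc)), temp_rate=0.02),
                RegionSpec("east", (0, nr), (int(0.55 * nc), nc), temp_rate=0.03),
            ]
        if len(self.regions) < 1:
            raise SimConfigError("regions: at least one region required")
        masks = [self.region_mask(r) for r in self.regions]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    raise SimConfigError(
                        f"regions: {self.regions[i].name} and {self.regions[j].name} overlap"
                    )

    def region_mask(self, region: RegionSpec) -> np.ndarray:
        m = np.zeros(self.grid_shape, bool)
        m[region.rows[0] : region.rows[1], region.cols[0] : region.cols[1]] = True
        return m


def simulate_climate_stack(config: ClimateSimConfig) -> dict[str, dict[int, ClimateGrid]]:
    """Yearly grids per variable: value = base + rate (year - year0) + noise.

    Cells outside every region are nodata.  Returns
    ``{"tmean": {year: grid}, "ppt": {year: grid}}``.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    out: dict[str, dict[int, ClimateGrid]] = {"tmean": {}, "ppt": {}}
    masks = [(r, config.region_mask(r)) for r in config.regions]
    for year in range(y0, y1 + 1):
        for var in ("tmean", "ppt"):
            vals = np.full(config.grid_shape, np.nan)
            for region, mask in masks:
                base = region.temp_base if var == "tmean" else region.precip_base
                rate = region.temp_rate if var == "tmean" else region.precip_rate
                level = base + rate * (year - y0)
                noise = rng.normal(0.0, config.noise_sd, config.grid_shape) if config.noise_sd > 0 else 0.0
                vals[mask] = level + (noise[mask] if config.noise_sd > 0 else 0.0)
            out[var][year] = ClimateGrid(
                vals, config.origin[0], config.origin[1], config.cell_size,
                variable=var, label=str(year),
            )
    return out


# ---------------------------------------------------------------------------
# On-disk round trip


def write_dataset(dataset: SimulatedDataset, directory, climate: dict | None = None) -> dict[str, str]:
    """Write VCF + CSV metadata + truth tables (+ optional rasters).

    Returns a manifest of written paths.  ``read_dataset`` on the same
    directory reproduces the in-memory dataset exactly.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(directory / "genotypes.vcf"),
        "samples": str(directory / "samples.csv"),
        "truth_individuals": str(directory / "truth_individuals.csv"),
        "truth_loci": str(directory / "truth_loci.csv"),
        "truth_clines": str(directory / "truth_clines.csv"),
    }
    genotype_io.write_vcf(dataset.genotypes, paths["vcf"])
    dataset.samples.to_csv(paths["samples"])
    dataset.truth_individuals.to_csv(paths["truth_individuals"], index=False)
    dataset.truth_loci.to_csv(paths["truth_loci"], index=False)
    dataset.truth_clines.to_csv(paths["truth_clines"], index=False)
    if climate:
        for var, stack in climate.items():
            for year, grid in stack.items():
                p = directory / f"{var}_{year}.asc"
                write_ascii_grid(grid, p)
                paths[f"{var}_{year}"] = str(p)
    return paths


def read_dataset(directory) -> tuple[GenotypeMatrix, SampleTable]:
    """Read back the genotype matrix and sample table written by write_dataset."""
    from pathlib import Path

    directory = Path(directory)
    gm = genotype_io.read_vcf(directory / "genotypes.vcf")
    samples = SampleTable.from_csv(directory / "samples.csv")
    return gm, samples
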