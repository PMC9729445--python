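"""Climate raster stacks: window means, rates of change, regional contrasts.

Rasters travel as ESRI ASCII grids (6-line header: ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value, then rows north-to-south).  The analysis
follows a two-window design: average each climate variable over a 5-year
window at each end of the study interval, difference the window means, and
divide by the interval length in years to get a per-year rate of change.
Regional summaries are taken over cells within a fixed buffer (degrees) of
the sampling sites, and two regions are contrasted as a percent difference
of mean rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from hybridzone.genotype_io import SampleTable


@dataclass
class ClimateGrid:
    """A georeferenced raster of one climate variable for one year/window.

    ``values`` is a (nrows, ncols) float array, row 0 = northernmost;
    nodata cells hold NaN internally and the ``nodata`` sentinel on disk.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    variable: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where data is valid."""
        return ~np.isnan(self.values)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (nrows, ncols), row 0 northernmost."""
        lon = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def same_georef(self, other: "ClimateGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )


@dataclass
class RateGrid(ClimateGrid):
    """Per-year rate of change with the same georeferencing."""

    start_label: str = ""
    end_label: str = ""
    interval_years: float = np.nan


class AsciiGridError(ValueError):
    pass


def read_ascii_grid(path, variable: str = "", label: str = "") -> ClimateGrid:
    """Parse an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise AsciiGridError(f"{path}: missing header field {req}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = " ".join(lines[i:])
    try:
        flat = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    except ValueError as exc:
        raise AsciiGridError(f"{path}: cannot parse grid body: {exc}") from exc
    if flat.size != nrows * ncols:
        raise AsciiGridError(
            f"{path}: expected {nrows * ncols} values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    return ClimateGrid(values, header["xllcorner"], header["yllcorner"],
                       header["cellsize"], nodata, variable, label)


def write_ascii_grid(grid: ClimateGrid, path) -> None:
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def window_mean(stack: dict[int, ClimateGrid], years: tuple[int, int]) -> ClimateGrid:
    """Cellwise mean over an inclusive year window (typically 5 years).

    A cell is masked in the result if it is masked in any contributing
    year.  All grids must share georeferencing.
    """
    y0, y1 = years
    wanted = list(range(y0, y1 + 1))
    missing = [y for y in wanted if y not in stack]
    if missing:
        raise ValueError(f"window_mean: missing years {missing}")
    grids = [stack[y] for y in wanted]
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_georef(g):
            raise ValueError("window_mean: inconsistent georeferencing across years")
    arr = np.stack([g.values for g in grids])
    mean = arr.mean(axis=0)  # NaN propagates: any masked year masks the cell
    return replace(ref, values=mean, label=f"{y0}-{y1}")


def rate_of_change(
    mean_start: ClimateGrid, mean_end: ClimateGrid, interval_years: float
) -> RateGrid:
    """Cellwise (end - start) / interval_years."""
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    if not mean_start.same_georef(mean_end):
        raise ValueError("rate_of_change: georeferencing mismatch")
    rate = (mean_end.values - mean_start.values) / interval_years
    return RateGrid(
        rate,
        mean_start.xllcorner,
        mean_start.yllcorner,
        mean_start.cellsize,
        mean_start.nodata,
        mean_start.variable,
        f"{mean_start.label}->{mean_end.label}",
        start_label=mean_start.label,
        end_label=mean_end.label,
        interval_years=float(interval_years),
    )


def buffer_cells(grid: ClimateGrid, sites: SampleTable | pd.DataFrame, radius_deg: float = 0.5) -> np.ndarray:
    """Mask of cells whose centre lies within ``radius_deg`` of any site.

    Distance is Euclidean in degrees, matching the 0.5-degree buffer
    convention of the study design.
    """
    table = sites.table if isinstance(sites, SampleTable) else sites
    if len(table) == 0:
        raise ValueError("no sites given")
    lon, lat = grid.cell_centres()
    d2min = np.full(grid.values.shape, np.inf)
    for _, row in table.drop_duplicates(subset=["lon", "lat"]).iterrows():
        d2 = (lon - row["lon"]) ** 2 + (lat - row["lat"]) ** 2
        np.minimum(d2min, d2, out=d2min)
    return np.sqrt(d2min) <= radius_deg


def regional_mean_rate(rate: RateGrid, mask: np.ndarray) -> float:
    """Unweighted mean rate over unmasked, valid cells."""
    sel = mask & rate.mask
    if not sel.any():
        raise ValueError("no valid cells inside region mask")
    return float(rate.values[sel].mean())


def regional_contrast(
    rate_a: RateGrid, mask_a: np.ndarray, rate_b: RateGrid, mask_b: np.ndarray
) -> float:
    """Percent by which region A's mean rate exceeds region B's.

    100 * (mean_A - mean_B) / mean_B; errors when mean_B is zero.
    """
    mean_a = regional_mean_rate(rate_a, mask_a)
    mean_b = regional_mean_rate(rate_b, mask_b)
    if mean_b == 0:
        raise ValueError("regional contrast undefined: reference region mean rate is 0")
    return 100.0 * (mean_a - mean_b) / mean_b


def rate_histogram(rate: RateGrid, mask: np.ndarray, bin_width: float) -> pd.DataFrame:
    """Frequency histogram of rates over masked cells; bins [lo, hi)."""
    sel = mask & rate.mask
    vals = rate.values[sel]
    if vals.size == 0:
        raise ValueError("no valid cells to histogram")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil((vals.max() + 1e-12) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts})
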