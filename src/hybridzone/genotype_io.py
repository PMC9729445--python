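"""Genotype matrices, sample metadata, VCF I/O and SNP filters.

Genotypes are stored as counts of the counted (by default ALT) allele per
diploid individual, so values live in {0, 1, 2} with a boolean missing mask.
Filters implement the study's marker-selection rules: one variable site per
RAD locus, singleton removal, and a per-locus presence threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel inside the int8 values array


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele counts with per-locus metadata.

    Attributes
    ----------
    values : (n_individuals, n_loci) int8 array; counts of the counted
        allele in {0,1,2}, ``MISSING`` (-1) where the call is absent.
    individuals : list of individual ids (rows).
    locus_meta : DataFrame with columns ``chrom``, ``pos`` (1-based),
        ``rad_locus`` (nullable), one row per column of ``values``.
    """

    values: np.ndarray
    individuals: list[str]
    locus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (individuals x loci)")
        if self.values.shape[0] != len(self.individuals):
            raise ValueError(
                f"{len(self.individuals)} individuals but "
                f"{self.values.shape[0]} genotype rows"
            )
        if self.values.shape[1] != len(self.locus_meta):
            raise ValueError(
                f"{len(self.locus_meta)} locus_meta rows but "
                f"{self.values.shape[1]} genotype columns"
            )
        ok = (self.values >= 0) & (self.values <= 2) | (self.values == MISSING)
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"genotype values outside {{0,1,2,missing}}: {bad}")
        self.locus_meta = self.locus_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where missing."""
        return self.values == MISSING

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.missing_mask)

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[:, idx],
            individuals=list(self.individuals),
            locus_meta=self.locus_meta.iloc[idx].reset_index(drop=True),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[idx, :],
            individuals=[self.individuals[i] for i in idx],
            locus_meta=self.locus_meta.copy(),
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (counted-allele copies, total non-missing copies)."""
        obs = ~self.missing_mask
        alt = np.where(obs, self.values, 0).sum(axis=0)
        tot = 2 * obs.sum(axis=0)
        return alt.astype(int), tot.astype(int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and np.array_equal(self.values, other.values)
            and self.locus_meta[["chrom", "pos", "rad_locus"]]
            .astype(str)
            .equals(other.locus_meta[["chrom", "pos", "rad_locus"]].astype(str))
        )


@dataclass
class SampleTable:
    """Per-individual site, coordinates, sampling period and panel label.

    ``panel`` uses "ref0"/"ref1" for parental reference individuals
    (species 0 = Carolina-like, species 1 = black-capped-like) and empty
    string / NaN for everyone else.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("individual", "site", "lon", "lat", "period")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        if "panel" not in self.table.columns:
            self.table = self.table.assign(panel="")
        self.table = self.table.reset_index(drop=True)
        if self.table["individual"].duplicated().any():
            dups = self.table["individual"][self.table["individual"].duplicated()]
            raise ValueError(f"duplicate individuals in sample table: {list(dups)}")
        lat, lon = self.table["lat"], self.table["lon"]
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates out of range (|lat|<=90, |lon|<=180)")

    def __len__(self) -> int:
        return len(self.table)

    def panel_ids(self, label: str) -> list[str]:
        t = self.table
        return list(t.loc[t["panel"].fillna("") == label, "individual"])

    def aligned_to(self, individuals: list[str]) -> pd.DataFrame:
        """Rows reordered to match a genotype matrix's individual order."""
        t = self.table.set_index("individual")
        missing = [i for i in individuals if i not in t.index]
        if missing:
            raise ValueError(f"individuals absent from sample table: {missing}")
        return t.loc[individuals].reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        t = pd.read_csv(path, dtype={"individual": str, "site": str})
        if "panel" in t.columns:
            t["panel"] = t["panel"].fillna("")
        return cls(t)


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path) -> GenotypeMatrix:
    """Parse a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields are summed to ALT-allele counts; ``./.`` becomes
    missing.  Multiallelic records are rejected (counted and reported).
    RAD locus ids are read from the INFO key ``LOCUS`` when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error passthrough
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(rec.genotypes)  # (n, 3): allele0, allele1, phased
        alleles = gts[:, :2]
        missing = (alleles < 0).any(axis=1)
        counts = alleles.clip(min=0).sum(axis=1).astype(np.int8)
        counts[missing] = MISSING
        rows.append(counts)
        locus = rec.INFO.get("LOCUS")
        meta.append((rec.CHROM, rec.POS, None if locus is None else str(locus)))
    if n_multi:
        logger.warning("read_vcf: rejected %d multiallelic records", n_multi)
    values = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    locus_meta = pd.DataFrame(meta, columns=["chrom", "pos", "rad_locus"])
    return GenotypeMatrix(values=values, individuals=individuals, locus_meta=locus_meta)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF 4.2 with GT fields and INFO LOCUS annotations.

    Records are written in locus_meta order; REF/ALT are placeholder A/T
    (allele identity carries no information in this count representation).
    """
    contigs = list(dict.fromkeys(gm.locus_meta["chrom"].astype(str)))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridzone\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="RAD locus id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [str(i) for i in gm.individuals]
        fh.write("\t".join(header) + "\n")
        for j, row in gm.locus_meta.iterrows():
            locus = row["rad_locus"]
            info = "." if locus is None or (isinstance(locus, float) and np.isnan(locus)) else f"LOCUS={locus}"
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                f"snp{j}",
                "A",
                "T",
                ".",
                "PASS",
                info,
                "GT",
            ]
            fields += [gt_strings[int(v)] for v in gm.values[:, j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filters


def select_one_snp_per_locus(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly one variable site per RAD locus.

    The site with the lowest position is retained; ties broken by input
    order.  Requires the ``rad_locus`` annotation on every locus.
    """
    rad = gm.locus_meta["rad_locus"]
    if rad.isna().any():
        n_bad = int(rad.isna().sum())
        raise ValueError(f"rad_locus annotation missing for {n_bad} loci")
    order = np.lexsort((np.arange(gm.n_loci), gm.locus_meta["pos"].to_numpy()))
    seen: dict[str, int] = {}
    for j in order:
        key = str(rad.iloc[j])
        if key not in seen:
            seen[key] = j
    keep = np.sort(np.fromiter(seen.values(), dtype=int))
    logger.info(
        "select_one_snp_per_locus: %d -> %d loci", gm.n_loci, keep.size
    )
    return gm.take_loci(keep)


def filter_singletons(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop loci whose minor allele occurs exactly once (allele copies).

    A single heterozygote carries the minor allele once, so [0,0,0,1] is a
    singleton column while [0,0,2,0] is not.
    """
    alt, tot = gm.allele_counts()
    mac = np.minimum(alt, tot - alt)
    keep = np.flatnonzero(mac != 1)
    logger.info("filter_singletons: removed %d loci", gm.n_loci - keep.size)
    return gm.take_loci(keep)


def filter_by_presence(gm: GenotypeMatrix, min_fraction: float = 0.9) -> GenotypeMatrix:
    """Keep loci called in at least ``min_fraction`` of individuals."""
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    presence = (~gm.missing_mask).mean(axis=0)
    keep = np.flatnonzero(presence >= min_fraction)
    logger.info("filter_by_presence(%.2f): removed %d loci", min_fraction, gm.n_loci - keep.size)
    return gm.take_loci(keep)
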