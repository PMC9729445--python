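"""End-to-end orchestration: simulate -> filter -> ancestry -> clines ->
scans -> climate -> report, with a run manifest and full determinism.

One global seed deterministically derives per-stage seeds (CRC32 of the
stage name mixed with the global seed), so any stage can be rerun in
isolation and reproduce the full run's numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hybridzone import __version__, ancestry, climate_trends, genome_scan, genotype_io
from hybridzone import genomic_cline as gcl
from hybridzone import geographic_cline as geo
from hybridzone import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "ancestry", "geocline", "genomcline", "scan", "climate"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults mirror the study's choices."""

    outdir: str = "hybridzone_run"
    seed: int = 0
    # inputs: either paths to an existing dataset, or a simulation
    vcf: str | None = None
    samples_csv: str | None = None
    simulate: bool = True
    sim: synth.SimConfig | None = None
    climate_sim: synth.ClimateSimConfig | None = None
    # filters
    presence_min_fraction: float = 0.9
    drop_singletons: bool = True
    one_snp_per_locus: bool = True
    # ancestry / classification
    pure_threshold: float = 0.99
    hybrid_threshold: float = 0.95
    # geographic cline
    bearing_deg: float = 45.0
    baseline_lon: float | None = None
    baseline_lat: float | None = None
    n_boot: int = 400
    interval_years: float | None = None  # default: difference of period anchor years
    # genomic cline MCMC
    mcmc_iterations: int = 5000
    mcmc_burnin: int = 2500
    mcmc_thin: int = 5
    prior_sd: float = 1.0
    # scans
    min_run: int = 3
    n_perm: int = 10000
    # climate
    buffer_radius_deg: float = 0.5
    window_years: int = 5

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir``.

    Returns the manifest dict (also written as manifest.json).  Rerunning
    with identical config + seed writes byte-identical CSV outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        for p in (config.vcf, config.samples_csv):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"input path missing or nonexistent: {p}")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    artifacts: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        fn()
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.1fs", name, manifest["stages"][name]["seconds"])

    # --- simulate / load -------------------------------------------------
    def do_simulate():
        if config.simulate:
            sim = config.sim or synth.default_study_config(seed=stage_seed(config.seed, "simulate"))
            ds = synth.simulate_hybrid_zone(sim)
            synth.write_dataset(ds, outdir / "dataset")
            artifacts["dataset"] = ds
            artifacts["gm"] = ds.genotypes
            artifacts["samples"] = ds.samples
            artifacts["baseline"] = sim.baseline
            artifacts["interval_years"] = config.interval_years or sim.interval_years
        else:
            artifacts["gm"] = genotype_io.read_vcf(config.vcf)
            artifacts["samples"] = genotype_io.SampleTable.from_csv(config.samples_csv)
            if config.baseline_lon is None or config.baseline_lat is None:
                t = artifacts["samples"].table
                artifacts["baseline"] = geo.TransectBaseline(
                    float(t["lon"].mean()), float(t["lat"].mean()), config.bearing_deg
                )
            else:
                artifacts["baseline"] = geo.TransectBaseline(
                    config.baseline_lon, config.baseline_lat, config.bearing_deg
                )
            artifacts["interval_years"] = config.interval_years or 36.0

    # --- filter ----------------------------------------------------------
    def do_filter():
        gm = artifacts["gm"]
        if config.one_snp_per_locus and gm.locus_meta["rad_locus"].notna().all():
            gm = genotype_io.select_one_snp_per_locus(gm)
        if config.drop_singletons:
            gm = genotype_io.filter_singletons(gm)
        gm = genotype_io.filter_by_presence(gm, config.presence_min_fraction)
        artifacts["gm_filtered"] = gm
        genotype_io.write_vcf(gm, outdir / "filtered.vcf")

    # --- ancestry --------------------------------------------------------
    def do_ancestry():
        gm = artifacts["gm_filtered"]
        samples = artifacts["samples"]
        meta = samples.aligned_to(gm.individuals)
        panel0 = samples.panel_ids("ref0")
        panel1 = samples.panel_ids("ref1")
        seed = stage_seed(config.seed, "ancestry")
        if panel0 and panel1:
            freqs = ancestry.parental_allele_frequencies(gm, panel0, panel1)
            est = ancestry.hybrid_index_ml(gm, freqs)
            panel = ancestry.diagnostic_panel(gm, panel0, panel1)
        else:
            est_em, _ = ancestry.admixture_em(gm, seed=seed)
            est = est_em
            p0_ids = list(est.loc[est["q"] <= 0.01, "individual"])
            p1_ids = list(est.loc[est["q"] >= 0.99, "individual"])
            freqs = ancestry.parental_allele_frequencies(gm, p0_ids, p1_ids) if p0_ids and p1_ids else None
            panel = (
                ancestry.diagnostic_panel(gm, p0_ids, p1_ids)
                if p0_ids and p1_ids
                else pd.DataFrame(columns=["locus", "chrom", "pos", "orientation"])
            )
        est = ancestry.classify_individuals(est, config.pure_threshold, config.hybrid_threshold)
        if len(panel):
            est["H"] = ancestry.interspecific_heterozygosity(gm, panel).to_numpy()
        else:
            est["H"] = np.nan
        scores = ancestry.genotype_pca(gm, n_components=2, orient_with=est["q"].to_numpy())
        est["PC1"] = scores[:, 0]
        est["PC2"] = scores[:, 1]
        est = est.merge(meta[["individual", "site", "lon", "lat", "period", "panel"]], on="individual")
        est.to_csv(outdir / "ancestry.csv", index=False)
        if len(panel):
            panel.to_csv(outdir / "diagnostic_panel.csv", index=False)
        artifacts["ancestry"] = est
        artifacts["freqs"] = freqs
        artifacts["panel"] = panel

    # --- geographic cline ------------------------------------------------
    def do_geocline():
        est = artifacts["ancestry"]
        baseline = artifacts["baseline"]
        x = geo.project_to_transect(est, baseline)
        est = est.assign(x_km=x)
        est[["individual", "x_km", "q", "period"]].to_csv(outdir / "transect.csv", index=False)
        seed = stage_seed(config.seed, "geocline")
        periods = list(dict.fromkeys(est["period"]))
        fits = {}
        rows = []
        for k, period in enumerate(periods):
            sub = est[est["period"] == period].dropna(subset=["q"])
            fit = geo.fit_geographic_cline(sub["x_km"], sub["q"], seed=seed + k, period=str(period))
            fit = geo.bootstrap_cline(
                sub["x_km"].to_numpy(), sub["q"].to_numpy(), n_boot=config.n_boot,
                seed=seed + 100 + k, fit=fit,
            )
            fits[period] = fit
            rows.append(
                {
                    "period": period, "pmin": fit.pmin, "pmax": fit.pmax,
                    "centre_km": fit.centre_km, "width_km": fit.width_km,
                    "centre_lo": fit.ci["centre_km"][0], "centre_hi": fit.ci["centre_km"][1],
                    "n": fit.n,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "cline_fit.csv", index=False)
        shift = None
        if len(periods) == 2:
            shift = geo.estimate_movement(
                fits[periods[0]], fits[periods[1]], artifacts["interval_years"], seed=seed + 500
            )
            pd.DataFrame(
                [
                    {
                        "delta_c_km": shift.delta_c_km,
                        "interval_years": shift.interval_years,
                        "rate_km_per_yr": shift.rate_km_per_yr,
                        "delta_c_lo": shift.ci[0] if shift.ci else np.nan,
                        "delta_c_hi": shift.ci[1] if shift.ci else np.nan,
                    }
                ]
            ).to_csv(outdir / "movement.csv", index=False)
        artifacts["cline_fits"] = fits
        artifacts["shift"] = shift
        artifacts["ancestry"] = est

    # --- genomic clines --------------------------------------------------
    def do_genomcline():
        gm = artifacts["gm_filtered"]
        est = artifacts["ancestry"].set_index("individual").loc[gm.individuals]
        freqs = artifacts["freqs"]
        if freqs is None:
            raise RuntimeError("genomic clines require parental panels")
        use = freqs.defined
        gm_use = gm.take_loci(np.flatnonzero(use))
        h = est["q"].to_numpy(float)
        fit = gcl.fit_genomic_clines_mcmc(
            gm_use, h, freqs.p0[use], freqs.p1[use],
            iterations=config.mcmc_iterations, burnin=config.mcmc_burnin,
            thin=config.mcmc_thin, prior_sd=config.prior_sd,
            seed=stage_seed(config.seed, "genomcline"),
        )
        outliers = gcl.classify_outliers(fit)
        outliers["category"] = gcl.outlier_category_labels(outliers)
        outliers.to_csv(outdir / "genomic_clines.csv", index=False)
        artifacts["gcl_fit"] = fit
        artifacts["outliers"] = outliers

    # --- scans -----------------------------------------------------------
    def do_scan():
        outliers = artifacts["outliers"]
        seed = stage_seed(config.seed, "scan")
        gtest = genome_scan.chromosome_composition_test(outliers["category"], outliers["chrom"])
        gtest.to_csv(outdir / "chrom_gtest.csv", index=False)
        meta = outliers[["chrom", "pos"]].reset_index(drop=True)
        flags = outliers["pos_beta"].to_numpy(bool)
        runs = genome_scan.find_outlier_runs(flags, meta, min_run=config.min_run)
        run_df = pd.DataFrame([vars(r) for r in runs])
        run_df.to_csv(outdir / "outlier_runs.csv", index=False)
        with open(outdir / "outlier_runs.bed", "w") as fh:
            for r in runs:
                fh.write(f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\tposbeta_run\n")
        # the permutation p quantifies how unlikely a run of >= min_run is
        # under random flag placement; only meaningful when a run was seen
        p = (
            genome_scan.run_permutation_test(
                flags, meta, min_run=config.min_run, n_perm=config.n_perm, seed=seed
            )
            if runs
            else np.nan
        )
        artifacts["gtest"] = gtest
        artifacts["runs"] = runs
        artifacts["run_perm_p"] = p

    # --- climate ---------------------------------------------------------
    def do_climate():
        csim = config.climate_sim or synth.ClimateSimConfig(seed=stage_seed(config.seed, "climate"))
        stacks = synth.simulate_climate_stack(csim)
        y0, y1 = csim.years
        w = config.window_years
        start_win = (y0, y0 + w - 1)
        end_win = (y1 - w + 1, y1)
        interval = end_win[1] - start_win[1]
        results = {}
        for var, stack in stacks.items():
            m_start = climate_trends.window_mean(stack, start_win)
            m_end = climate_trends.window_mean(stack, end_win)
            rate = climate_trends.rate_of_change(m_start, m_end, interval)
            masks = [csim.region_mask(r) for r in csim.regions]
            means = [climate_trends.regional_mean_rate(rate, m) for m in masks]
            contrast = climate_trends.regional_contrast(rate, masks[1], rate, masks[0]) if len(masks) >= 2 else np.nan
            results[var] = {
                "region_means": dict(zip([r.name for r in csim.regions], means)),
                "contrast_pct": contrast,
                "interval_years": interval,
            }
        with open(outdir / "climate_contrast.json", "w") as fh:
            json.dump(results, fh, indent=2)
        artifacts["climate"] = results

    stage_fns = {
        "simulate": do_simulate,
        "filter": do_filter,
        "ancestry": do_ancestry,
        "geocline": do_geocline,
        "genomcline": do_genomcline,
        "scan": do_scan,
        "climate": do_climate,
    }
    for name in STAGES:
        try:
            run_stage(name, stage_fns[name])
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    report = make_report(artifacts)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(format_report(report))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = manifest
    artifacts["report"] = report
    return artifacts


def percent_increase(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after`` (e.g. of a mean hybrid
    index between sampling periods)."""
    if before == 0:
        raise ValueError("percent increase undefined for a zero baseline")
    return 100.0 * (after - before) / before


def percent_of(part: float, whole: float) -> float:
    """Share of ``whole`` represented by ``part``, in percent (e.g. outlier
    loci among all loci analysed)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def make_report(artifacts: dict) -> dict:
    """Summarise the run's headline quantities (machine-readable).

    Missing artifacts are listed under ``missing`` and the rest of the
    report is still produced.
    """
    report: dict = {"missing": []}
    est = artifacts.get("ancestry")
    if est is not None:
        hyb = {}
        for period, sub in est.groupby("period"):
            labelled = sub[sub["class"] != "undefined"]
            hyb[str(period)] = {
                "n": int(len(labelled)),
                "hybrid_fraction": float((labelled["class"] == "hybrid").mean()),
                "mean_q": float(labelled["q"].mean()),
            }
        report["hybrid_proportions_by_period"] = hyb
    else:
        report["missing"].append("ancestry")
    shift = artifacts.get("shift")
    if shift is not None:
        report["cline_shift"] = {
            "delta_c_km": shift.delta_c_km,
            "rate_km_per_yr": shift.rate_km_per_yr,
            "interval_years": shift.interval_years,
            "ci": list(shift.ci) if shift.ci else None,
        }
    else:
        report["missing"].append("cline_shift")
    outliers = artifacts.get("outliers")
    if outliers is not None:
        counts = outliers["category"].value_counts().to_dict()
        n = len(outliers)
        report["outliers"] = {
            "n_loci": n,
            "n_outliers": int(outliers["outlier"].sum()),
            "pct_outliers": 100.0 * float(outliers["outlier"].mean()),
            "by_category": {str(k): int(v) for k, v in counts.items()},
            "pct_pos_beta": 100.0 * float(outliers["pos_beta"].mean()),
        }
    else:
        report["missing"].append("outliers")
    runs = artifacts.get("runs")
    if runs is not None:
        report["pos_beta_runs"] = {
            "n_runs": len(runs),
            "runs": [vars(r) for r in runs],
            "permutation_p": artifacts.get("run_perm_p"),
        }
    else:
        report["missing"].append("runs")
    gtest = artifacts.get("gtest")
    if gtest is not None:
        report["chromosome_gtests"] = gtest.to_dict(orient="records")
    climate = artifacts.get("climate")
    if climate is not None:
        report["climate"] = climate
    else:
        report["missing"].append("climate")
    return report


def format_report(report: dict) -> str:
    lines = ["hybridzone run report", "=" * 40]
    cs = report.get("cline_shift")
    if cs:
        lines.append(
            f"cline centre shift: {cs['delta_c_km']:.2f} km over "
            f"{cs['interval_years']:.0f} yr = {cs['rate_km_per_yr']:.3f} km/yr"
        )
        if cs.get("ci"):
            lines.append(f"  95% CI for shift: [{cs['ci'][0]:.2f}, {cs['ci'][1]:.2f}] km")
    out = report.get("outliers")
    if out:
        lines.append(
            f"genomic-cline outliers: {out['n_outliers']}/{out['n_loci']} loci "
            f"({out['pct_outliers']:.2f}%)"
        )
        for cat, n in sorted(out["by_category"].items()):
            lines.append(f"  {cat}: {n}")
    rb = report.get("pos_beta_runs")
    if rb:
        lines.append(
            f"consecutive +beta runs: {rb['n_runs']} (permutation p = {rb['permutation_p']})"
        )
    hyb = report.get("hybrid_proportions_by_period")
    if hyb:
        for period, d in hyb.items():
            lines.append(
                f"period {period}: n={d['n']}, hybrid fraction {d['hybrid_fraction']:.2f}, "
                f"mean q {d['mean_q']:.3f}"
            )
    cl = report.get("climate")
    if cl:
        for var, d in cl.items():
            lines.append(f"climate {var}: contrast {d['contrast_pct']:.1f}% between regions")
    if report.get("missing"):
        lines.append(f"missing artifacts: {', '.join(report['missing'])}")
    return "\n".join(lines) + "\n"
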