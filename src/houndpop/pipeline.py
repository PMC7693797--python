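"""Declarative end-to-end runs: QC -> stats -> ROH -> Ne -> distances ->
pedigree -> iHS from one YAML config, with deterministic seeds and logging.

Each stage writes its tables under a named subdirectory of the output
directory; a machine-readable ``summary.json`` collects the headline
numbers, and ``run.log`` records versions, seeds, and the fully resolved
parameter set. A stage failure aborts the run but preserves everything
already written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__, genotype_io, ld, pedigree, popstats, roh, selection, synthetic_data

STAGES = ("simulate", "qc", "stats", "dist", "roh", "ne", "pedigree", "ihs")

_DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "houndpop_run",
    "log_level": "INFO",
    "genotypes": None,   # PLINK prefix
    "simulate": {"design": "full_sib", "n_snps": 2000, "n_chrom": 2,
                 "chrom_length_bp": 50_000_000},
    "qc": {"snp_call_rate": 0.95, "sample_call_rate": 0.90,
           "autosomes_only": True, "max_per_pop": 48, "min_per_pop": 5},
    "stats": {},
    "dist": {"format": "nexus"},
    "roh": {"min_snps": 25, "min_length_bp": 500_000, "max_het": 0,
            "max_missing": 5, "island_threshold": 0.70,
            "autosome_length_bp": roh.AUTOSOME_LENGTH_BP},
    "ne": {"max_dist_bp": 5e6, "n_bins": 20, "maf_min": 0.05, "alpha": 1.0,
           "cM_per_Mb": 1.0},
    "pedigree": {"path": None, "reference": None},
    "ihs": {"vcf": None, "maf_min": 0.05, "bin_width": 0.025,
            "cM_per_Mb": 1.0, "ehh_floor": 0.05},
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    cfg["stages"] = user.pop("stages", None)
    for key, value in user.items():
        if key not in _DEFAULTS:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(_DEFAULTS[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config block {key!r} must be a mapping")
            for sub in value:
                if sub not in _DEFAULTS[key]:
                    raise ConfigError(f"unknown key {key}.{sub}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in fixed order; return the summary dict."""
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("houndpop.pipeline")
    logger.setLevel(cfg["log_level"])
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    stages = cfg["stages"] or [
        s for s in STAGES
        if (s == "simulate" and cfg["genotypes"] is None)
        or (s in ("qc", "stats", "dist", "roh", "ne"))
        or (s == "pedigree" and cfg["pedigree"]["path"])
        or (s == "ihs" and cfg["ihs"]["vcf"])
    ]
    logger.info("houndpop %s | seed=%s | stages=%s", __version__, cfg["seed"], stages)
    logger.info("resolved config: %s", json.dumps(cfg, default=str))
    summary: dict = {"version": __version__, "seed": cfg["seed"], "stages": stages}
    ds = None
    current_stage = None
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            current_stage = stage
            t0 = time.time()
            stage_dir = out / stage
            stage_dir.mkdir(exist_ok=True)
            if stage == "simulate":
                sim = cfg["simulate"]
                sim_cfg = synthetic_data.SimConfig(
                    seed=cfg["seed"], n_snps=sim["n_snps"], n_chrom=sim["n_chrom"],
                    chrom_length_bp=sim["chrom_length_bp"],
                )
                ped_df, _ = synthetic_data.sim_pedigree(sim["design"], seed=cfg["seed"])
                founders = synthetic_data.sim_founder_haplotypes(sim_cfg, 64)
                ds, truth = synthetic_data.gene_drop(ped_df, founders, sim_cfg)
                genotype_io.write_plink(ds, stage_dir / "simulated")
                ped_df.to_csv(stage_dir / "pedigree.csv", index=False)
                truth.to_json(stage_dir / "truth.json")
                summary["simulate"] = {"n_samples": ds.n_samples, "n_snps": ds.n_snps}
            elif stage == "qc":
                if ds is None:
                    ds = genotype_io.read_plink(cfg["genotypes"])
                q = cfg["qc"]
                ds, report = genotype_io.qc_filter(
                    ds, q["snp_call_rate"], q["sample_call_rate"], q["autosomes_only"]
                )
                ds = genotype_io.subsample_populations(
                    ds, q["max_per_pop"], q["min_per_pop"], cfg["seed"]
                )
                report.to_frame().to_csv(stage_dir / "qc_report.tsv", sep="\t", index=False)
                genotype_io.write_plink(ds, stage_dir / "filtered")
                summary["qc"] = dataclasses.asdict(report)
            elif stage == "stats":
                table = popstats.stats_table(ds)
                table.to_csv(stage_dir / "population_stats.tsv", sep="\t", index=False)
                summary["stats"] = table.to_dict(orient="records")
            elif stage == "dist":
                if len(ds.populations) < 2:
                    logger.info("dist: fewer than two populations, skipped")
                    continue
                dm = popstats.distance_matrix(ds)
                popstats.export_phylip(dm, stage_dir / "nei.dist")
                popstats.export_nexus(dm, stage_dir / "nei.nex")
                summary["dist"] = {"labels": dm.labels}
            elif stage == "roh":
                r = cfg["roh"]
                params = roh.ROHParams(
                    min_snps=r["min_snps"], min_length_bp=r["min_length_bp"],
                    max_het=r["max_het"], max_missing=r["max_missing"],
                    autosome_length_bp=r["autosome_length_bp"],
                )
                segments = roh.call_roh(ds, params)
                roh.segments_to_frame(segments).to_csv(
                    stage_dir / "segments.tsv", sep="\t", index=False
                )
                roh.write_bed(segments, stage_dir / "segments.bed")
                summaries = roh.classify_and_summarize(segments, ds.samples, params)
                frames = [s.to_frame() for s in summaries.values()]
                import pandas as pd

                pd.concat(frames).to_csv(stage_dir / "summary.tsv", sep="\t", index=False)
                incidence = roh.roh_incidence(segments, ds)
                incidence.to_csv(stage_dir / "incidence.tsv", sep="\t", index=False)
                islands = roh.find_islands(incidence, ds.n_samples, r["island_threshold"])
                summary["roh"] = {
                    "n_segments": len(segments),
                    "n_islands": len(islands),
                    "mean_froh": {
                        pop: s.by_class["all"].f_roh for pop, s in summaries.items()
                    },
                }
            elif stage == "ne":
                n = cfg["ne"]
                bins = ld.ld_decay_bins(ds, n["max_dist_bp"], n["n_bins"], n["maf_min"])
                est = ld.estimate_ne(bins, ds.n_samples, n["alpha"], n["cM_per_Mb"])
                est.to_csv(stage_dir / "ne_trajectory.tsv", sep="\t", index=False)
                valid = est["ne"].dropna()
                summary["ne"] = {
                    "median_ne": float(valid.median()) if len(valid) else None
                }
            elif stage == "pedigree":
                ped = pedigree.read_pedigree(cfg["pedigree"]["path"])
                pedigree.per_individual_table(ped).to_csv(
                    stage_dir / "per_individual.tsv", sep="\t", index=False
                )
                metrics = pedigree.pedigree_metrics(ped)
                metrics.summary().to_csv(stage_dir / "metrics.tsv", sep="\t", index=False)
                summary["pedigree"] = dataclasses.asdict(metrics)
            elif stage == "ihs":
                i = cfg["ihs"]
                panel = selection.read_phased_vcf(i["vcf"])
                result = selection.ihs_scan(
                    panel, i["maf_min"], i["bin_width"], i["cM_per_Mb"], i["ehh_floor"]
                )
                result.to_csv(stage_dir / "ihs.tsv", sep="\t", index=False)
                top = result.reindex(result["ihs"].abs().sort_values(ascending=False).index)
                summary["ihs"] = top.head(10).to_dict(orient="records")
            logger.info("stage %s done in %.2fs", stage, time.time() - t0)
    except Exception:
        logger.exception("stage %s failed; partial outputs preserved", current_stage)
        logger.removeHandler(handler)
        handler.close()
        raise
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    logger.removeHandler(handler)
    handler.close()
    return summary
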