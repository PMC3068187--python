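"""End-to-end pipeline: simulate -> call -> estimate -> evaluate -> cost.

``run_pipeline`` chains the package's stages over a single config and
seed, writing every stage's outputs (truth VCF, counts TSV, calls VCF,
frequency TSV, evaluation report, cost table) plus the resolved config
and a manifest into a run directory.  Identical config + seed yields
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .caller import (
    DEFAULT_ALPHA_ERROR,
    DEFAULT_ALPHA_POOL,
    DEFAULT_MIN_ALT,
    call_variants,
)
from .costs import cost_table
from .design import PoolDesign
from .evaluate import detection_summary, match_calls
from .freqs import error_histogram, estimate_frequency, frequency_correlation
from .simulate import (
    DEFAULT_COVERAGE_DISPERSION,
    DEFAULT_ERROR_RATE,
    DEFAULT_INDEL_FRACTION,
    DEFAULT_MEAN_COVERAGE,
    simulate_site_counts,
    simulate_truth,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Study-scale defaults: 5 pools of 20, ~600x pools, 0.75% error."""

    n_pools: int = 5
    individuals_per_pool: int = 20
    n_sites: int = 2849
    sfs: str | None = None              # None -> neutral (mass ∝ 1/count)
    indel_fraction: float = DEFAULT_INDEL_FRACTION
    mean_coverage_per_pool: float = DEFAULT_MEAN_COVERAGE
    coverage_dispersion: float | None = DEFAULT_COVERAGE_DISPERSION
    error_rate: float = DEFAULT_ERROR_RATE
    imbalance: float | None = None
    alpha_error: float = DEFAULT_ALPHA_ERROR
    alpha_pool: float = DEFAULT_ALPHA_POOL
    min_alt: int = DEFAULT_MIN_ALT
    coverage_thresholds: tuple[int, ...] = (10, 30)
    maf_threshold: float = 0.05
    cost_sample_tiers: tuple[int, ...] = (400, 4000, 10_000)
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "call", "freq", "evaluate", "cost")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for tup_field in ("coverage_thresholds", "cost_sample_tiers", "stages"):
            setattr(cfg, tup_field, tuple(getattr(cfg, tup_field)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def run_pipeline(config: PipelineConfig | dict, out_dir) -> dict:
    """Run the configured stages; return a results dict with file paths."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.save_config(config.to_dict(), out / "config.yaml")
    design = PoolDesign(config.n_pools, config.individuals_per_pool)
    results: dict = {"out_dir": str(out), "stages_run": []}

    truth = None
    table = None
    calls = None

    if "simulate" in config.stages:
        truth = simulate_truth(
            design,
            config.n_sites,
            sfs=config.sfs,
            indel_fraction=config.indel_fraction,
            seed=config.seed,
        )
        table = simulate_site_counts(
            truth,
            design,
            mean_coverage_per_pool=config.mean_coverage_per_pool,
            coverage_dispersion=config.coverage_dispersion,
            error_rate=config.error_rate,
            imbalance=config.imbalance,
            seed=config.seed,
        )
        pio.write_truth_vcf(truth, design, out / "truth.vcf")
        pio.write_counts_tsv(table, out / "counts.tsv")
        results["n_truth_sites"] = len(truth)
        results["stages_run"].append("simulate")

    if "call" in config.stages and table is not None:
        calls = call_variants(
            table,
            design,
            alpha_error=config.alpha_error,
            alpha_pool=config.alpha_pool,
            min_alt=config.min_alt,
            seed=config.seed,
        )
        pio.write_calls_vcf(calls, design, out / "calls.vcf")
        results["n_candidates"] = len(calls)
        results["n_pass"] = sum(c.passed for c in calls)
        results["stages_run"].append("call")

    if "freq" in config.stages and calls is not None and truth is not None:
        truth_by_key = {tv.key: tv for tv in truth}
        estimates = []
        for vc in calls:
            if not vc.passed:
                continue
            tv = truth_by_key.get(vc.key)
            tpp = (
                None
                if tv is None
                else [c / design.chromosomes_per_pool for c in tv.per_pool_alt_chromosomes]
            )
            fe = estimate_frequency(vc.evidence, design=design, truth_per_pool=tpp)
            if fe is not None:
                estimates.append(fe)
        rows = []
        for fe in estimates:
            errs = fe.abs_error_per_pool
            for p, est in enumerate(fe.per_pool):
                rows.append(
                    {
                        "contig": fe.contig,
                        "position": fe.position,
                        "pool": p,
                        "estimate": est,
                        "truth": None if fe.truth_per_pool is None else fe.truth_per_pool[p],
                        "abs_error": None if errs is None else errs[p],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "frequencies.tsv", sep="\t", index=False)
        with_truth = [fe for fe in estimates if fe.truth_per_pool is not None]
        summary = {
            "n_estimates": len(estimates),
            "r_squared_overall": frequency_correlation(with_truth)
            if len(with_truth) >= 3
            else None,
            "r_squared_per_pool": [
                frequency_correlation(with_truth, pool=p) if len(with_truth) >= 3 else None
                for p in range(design.n_pools)
            ],
        }
        hist = error_histogram(with_truth)
        summary["within_1_40"] = hist.get("within_0.025")
        summary["within_1_20"] = hist.get("within_0.05")
        summary["mean_abs_error"] = hist.get("mean_abs_error")
        pio.save_json(summary, out / "frequency_summary.json")
        results["frequency_summary"] = summary
        results["stages_run"].append("freq")

    if "evaluate" in config.stages and calls is not None and truth is not None:
        site_depths = {
            (table.contig, int(table.positions[s])): table.depth[s]
            for s in range(table.n_sites)
        }
        match = match_calls(calls, truth, design, min_alt_in_pool=config.min_alt)
        report = detection_summary(
            match,
            design,
            site_depths=site_depths,
            thresholds=config.coverage_thresholds,
            maf_threshold=config.maf_threshold,
        )
        report.table.to_csv(out / "eval_report.tsv", sep="\t", index=False)
        eval_summary = {
            "fdr": report.fdr(),
            "fnr_all": report.fnr("all"),
            **{
                f"fnr_cov{t}": report.fnr(f"cov{t}")
                for t in config.coverage_thresholds
            },
            **{
                f"fnr_cov{t}_low_maf": report.fnr(f"cov{t}", low_maf=True)
                for t in config.coverage_thresholds
            },
        }
        pio.save_json(eval_summary, out / "eval_summary.json")
        results["eval_summary"] = eval_summary
        results["stages_run"].append("evaluate")

    if "cost" in config.stages:
        costs = cost_table(sample_tiers=config.cost_sample_tiers)
        costs.to_csv(out / "cost_table.tsv", sep="\t", index=False)
        results["stages_run"].append("cost")

    manifest = {
        "seed": config.seed,
        "stages": results["stages_run"],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
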