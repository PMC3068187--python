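#!/usr/bin/env python
"""Allele-frequency recovery from pooled read counts.

Compares the read-fraction frequency estimate at every PASS site with
the true per-pool chromosome frequency: squared correlation per pool
and the fraction of estimates within 1/40 and 1/20 of the truth.
"""

import argparse
from pathlib import Path

from poolseq import (
    PoolDesign,
    error_histogram,
    estimate_frequency,
    frequency_correlation,
)
from poolseq.io import read_calls_vcf, read_truth_vcf, save_json


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    design = PoolDesign(5, 20)
    calls_path = args.out / "calls.vcf"
    if not calls_path.exists():
        raise SystemExit("run analysis/03_call_and_evaluate.py first")
    calls = read_calls_vcf(calls_path)
    truth = {tv.key: tv for tv in read_truth_vcf(args.out / "truth.vcf")}

    estimates = []
    for vc in calls:
        tv = truth.get(vc.key)
        if not vc.passed or tv is None:
            continue
        tpp = [c / design.chromosomes_per_pool for c in tv.per_pool_alt_chromosomes]
        fe = estimate_frequency(vc.evidence, design=design, truth_per_pool=tpp)
        if fe is not None:
            estimates.append(fe)

    r2 = [frequency_correlation(estimates, pool=p) for p in range(design.n_pools)]
    hist = error_histogram(estimates)
    print(f"{len(estimates)} PASS sites with truth")
    print("per-pool r^2:", ", ".join(f"{x:.4f}" for x in r2))
    print(f"within 1/40 of truth: {100 * hist['within_0.025']:.1f}%")
    print(f"within 1/20 of truth: {100 * hist['within_0.05']:.1f}%")
    print(f"mean |error|: {hist['mean_abs_error']:.4f}")
    save_json(
        {
            "n_sites": len(estimates),
            "r_squared_per_pool": r2,
            "within_1_40": hist["within_0.025"],
            "within_1_20": hist["within_0.05"],
            "mean_abs_error": hist["mean_abs_error"],
        },
        args.out / "frequency_summary.json",
    )


if __name__ == "__main__":
    main()
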