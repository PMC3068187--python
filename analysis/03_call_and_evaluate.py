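#!/usr/bin/env python
"""Call variants on the simulated pools and score them against truth.

Reads the counts and truth written by 01_design_and_simulation.py (or
regenerates them with the same seed if absent), runs the pool-aware
caller, and prints the detection-statistics table: truth totals,
detected, false negatives and FNR, within per-individual coverage
strata (all / >=10x / >=30x) and for the <=5% frequency class.
"""

import argparse
from pathlib import Path

from poolseq import PoolDesign, call_variants, detection_summary, match_calls
from poolseq.io import (
    read_counts_tsv,
    read_truth_vcf,
    save_json,
    write_calls_vcf,
)


def load_or_simulate(study_dir: Path, seed: int):
    from poolseq import simulate_site_counts, simulate_truth

    design = PoolDesign(5, 20)
    truth_path = study_dir / "truth.vcf"
    counts_path = study_dir / "counts.tsv"
    if truth_path.exists() and counts_path.exists():
        return design, read_truth_vcf(truth_path), read_counts_tsv(counts_path)
    truth = simulate_truth(design, 2849, seed=seed)
    return design, truth, simulate_site_counts(truth, design, seed=seed)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design, truth, table = load_or_simulate(args.out, args.seed)
    calls = call_variants(table, design, seed=args.seed)
    write_calls_vcf(calls, design, args.out / "calls.vcf")
    n_pass = sum(c.passed for c in calls)
    print(f"{len(calls)} candidate sites, {n_pass} PASS "
          f"({sum(c.passed and c.var_type != 'SNV' for c in calls)} indels)")

    site_depths = {
        (table.contig, int(table.positions[s])): table.depth[s]
        for s in range(table.n_sites)
    }
    match = match_calls(calls, truth, design)
    report = detection_summary(match, design, site_depths=site_depths)
    report.table.to_csv(args.out / "eval_report.tsv", sep="\t", index=False)

    print("\nstratum   truth  detected  FN    FNR     FNR(<=5%)")
    for stratum in ("all", "cov10", "cov30"):
        row = report.table[
            (report.table["stratum"] == stratum) & (report.table["pool"] == "sum")
        ].iloc[0]
        print(f"{stratum:8} {row['truth_total']:6.0f}  {row['detected']:7.0f} "
              f"{row['false_negatives']:4.0f}  {100 * row['fnr']:5.1f}%  "
              f"{100 * row['fnr_low']:5.1f}%")
    print(f"\npool-level FDR: {100 * report.fdr():.2f}%")
    save_json(
        {
            "n_candidates": len(calls),
            "n_pass": n_pass,
            "fdr": report.fdr(),
            "fnr": {s: report.fnr(s) for s in ("all", "cov10", "cov30")},
        },
        args.out / "eval_summary.json",
    )


if __name__ == "__main__":
    main()
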