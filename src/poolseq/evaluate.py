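"""Detection statistics: call set vs truth set, per pool and stratified.

The report mirrors the standard pooled-resequencing accounting: per
pool and summed, the number of truth variants, how many were detected,
false negatives and the false-negative rate, and false positives split
by a known-variant annotation flag (the stand-in for membership in an
external variant catalogue); all of it repeated within per-individual
coverage strata (>=10x and >=30x per individual) and restricted to
low-frequency variants (<=5% within-pool frequency, the "rare" class).

Frequency classification uses the TRUE within-pool frequency on the
truth side and the ESTIMATED read fraction for false positives, which
have no truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import VariantCall
from .design import PoolDesign
from .realign import left_normalize
from .simulate import TruthVariant

__all__ = ["MatchResult", "EvalReport", "match_calls", "stratify_by_coverage", "detection_summary"]

SiteKey = tuple[str, int, str, str]


class InputError(ValueError):
    pass


@dataclass
class MatchResult:
    """Per-pool partition of calls and truth into detected / FN / FP."""

    n_pools: int
    detected: list[set[SiteKey]]
    false_negatives: list[set[SiteKey]]
    false_positives: list[set[SiteKey]]
    truth_by_key: dict[SiteKey, TruthVariant]
    calls_by_key: dict[SiteKey, VariantCall]


def _normalized_key(
    contig: str, position: int, ref: str, alt: str, reference: str | None
) -> SiteKey:
    if reference is not None and len(ref) != len(alt):
        position, ref, alt = left_normalize(reference, position, ref, alt)
    return (contig, position, ref, alt)


def match_calls(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthVariant],
    design: PoolDesign,
    min_alt_in_pool: int = 4,
    pool_alpha: float = 1e-4,
    reference: str | None = None,
    passing_only: bool = True,
) -> MatchResult:
    """Match calls to truth by exact (normalized) position and alleles.

    Matching is per pool: a call counts as detected in pool i only if
    the truth variant segregates in pool i, and a call is *assigned* to
    pool i when that pool shows at least ``min_alt_in_pool`` supporting
    reads AND its per-pool error-test p-value clears ``pool_alpha`` —
    otherwise the handful of error reads a deep non-carrier pool
    accumulates at a real variant's site would count as pool-level
    false positives.  Indel keys are left-normalized before comparison
    when a reference is supplied.
    """
    truth_by_key: dict[SiteKey, TruthVariant] = {}
    for tv in truth:
        key = _normalized_key(tv.contig, tv.position, tv.ref_allele, tv.alt_allele, reference)
        if key in truth_by_key:
            raise InputError(f"duplicate truth record {key}")
        truth_by_key[key] = tv

    calls_by_key: dict[SiteKey, VariantCall] = {}
    for vc in calls:
        if passing_only and not vc.passed:
            continue
        ev = vc.evidence
        key = _normalized_key(ev.contig, ev.position, ev.ref_allele, ev.alt_allele, reference)
        calls_by_key[key] = vc

    P = design.n_pools
    detected = [set() for _ in range(P)]
    false_negatives = [set() for _ in range(P)]
    false_positives = [set() for _ in range(P)]
    for p in range(P):
        truth_p = {k for k, tv in truth_by_key.items() if tv.per_pool_alt_chromosomes[p] > 0}
        called_p = {
            k
            for k, vc in calls_by_key.items()
            if vc.evidence.alt_counts[p] >= min_alt_in_pool
            and vc.p_error_per_pool[p] <= pool_alpha
        }
        detected[p] = truth_p & called_p
        false_negatives[p] = truth_p - called_p
        false_positives[p] = called_p - truth_p
    return MatchResult(
        n_pools=P,
        detected=detected,
        false_negatives=false_negatives,
        false_positives=false_positives,
        truth_by_key=truth_by_key,
        calls_by_key=calls_by_key,
    )


def stratify_by_coverage(
    site_depths: Mapping[tuple[str, int], Sequence[int]],
    design: PoolDesign,
    thresholds: Sequence[int] = (10, 30),
) -> dict[int, dict[tuple[str, int], np.ndarray]]:
    """Per-individual coverage stratum membership.

    A site enters stratum t in pool p iff its pool depth divided by the
    number of individuals per pool is at least t.
    """
    N = design.individuals_per_pool
    out: dict[int, dict[tuple[str, int], np.ndarray]] = {}
    for t in thresholds:
        out[t] = {
            site: np.asarray(depths, dtype=float) / N >= t
            for site, depths in site_depths.items()
        }
    return out


@dataclass
class EvalReport:
    """Tidy detection-statistics table plus the inputs to recompute FDR."""

    table: pd.DataFrame
    maf_threshold: float
    thresholds: tuple[int, ...]

    def fdr(self, pools: Sequence[int] | None = None, stratum: str = "all") -> float:
        """False positives / total calls, optionally on a pool subset."""
        df = self.table
        rows = df[(df["stratum"] == stratum) & (df["pool"] != "sum")]
        if pools is not None:
            rows = rows[rows["pool"].isin([str(p) for p in pools])]
        fp = rows["false_positives"].sum()
        calls = rows["detected"].sum() + fp
        return float(fp / calls) if calls else float("nan")

    def fnr(self, stratum: str = "all", low_maf: bool = False) -> float:
        row = self.table[(self.table["stratum"] == stratum) & (self.table["pool"] == "sum")]
        col = "fnr_low" if low_maf else "fnr"
        return float(row[col].iloc[0])


def _call_est_freq(vc: VariantCall, pool: int) -> float:
    d = vc.evidence.depths[pool]
    return vc.evidence.alt_counts[pool] / d if d else float("nan")


def detection_summary(
    match: MatchResult,
    design: PoolDesign,
    site_depths: Mapping[tuple[str, int], Sequence[int]] | None = None,
    thresholds: Sequence[int] = (10, 30),
    maf_threshold: float = 0.05,
    known_variant_flags: Mapping[SiteKey, bool] | None = None,
) -> EvalReport:
    """Build the full detection-statistics report.

    One row per (pool, stratum) plus summed rows.  Count columns come in
    pairs: the unrestricted count and a ``_low`` companion restricted to
    <=``maf_threshold`` within-pool frequency (true frequency for
    truth-side columns, estimated for false positives).  FNR is false
    negatives over the stratum's truth total.
    """
    P = design.n_pools
    known = known_variant_flags or {}
    strata: dict[str, dict[tuple[str, int], np.ndarray] | None] = {"all": None}
    if site_depths is not None:
        cov = stratify_by_coverage(site_depths, design, thresholds)
        for t in thresholds:
            strata[f"cov{t}"] = cov[t]

    def in_stratum(key: SiteKey, pool: int, members) -> bool:
        if members is None:
            return True
        site = (key[0], key[1])
        mask = members.get(site)
        return bool(mask[pool]) if mask is not None else False

    def is_low_truth(key: SiteKey, pool: int) -> bool:
        tv = match.truth_by_key[key]
        return tv.pool_frequency(pool, design.chromosomes_per_pool) <= maf_threshold + 1e-12

    def is_low_call(key: SiteKey, pool: int) -> bool:
        f = _call_est_freq(match.calls_by_key[key], pool)
        return (not np.isnan(f)) and f <= maf_threshold + 1e-12

    rows = []
    for stratum, members in strata.items():
        sums: dict[str, float] = {}
        for p in range(P):
            det = {k for k in match.detected[p] if in_stratum(k, p, members)}
            fn = {k for k in match.false_negatives[p] if in_stratum(k, p, members)}
            fp = {k for k in match.false_positives[p] if in_stratum(k, p, members)}
            truth_total = len(det) + len(fn)
            fp_known = {k for k in fp if known.get(k, False)}
            row = {
                "pool": str(p),
                "stratum": stratum,
                "truth_total": truth_total,
                "detected": len(det),
                "false_negatives": len(fn),
                "false_positives": len(fp),
                "fp_known": len(fp_known),
                "fp_novel": len(fp) - len(fp_known),
                "truth_total_low": sum(is_low_truth(k, p) for k in det | fn),
                "detected_low": sum(is_low_truth(k, p) for k in det),
                "false_negatives_low": sum(is_low_truth(k, p) for k in fn),
                "false_positives_low": sum(is_low_call(k, p) for k in fp),
                "fp_known_low": sum(is_low_call(k, p) for k in fp_known),
            }
            row["fp_novel_low"] = row["false_positives_low"] - row["fp_known_low"]
            row["fnr"] = row["false_negatives"] / truth_total if truth_total else float("nan")
            row["fnr_low"] = (
                row["false_negatives_low"] / row["truth_total_low"]
                if row["truth_total_low"]
                else float("nan")
            )
            rows.append(row)
            for k, v in row.items():
                if isinstance(v, (int, np.integer)):
                    sums[k] = sums.get(k, 0) + v
        sum_row = {"pool": "sum", "stratum": stratum, **sums}
        tt = sum_row.get("truth_total", 0)
        ttl = sum_row.get("truth_total_low", 0)
        sum_row["fnr"] = sum_row.get("false_negatives", 0) / tt if tt else float("nan")
        sum_row["fnr_low"] = (
            sum_row.get("false_negatives_low", 0) / ttl if ttl else float("nan")
        )
        rows.append(sum_row)
    table = pd.DataFrame(rows)
    return EvalReport(table=table, maf_threshold=maf_threshold, thresholds=tuple(thresholds))
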