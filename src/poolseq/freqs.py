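"""Allele-frequency estimation from pooled read counts.

The pooled estimator is the raw read fraction: per pool, alt/depth; the
combined estimate is depth-weighted (sum of alt reads over sum of
depths across informative pools).  No error-rate correction is
subtracted.  The rounded estimate snaps to the nearest multiple of
1/(chromosomes with data), the resolution pooling can in principle
achieve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .caller import SiteEvidence
from .design import PoolDesign

__all__ = [
    "FrequencyEstimate",
    "estimate_frequency",
    "error_histogram",
    "frequency_correlation",
]


@dataclass(frozen=True)
class FrequencyEstimate:
    """Estimated allele frequency at one site, with truth when supplied."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    per_pool: tuple[float, ...]          # nan where a pool has no depth
    combined: float
    rounded: float                       # nan when no design was supplied
    truth_per_pool: tuple[float, ...] | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    @property
    def abs_error_per_pool(self) -> tuple[float, ...] | None:
        if self.truth_per_pool is None:
            return None
        return tuple(
            abs(e - t) if not np.isnan(e) else float("nan")
            for e, t in zip(self.per_pool, self.truth_per_pool)
        )


def estimate_frequency(
    evidence: SiteEvidence,
    design: PoolDesign | None = None,
    truth_per_pool: Sequence[float] | None = None,
) -> FrequencyEstimate | None:
    """Read-count frequency estimate for one site.

    Returns None (no-estimate sentinel) when every pool has zero depth.
    """
    depths = np.asarray(evidence.depths, dtype=float)
    alts = np.asarray(evidence.alt_counts, dtype=float)
    with_data = depths > 0
    if not with_data.any():
        return None
    per_pool = np.full(len(depths), np.nan)
    per_pool[with_data] = alts[with_data] / depths[with_data]
    combined = float(alts[with_data].sum() / depths[with_data].sum())
    if design is not None:
        chroms = int(with_data.sum()) * design.chromosomes_per_pool
        rounded = round(combined * chroms) / chroms
    else:
        rounded = float("nan")
    return FrequencyEstimate(
        contig=evidence.contig,
        position=evidence.position,
        ref_allele=evidence.ref_allele,
        alt_allele=evidence.alt_allele,
        per_pool=tuple(float(x) for x in per_pool),
        combined=combined,
        rounded=float(rounded),
        truth_per_pool=None if truth_per_pool is None else tuple(float(t) for t in truth_per_pool),
    )


def _paired_errors(estimates: Sequence[FrequencyEstimate]):
    """Flatten per-pool (estimate, truth) pairs over pools with data."""
    est, tru, excluded = [], [], 0
    for fe in estimates:
        if fe.truth_per_pool is None:
            excluded += 1
            continue
        for e, t in zip(fe.per_pool, fe.truth_per_pool):
            if not np.isnan(e):
                est.append(e)
                tru.append(t)
    return np.array(est), np.array(tru), excluded


def error_histogram(
    estimates: Sequence[FrequencyEstimate],
    bin_edges: Sequence[float] = (1 / 40, 1 / 20),
) -> dict:
    """Distribution of |estimate - truth| over all pool-site observations.

    Returns the fraction of observations within each requested edge
    (default: within 1/40 and within 1/20 of the true frequency), the
    full histogram, and the number of estimates excluded for lacking
    truth.
    """
    est, tru, excluded = _paired_errors(estimates)
    abs_err = np.abs(est - tru)
    n = len(abs_err)
    within = {
        f"within_{edge:g}": float((abs_err <= edge + 1e-12).mean()) if n else float("nan")
        for edge in bin_edges
    }
    hist_edges = np.linspace(0.0, 0.25, 26)
    hist, _ = np.histogram(abs_err, bins=hist_edges)
    return {
        **within,
        "n": n,
        "n_excluded_no_truth": excluded,
        "histogram_counts": hist,
        "histogram_edges": hist_edges,
        "mean_abs_error": float(abs_err.mean()) if n else float("nan"),
    }


def frequency_correlation(
    estimates: Sequence[FrequencyEstimate],
    pool: int | None = None,
) -> float:
    """Squared Pearson correlation between estimated and true frequencies.

    ``pool`` restricts to one pool's estimates (the primary, per-pool
    view); None pools all per-pool observations.  Requires >= 3 paired
    sites; returns nan when the truth has zero variance.
    """
    if pool is None:
        est, tru, _ = _paired_errors(estimates)
    else:
        est_l, tru_l = [], []
        for fe in estimates:
            if fe.truth_per_pool is None:
                continue
            e = fe.per_pool[pool]
            if not np.isnan(e):
                est_l.append(e)
                tru_l.append(fe.truth_per_pool[pool])
        est, tru = np.array(est_l), np.array(tru_l)
    if len(est) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.allclose(tru.var(), 0) or np.allclose(est.var(), 0):
        return float("nan")
    r = np.corrcoef(est, tru)[0, 1]
    return float(r**2)
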