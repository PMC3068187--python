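"""Pool-aware SNV/indel calling from per-pool filtered read counts.

The decision at every candidate site combines three ingredients:

* a **support floor**: at least ``min_alt`` (default 4) reads carrying
  the non-reference allele in one or more pools;
* a **within-pool error test** (``pool_error_pvalue``): the exact
  binomial tail probability of seeing >= k alt reads out of n if every
  alt read were a sequencing error, at the quality-derived per-allele
  error rate (e/3 per alternative base for SNVs, a separate per-read
  rate for indels).  The site-level statistic is the minimum over pools;
* a **cross-pool contingency test** (``cross_pool_test``): whether alt
  reads are concentrated in particular pools (variant-like) or dispersed
  uniformly in proportion to depth (error-like).  Exact (Fisher-rule,
  multivariate hypergeometric null) for small alt totals, Monte-Carlo
  chi-square otherwise.

A variant segregating at similar frequency in *every* pool is
homogeneous across pools by construction, so the contingency gate is
bypassed when each pool independently clears the support floor and the
error test (the "rescue" rule for common variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ._rng import substream
from .design import PoolDesign
from .simulate import SiteCountsTable

__all__ = [
    "SiteEvidence",
    "VariantCall",
    "pool_error_pvalue",
    "cross_pool_test",
    "call_variants",
    "DEFAULT_ALPHA_ERROR",
    "DEFAULT_ALPHA_POOL",
    "DEFAULT_MIN_ALT",
]

DEFAULT_ALPHA_ERROR = 1e-4
DEFAULT_ALPHA_POOL = 1e-3
DEFAULT_MIN_ALT = 4
DEFAULT_MAPQ_MIN = 20
DEFAULT_BASEQ_MIN = 10


class DataIntegrityError(ValueError):
    """Raised when evidence is internally inconsistent (e.g. alt > depth)."""


@dataclass(frozen=True)
class SiteEvidence:
    """Post-filter per-pool evidence for one candidate allele at one site."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    depths: tuple[int, ...]
    alt_counts: tuple[int, ...]
    mean_error_probs: tuple[float, ...]
    var_type: str = "SNV"
    discarded: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if any(a > d for a, d in zip(self.alt_counts, self.depths)):
            raise DataIntegrityError(
                f"alt count exceeds depth at {self.contig}:{self.position}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    @property
    def max_alt(self) -> int:
        return max(self.alt_counts)


@dataclass(frozen=True)
class VariantCall:
    """A tested candidate site with its statistics and filter status."""

    evidence: SiteEvidence
    p_error: float                       # min over pools
    p_error_per_pool: tuple[float, ...]
    p_pool: float                        # nan: not applicable / not computed
    filter_status: str                   # PASS | min_alt_fail | stat_fail
    var_type: str

    @property
    def passed(self) -> bool:
        return self.filter_status == "PASS"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.evidence.key


def pool_error_pvalue(
    alt_count: int,
    depth: int,
    mean_error_prob: float,
    var_type: str = "SNV",
    indel_error_rate: float = 1e-4,
) -> float:
    """P(X >= alt_count) for X ~ Binomial(depth, per-allele error rate).

    The per-allele rate is ``mean_error_prob / 3`` for SNVs (a
    substitution error lands on each alternative base with equal
    probability) and ``indel_error_rate`` for indels.
    """
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count must be within [0, depth]")
    if alt_count == 0:
        return 1.0
    rate = mean_error_prob / 3.0 if var_type == "SNV" else indel_error_rate
    return float(stats.binom.sf(alt_count - 1, depth, rate))


# ---------------------------------------------------------------------------
# cross-pool contingency test


def _compositions(total: int, caps: Sequence[int]) -> np.ndarray:
    """All ways to split ``total`` alt reads across pools with per-pool caps."""
    out: list[tuple[int, ...]] = []
    P = len(caps)

    def rec(i: int, remaining: int, prefix: tuple[int, ...]) -> None:
        if i == P - 1:
            if remaining <= caps[i]:
                out.append(prefix + (remaining,))
            return
        tail_cap = sum(caps[i + 1 :])
        lo = max(0, remaining - tail_cap)
        hi = min(caps[i], remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a, prefix + (a,))

    rec(0, total, ())
    return np.array(out, dtype=np.int64).reshape(-1, P)


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _exact_contingency_pvalue(alts: np.ndarray, depths: np.ndarray) -> float:
    """Fisher-rule exact p-value for the 2xP alt/ref table.

    Null: the ``total_alt`` alt reads are a simple random sample of the
    pooled reads (multivariate hypergeometric with the depth margins).
    The p-value sums the probability of every table no more probable
    than the observed one.
    """
    total_alt = int(alts.sum())
    N = int(depths.sum())
    tables = _compositions(total_alt, [int(d) for d in depths])
    logp = _log_binom(depths[None, :], tables).sum(axis=1) - _log_binom(N, total_alt)
    obs_logp = _log_binom(depths, alts).sum() - _log_binom(N, total_alt)
    p = np.exp(logp[logp <= obs_logp + 1e-9]).sum()
    return float(min(p, 1.0))


def _chi2_stat(alts: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Pearson chi-square of the 2xP table(s); alts may be (P,) or (K, P)."""
    alts = np.atleast_2d(alts)
    N = depths.sum()
    A = alts.sum(axis=1, keepdims=True)
    e_alt = A * depths[None, :] / N
    e_ref = (N - A) * depths[None, :] / N
    refs = depths[None, :] - alts
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(e_alt > 0, (alts - e_alt) ** 2 / e_alt, 0.0).sum(axis=1)
        stat = stat + np.where(e_ref > 0, (refs - e_ref) ** 2 / e_ref, 0.0).sum(axis=1)
    return stat


def cross_pool_test(
    alt_counts: Sequence[int],
    depths: Sequence[int],
    seed: int = 0,
    max_exact_total_alt: int = 20,
    n_permutations: int = 10_000,
) -> float:
    """Homogeneity test of alt fractions across pools.

    Small p: alt reads concentrated in specific pools (variant-like).
    Large p: alt reads dispersed in proportion to depth (error-like).
    Pools with zero depth are dropped; with fewer than two informative
    pools the test is not applicable and ``nan`` is returned.  The
    Monte-Carlo branch is made invariant to pool ordering by sorting the
    margins canonically and keying its random stream off them.
    """
    alts = np.asarray(alt_counts, dtype=np.int64)
    deps = np.asarray(depths, dtype=np.int64)
    if (alts > deps).any():
        raise DataIntegrityError("alt count exceeds depth")
    keep = deps > 0
    alts, deps = alts[keep], deps[keep]
    if len(deps) < 2:
        return float("nan")
    total_alt = int(alts.sum())
    if total_alt == 0 or total_alt == int(deps.sum()):
        return 1.0
    # canonical pool order: invariance to relabeling
    order = np.lexsort((alts, deps))
    alts, deps = alts[order], deps[order]
    if total_alt <= max_exact_total_alt:
        return _exact_contingency_pvalue(alts, deps)
    label = "crosspool:" + ",".join(f"{d}.{a}" for d, a in zip(deps, alts))
    rng = substream(seed, label)
    obs = _chi2_stat(alts, deps)[0]
    perm = rng.multivariate_hypergeometric(deps, total_alt, size=n_permutations)
    stats_perm = _chi2_stat(perm, deps)
    p = (1.0 + (stats_perm >= obs - 1e-9).sum()) / (n_permutations + 1.0)
    return float(p)


# ---------------------------------------------------------------------------
# the caller


def _evidence_arrays(evidence):
    if isinstance(evidence, SiteCountsTable):
        t = evidence
        depths = t.depth
        alts = t.alt
        errs = t.mean_error_prob
        is_indel = np.array([vt != "SNV" for vt in t.var_types])
        meta = [
            (t.contig, int(t.positions[s]), t.ref_alleles[s], t.alt_alleles[s], t.var_types[s])
            for s in range(t.n_sites)
        ]
        return depths, alts, errs, is_indel, meta, None
    ev_list = list(evidence)
    depths = np.array([e.depths for e in ev_list], dtype=np.int64)
    alts = np.array([e.alt_counts for e in ev_list], dtype=np.int64)
    errs = np.array([e.mean_error_probs for e in ev_list], dtype=float)
    is_indel = np.array([e.var_type != "SNV" for e in ev_list])
    meta = [(e.contig, e.position, e.ref_allele, e.alt_allele, e.var_type) for e in ev_list]
    return depths, alts, errs, is_indel, meta, ev_list


def call_variants(
    evidence,
    design: PoolDesign,
    alpha_error: float = DEFAULT_ALPHA_ERROR,
    alpha_pool: float = DEFAULT_ALPHA_POOL,
    min_alt: int = DEFAULT_MIN_ALT,
    indel_error_rate: float = 1e-4,
    seed: int = 0,
    full_stats: bool = False,
) -> list[VariantCall]:
    """Call variants over an evidence stream (SiteEvidence list or counts table).

    A site is PASS iff its maximum per-pool alt count is >= ``min_alt``,
    its minimum per-pool error-test p-value is <= ``alpha_error``, and
    the cross-pool test is <= ``alpha_pool``, not applicable, or bypassed
    by the common-variant rescue rule (every informative pool clears the
    floor and the error test on its own).  Sites with no alt reads
    anywhere are not candidates and are not emitted; every candidate
    appears exactly once with a definite filter status.

    The cross-pool p-value is computed only where it can affect the
    decision unless ``full_stats`` is set (it is reported ``nan``
    elsewhere).  Output is deterministic given inputs and ``seed``.
    """
    depths, alts, errs, is_indel, meta, ev_list = _evidence_arrays(evidence)
    if depths.size == 0:
        return []
    if (alts > depths).any():
        raise DataIntegrityError("alt count exceeds depth")

    per_allele = np.where(is_indel[:, None], indel_error_rate, errs / 3.0)
    p_err = stats.binom.sf(alts - 1, depths, per_allele)
    p_err = np.where(alts == 0, 1.0, p_err)
    min_p_err = p_err.min(axis=1)
    max_alt = alts.max(axis=1)
    informative = depths > 0
    rescue = np.logical_and(
        informative.any(axis=1),
        np.logical_and(
            np.where(informative, alts >= min_alt, True).all(axis=1),
            np.where(informative, p_err <= alpha_error, True).all(axis=1),
        ),
    )

    calls: list[VariantCall] = []
    candidate = alts.sum(axis=1) > 0
    for s in np.nonzero(candidate)[0]:
        contig, pos, ref, alt, var_type = meta[s]
        p_pool = float("nan")
        if max_alt[s] < min_alt:
            status = "min_alt_fail"
            if full_stats:
                p_pool = cross_pool_test(alts[s], depths[s], seed=seed)
        elif min_p_err[s] > alpha_error and not full_stats:
            status = "stat_fail"
        else:
            p_pool = cross_pool_test(alts[s], depths[s], seed=seed)
            pool_ok = math.isnan(p_pool) or p_pool <= alpha_pool or bool(rescue[s])
            if min_p_err[s] <= alpha_error and pool_ok:
                status = "PASS"
            else:
                status = "stat_fail"
        if ev_list is not None:
            ev = ev_list[s]
        else:
            ev = SiteEvidence(
                contig=contig,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                depths=tuple(int(d) for d in depths[s]),
                alt_counts=tuple(int(a) for a in alts[s]),
                mean_error_probs=tuple(float(e) for e in errs[s]),
                var_type=var_type,
            )
        calls.append(
            VariantCall(
                evidence=ev,
                p_error=float(min_p_err[s]),
                p_error_per_pool=tuple(float(p) for p in p_err[s]),
                p_pool=p_pool,
                filter_status=status,
                var_type=var_type,
            )
        )
    return calls
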