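"""Per-site read evidence: pileup construction and quality filtering.

Bridges the read level (SAM-like records) and the count level the
caller consumes.  Reads with mapping quality below 20 and base calls
with quality below 10 are discarded (strict less-than: MAPQ 20 and BQ
10 are retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .caller import DEFAULT_BASEQ_MIN, DEFAULT_MAPQ_MIN, SiteEvidence
from .cigar import parse_cigar
from .simulate import SimulatedRead

__all__ = ["RawSiteObservations", "pileup_reads", "filter_read_evidence"]


@dataclass
class RawSiteObservations:
    """Unfiltered per-pool base observations at one reference position."""

    contig: str
    position: int                       # 1-based
    ref_allele: str
    bases: list[list[str]]              # [pool][read]
    base_quals: list[list[int]]
    map_quals: list[list[int]]

    @property
    def n_pools(self) -> int:
        return len(self.bases)


def pileup_reads(
    reads_per_pool: Sequence[Sequence[SimulatedRead]],
    reference: str,
    contig: str = "ref",
) -> list[RawSiteObservations]:
    """Column-wise pileup of aligned reads over the reference.

    Walks each read's CIGAR; M bases contribute to their reference
    column, insertions and soft clips consume query only, deletions
    consume reference only.  Returns one record per covered position,
    sorted by position.
    """
    P = len(reads_per_pool)
    columns: dict[int, RawSiteObservations] = {}
    for pool_id, reads in enumerate(reads_per_pool):
        for read in reads:
            rpos = read.start
            qpos = 0
            for op, n in parse_cigar(read.cigar):
                if op == "M":
                    for i in range(n):
                        pos = rpos + i
                        if not 1 <= pos <= len(reference):
                            continue
                        col = columns.get(pos)
                        if col is None:
                            col = RawSiteObservations(
                                contig=contig,
                                position=pos,
                                ref_allele=reference[pos - 1],
                                bases=[[] for _ in range(P)],
                                base_quals=[[] for _ in range(P)],
                                map_quals=[[] for _ in range(P)],
                            )
                            columns[pos] = col
                        col.bases[pool_id].append(read.sequence[qpos + i])
                        col.base_quals[pool_id].append(int(read.base_qualities[qpos + i]))
                        col.map_quals[pool_id].append(read.mapping_quality)
                    rpos += n
                    qpos += n
                elif op in "IS":
                    qpos += n
                elif op == "D":
                    rpos += n
    return [columns[pos] for pos in sorted(columns)]


def filter_read_evidence(
    observations: RawSiteObservations,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    baseq_min: int = DEFAULT_BASEQ_MIN,
) -> list[SiteEvidence]:
    """Apply the quality filters and recompute counts.

    Reads with MAPQ < ``mapq_min`` and bases with quality < ``baseq_min``
    are discarded; the discarded tally per pool is recorded.  One
    :class:`SiteEvidence` is returned per distinct non-reference allele
    that survives filtering (most-supported first); an unevaluable site
    (no retained non-reference base, or no retained depth) yields an
    empty list.
    """
    P = observations.n_pools
    depths = np.zeros(P, dtype=int)
    discarded = np.zeros(P, dtype=int)
    mean_err = np.zeros(P)
    allele_counts: dict[str, np.ndarray] = {}
    for p in range(P):
        errs = []
        for base, bq, mq in zip(
            observations.bases[p], observations.base_quals[p], observations.map_quals[p]
        ):
            if mq < mapq_min or bq < baseq_min:
                discarded[p] += 1
                continue
            depths[p] += 1
            errs.append(10.0 ** (-bq / 10.0))
            counts = allele_counts.setdefault(base, np.zeros(P, dtype=int))
            counts[p] += 1
        mean_err[p] = float(np.mean(errs)) if errs else 1e-10
    mean_err = np.maximum(mean_err, 1e-10)

    ref = observations.ref_allele
    alts = sorted(
        (a for a in allele_counts if a != ref),
        key=lambda a: (-int(allele_counts[a].sum()), a),
    )
    return [
        SiteEvidence(
            contig=observations.contig,
            position=observations.position,
            ref_allele=ref,
            alt_allele=alt,
            depths=tuple(int(d) for d in depths),
            alt_counts=tuple(int(c) for c in allele_counts[alt]),
            mean_error_probs=tuple(float(e) for e in mean_err),
            var_type="SNV",
            discarded=tuple(int(d) for d in discarded),
        )
        for alt in alts
    ]
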