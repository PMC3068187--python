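"""Indel-sensitive gapless realignment.

Independent per-read aligners cannot place a gap near the ends of a
short read; an indel-spanning read then gets forced into a gapless
alignment whose tail is pure mismatch, which later surfaces as false
SNVs.  The remedy implemented here:

1. collect candidate indels from the gapped alignments that *were*
   recovered (``collect_candidate_indels``), left-normalizing so
   shift-equivalent representations collapse;
2. build one alternate ("indel-sensitive") reference window per
   candidate with the indel applied (``build_alt_reference``);
3. realign every read *gaplessly* against each overlapping alternate
   window and replace its alignment only when the new score is strictly
   better than the original's (``realign_read``) — ties keep the
   original alignment.

Scoring is a fixed quality-blind match/mismatch scheme.  Insertion
bases of a gapped alignment score as matches (they are exactly what the
indel haplotype explains), so a correctly gapped alignment ties its
gapless equivalent on the alternate reference and is never churned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cigar import parse_cigar, reference_length
from .simulate import SimulatedRead

__all__ = [
    "CandidateIndel",
    "AltReference",
    "ScoringScheme",
    "left_normalize",
    "score_alignment",
    "collect_candidate_indels",
    "build_alt_reference",
    "realign_read",
    "apply_realignment",
]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -3


@dataclass(frozen=True)
class CandidateIndel:
    """A left-normalized indel candidate observed in gapped alignments."""

    contig: str
    position: int          # 1-based anchor base
    ref_allele: str
    alt_allele: str
    supporting_read_count: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("identity 'indel' (ref == alt) is not a candidate")
        if self.supporting_read_count < 1:
            raise ValueError("supporting_read_count must be >= 1")

    @property
    def is_deletion(self) -> bool:
        return len(self.ref_allele) > len(self.alt_allele)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))


def left_normalize(
    reference: str, position: int, ref_allele: str, alt_allele: str
) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent VCF representation.

    ``position`` is 1-based; alleles carry the anchor base.  The standard
    normalization: trim shared trailing bases (extending left through the
    reference when an allele would become empty), then trim shared
    leading bases.
    """
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    pos = position
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                prev = reference[pos - 2].upper()
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            else:
                ref, alt = ref[:-1], alt[:-1]
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def score_alignment(
    read: SimulatedRead, reference: str, scoring: ScoringScheme = ScoringScheme()
) -> int:
    """Score a read's current alignment against the original reference.

    M bases score match/mismatch; insertion bases score as matches
    (consistent with an indel haplotype); deletions score 0.  Bases
    aligned outside the reference count as mismatches.
    """
    matches = 0
    mismatches = 0
    rpos = read.start
    qpos = 0
    for op, n in parse_cigar(read.cigar):
        if op == "M":
            for i in range(n):
                if 1 <= rpos + i <= len(reference) and (
                    reference[rpos + i - 1] == read.sequence[qpos + i]
                ):
                    matches += 1
                else:
                    mismatches += 1
            rpos += n
            qpos += n
        elif op == "I":
            matches += n
            qpos += n
        elif op == "D":
            rpos += n
        elif op == "S":
            qpos += n
    return scoring.match * matches + scoring.mismatch * mismatches


def collect_candidate_indels(
    reads: Sequence[SimulatedRead],
    reference: str,
    min_support: int = 2,
    contig: str | None = None,
) -> list[CandidateIndel]:
    """Distinct left-normalized indels seen in gapped alignments.

    One candidate per (position, ref, alt) with support >= ``min_support``,
    sorted by position then alleles.
    """
    counts: dict[tuple[str, int, str, str], int] = {}
    for read in reads:
        rpos = read.start
        qpos = 0
        for op, n in parse_cigar(read.cigar):
            if op == "M":
                rpos += n
                qpos += n
            elif op == "S":
                qpos += n
            elif op == "D":
                anchor = rpos - 1
                if anchor >= 1 and rpos + n - 1 <= len(reference):
                    ref = reference[anchor - 1 : rpos + n - 1]
                    alt = reference[anchor - 1]
                    key_pos, key_ref, key_alt = left_normalize(reference, anchor, ref, alt)
                    key = (read.contig, key_pos, key_ref, key_alt)
                    counts[key] = counts.get(key, 0) + 1
                rpos += n
            elif op == "I":
                anchor = rpos - 1
                if anchor >= 1:
                    inserted = read.sequence[qpos : qpos + n]
                    ref = reference[anchor - 1]
                    alt = ref + inserted
                    key_pos, key_ref, key_alt = left_normalize(reference, anchor, ref, alt)
                    key = (read.contig, key_pos, key_ref, key_alt)
                    counts[key] = counts.get(key, 0) + 1
                qpos += n
    out = [
        CandidateIndel(
            contig=contig if contig is not None else c,
            position=p,
            ref_allele=r,
            alt_allele=a,
            supporting_read_count=n,
        )
        for (c, p, r, a), n in counts.items()
        if n >= min_support
    ]
    out.sort(key=lambda ci: (ci.contig, ci.position, ci.ref_allele, ci.alt_allele))
    return out


@dataclass(frozen=True)
class AltReference:
    """A reference window with one candidate indel applied.

    ``window_start``/``window_end`` are 1-based inclusive coordinates on
    the original reference; ``sequence`` is the window with the indel
    applied.  ``offset_to_ref`` maps a 0-based offset in ``sequence``
    back to a 1-based reference position (None for inserted bases).
    """

    contig: str
    window_start: int
    window_end: int
    sequence: str
    source_indel: CandidateIndel

    @property
    def _pre_len(self) -> int:
        # window bases up to and including the indel anchor
        return self.source_indel.position - self.window_start + 1

    def offset_to_ref(self, offset: int) -> int | None:
        indel = self.source_indel
        pre = self._pre_len
        if offset < pre:
            return self.window_start + offset
        if indel.is_deletion:
            return self.window_start + offset + indel.indel_length
        # insertion
        if offset < pre + indel.indel_length:
            return None
        return self.window_start + offset - indel.indel_length

    def overlaps(self, start: int, end: int) -> bool:
        return not (end < self.window_start or start > self.window_end)


class CoordinateError(ValueError):
    """Raised when an indel does not fit the reference it is applied to."""


def build_alt_reference(
    reference: str,
    indel: CandidateIndel,
    flank: int = 55,
) -> AltReference:
    """Apply one candidate indel to a flank-bounded reference window."""
    p = indel.position
    span_end = p + len(indel.ref_allele) - 1
    if not (1 <= p and span_end <= len(reference)):
        raise CoordinateError(f"indel at {p} outside reference of length {len(reference)}")
    if reference[p - 1 : span_end].upper() != indel.ref_allele.upper():
        raise CoordinateError(
            f"ref allele {indel.ref_allele!r} does not match reference at {p}"
        )
    ws = max(1, p - flank)
    we = min(len(reference), span_end + flank)
    left = reference[ws - 1 : p]                # up to and including anchor
    right = reference[span_end:we]              # after the ref allele span
    if indel.is_deletion:
        seq = left + right
    else:
        seq = left + indel.alt_allele[1:] + reference[p:we]
    return AltReference(
        contig=indel.contig,
        window_start=ws,
        window_end=we,
        sequence=seq,
        source_indel=indel,
    )


def _gapless_scores(window: str, read_seq: str, scoring: ScoringScheme) -> np.ndarray:
    """Score of every gapless placement of the read within the window."""
    L = len(read_seq)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    r = np.frombuffer(read_seq.encode(), dtype=np.uint8)
    if len(w) < L:
        return np.empty(0, dtype=np.int64)
    views = np.lib.stride_tricks.sliding_window_view(w, L)
    mism = (views != r).sum(axis=1)
    return scoring.match * (L - mism) + scoring.mismatch * mism


def _mapped_back_alignment(
    alt_ref: AltReference, offset: int, read_len: int
) -> tuple[int, str] | None:
    """Translate a gapless alt-window placement into (start, CIGAR) on the
    original reference.  Returns None when the placement starts inside
    inserted bases (not representable as an alignment)."""
    ops: list[tuple[str, int]] = []
    start = None
    prev = None
    for i in range(read_len):
        rpos = alt_ref.offset_to_ref(offset + i)
        if rpos is None:
            op = "I"
        else:
            if start is None:
                start = rpos
            if prev is not None and rpos > prev + 1:
                ops.append(("D", rpos - prev - 1))
            prev = rpos
            op = "M"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if start is None or ops[0][0] == "I":
        return None
    # trailing insertions are representable; keep them
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return start, cigar


def realign_read(
    read: SimulatedRead,
    alt_refs: Sequence[AltReference],
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
) -> SimulatedRead:
    """Gaplessly realign one read against the alternate references.

    Every gapless placement of the read on every overlapping alternate
    window is scored; if the best is *strictly* better than the score of
    the read's current alignment, the alignment is replaced (mapped back
    through the window's coordinate map, so it now carries the indel
    implicitly).  Ties and non-overlapping reads leave the read unchanged.
    """
    span = reference_length(read.cigar)
    read_end = read.start + max(span, 1) - 1
    orig_score = score_alignment(read, reference, scoring)
    best_score = orig_score
    best: tuple[int, str] | None = None
    L = len(read.sequence)
    for alt_ref in alt_refs:
        if not alt_ref.overlaps(read.start, read_end):
            continue
        scores = _gapless_scores(alt_ref.sequence, read.sequence, scoring)
        if scores.size == 0:
            continue
        # examine offsets best-first so the leftmost best valid placement wins
        order = np.argsort(-scores, kind="stable")
        for off in order:
            if scores[off] <= best_score:
                break
            mapped = _mapped_back_alignment(alt_ref, int(off), L)
            if mapped is None:
                continue
            best_score = int(scores[off])
            best = mapped
            break
    if best is None:
        return read
    start, cigar = best
    return replace(read, start=start, cigar=cigar, is_original_alignment=False)


def apply_realignment(
    reads: Sequence[SimulatedRead],
    alt_refs: Sequence[AltReference],
    reference: str,
    scoring: ScoringScheme = ScoringScheme(),
) -> tuple[list[SimulatedRead], float]:
    """Realign every read; return (updated reads, fraction changed)."""
    out: list[SimulatedRead] = []
    changed = 0
    for read in reads:
        new = realign_read(read, alt_refs, reference, scoring)
        if (new.start, new.cigar) != (read.start, read.cigar):
            changed += 1
        out.append(new)
    frac = changed / len(reads) if reads else 0.0
    return out, frac
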