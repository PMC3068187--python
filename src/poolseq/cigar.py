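"""Minimal CIGAR handling for SAM-like read records.

Supported operations: M (alignment match), I (insertion to the
reference), D (deletion from the reference), S (soft clip).
"""

from __future__ import annotations

import re

_CIGAR_RE = re.compile(r"(\d+)([MIDS])")

__all__ = ["parse_cigar", "query_length", "reference_length", "has_gap"]


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


def query_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MIS")


def reference_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MD")


def has_gap(cigar: str) -> bool:
    return any(op in "ID" for op, _ in parse_cigar(cigar))
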