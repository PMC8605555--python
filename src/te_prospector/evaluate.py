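"""Truth-matching helpers for synthetic-genome benchmarking."""

from __future__ import annotations

from typing import Sequence

from .seqio import Interval
from .synthetic import TruthRecord


def boundary_error(detected: Interval, truth: Interval) -> int:
    return max(abs(detected.start - truth.start), abs(detected.end - truth.end))


def recall(
    truth: Sequence[TruthRecord],
    detected: Sequence[Interval],
    kind: str | None = None,
    max_boundary_error: int = 10,
) -> tuple[int, int]:
    """(recovered, total) planted elements matched by a detected interval
    within ``max_boundary_error`` bp at both ends."""
    records = [t for t in truth if kind is None or t.element_kind == kind]
    hit = 0
    for t in records:
        if any(
            d.seq_id == t.interval.seq_id and boundary_error(d, t.interval) <= max_boundary_error
            for d in detected
        ):
            hit += 1
    return hit, len(records)


def overlap_recall(
    truth: Sequence[TruthRecord],
    detected: Sequence[Interval],
    kind: str | None = None,
    min_overlap: float = 0.5,
) -> tuple[int, int]:
    """(recovered, total) planted elements covered >= ``min_overlap`` of
    their length by a single detected interval."""
    records = [t for t in truth if kind is None or t.element_kind == kind]
    hit = 0
    for t in records:
        for d in detected:
            if d.seq_id != t.interval.seq_id:
                continue
            ov = min(d.end, t.interval.end) - max(d.start, t.interval.start)
            if ov >= min_overlap * t.interval.length:
                hit += 1
                break
    return hit, len(records)
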