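"""Shared affine-gap pairwise alignment core.

A thin deterministic wrapper around :class:`Bio.Align.PairwiseAligner` with
the scoring scheme used throughout the toolkit: match +2, mismatch -3,
gap open -5, gap extend -2.  All callers (family clustering, homology
filtering, library masking) share this one scheme so score cutoffs keep a
single meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise alignment: gapped strings plus summary statistics.

    ``identity`` is matches over aligned columns (end gaps excluded in global
    mode); ``aligned_length`` counts those columns.  ``a_range``/``b_range``
    give the half-open spans of each input covered by the alignment.
    """

    a_aligned: str
    b_aligned: str
    score: float
    identity: float
    aligned_length: int
    a_range: tuple[int, int]
    b_range: tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(mode: str, match: int, mismatch: int, open_gap: int, extend_gap: int):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def align_score(a: str, b: str, mode: str = "local") -> float:
    """Alignment score only (no traceback); local scores floor at 0."""
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    return _aligner(mode, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND).score(a, b)


def align_pair(a: str, b: str, mode: str = "global") -> PairwiseResult:
    """Affine-gap alignment of two sequences.

    Global mode is Needleman-Wunsch with penalized end gaps; identity and
    aligned length exclude end-gap columns.  Local mode is Smith-Waterman;
    a best score of 0 yields an empty alignment rather than an error.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    aligner = _aligner(mode, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    alignments = aligner.align(a, b)
    try:
        aln = alignments[0]
    except IndexError:  # local mode with no positive-scoring alignment
        return PairwiseResult("", "", 0.0, 0.0, 0, (0, 0), (0, 0))
    score = aln.score
    if mode == "local" and score <= 0:
        return PairwiseResult("", "", 0.0, 0.0, 0, (0, 0), (0, 0))
    a_gapped, b_gapped = str(aln[0]), str(aln[1])
    # Trim end-gap columns (boundary columns where one side is gapped).
    start, end = 0, len(a_gapped)
    while start < end and (a_gapped[start] == "-" or b_gapped[start] == "-"):
        start += 1
    while end > start and (a_gapped[end - 1] == "-" or b_gapped[end - 1] == "-"):
        end -= 1
    core_a, core_b = a_gapped[start:end], b_gapped[start:end]
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    cols = len(core_a)
    identity = matches / cols if cols else 0.0
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a):
        a_range = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
        b_range = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    else:  # pragma: no cover - degenerate traceback
        a_range, b_range = (0, 0), (0, 0)
    return PairwiseResult(core_a, core_b, float(score), identity, cols, a_range, b_range)
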