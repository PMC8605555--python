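"""Structure-based discovery of full-length LTR retrotransposons.

A full-length LTR-RT is a pair of near-identical direct repeats (the LTRs)
separated by an internal region, flanked by a short exact target-site
duplication (TSD).  Discovery is seed-and-extend: exact ``seed_k``-mer
matches on the same strand whose spacing falls between the minimum repeat
distance and the maximum element length are chained by diagonal, extended
ungapped with an X-drop, then refined by global affine alignment of the two
repeat arms.  Candidates must meet LTR length and identity bounds and carry
an exact TSD of 4-6 bp within a small window of both element ends.

Structural candidates are then annotated internally (stop-to-stop ORFs of
>= 100 aa, scored against domain profiles) and screened for homology against
a labeled repeat library: candidates without a sufficiently scoring local
alignment to any library entry of order LTR are discarded as false
positives, and the survivors take the superfamily of their best hit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .align import align_pair, align_score
from .library import RepeatLibrary
from .nonltr_detect import ProfileHit, ScoringProfile, score_profile
from .orfs import Orf, find_orfs
from .seqio import GenomeSequence, Interval, reverse_complement


@dataclass(frozen=True)
class LtrSearchConfig:
    """Structural search bounds; defaults follow the published defaults of
    the LTRharvest tool family (identity floor 0.85, TSD 4-6 bp) with the
    element-length ceiling sized to the largest observed full-length span."""

    min_ltr_len: int = 100
    max_ltr_len: int = 3500
    min_internal_distance: int = 1000
    max_element_len: int = 25500
    min_ltr_identity: float = 0.85
    tsd_len_range: tuple[int, int] = (4, 6)
    tsd_search_window: int = 10
    seed_k: int = 20
    max_seed_gap: int = 500
    min_orf_aa: int = 100

    def __post_init__(self) -> None:
        if self.min_ltr_len >= self.max_ltr_len:
            raise ValueError("min_ltr_len must be < max_ltr_len")
        if self.min_internal_distance < 0:
            raise ValueError("min_internal_distance must be >= 0")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass(frozen=True)
class LtrElement:
    """A full-length LTR-RT candidate with paired repeats and TSDs."""

    element: Interval
    ltr5: Interval
    ltr3: Interval
    ltr_identity: float
    tsd: tuple[str, str] | None = None
    internal_orfs: tuple[Orf, ...] = ()
    domain_hits: tuple[tuple[str, float], ...] = ()
    classification: str = "UNFILTERED"
    classification_score: float = 0.0
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.ltr5.end > self.ltr3.start:
            raise ValueError("5' LTR must end before the 3' LTR starts")
        if self.tsd is not None and self.tsd[0] != self.tsd[1]:
            raise ValueError("TSD copies must be identical")

    @property
    def length(self) -> int:
        return self.element.length


def _xdrop_extend(seq: str, i: int, j: int, direction: int, limit: int, xdrop: int = 20) -> int:
    """Ungapped extension of positions (i + t*dir, j + t*dir); returns the
    offset (in steps) of the best-scoring extension end."""
    score = best = 0
    best_t = 0
    t = 1
    n = len(seq)
    while t <= limit:
        a, b = i + direction * t, j + direction * t
        if not (0 <= a < n and 0 <= b < n):
            break
        x, y = seq[a], seq[b]
        if x == "N" or y == "N":
            break
        score += 1 if x == y else -2
        if score > best:
            best, best_t = score, t
        if best - score >= xdrop:
            break
        t += 1
    return best_t


def _find_tsd(
    seq: str, start: int, end: int, config: LtrSearchConfig
) -> tuple[str, int, int] | None:
    """Exact direct repeat of tsd length within the search window of both
    element ends (inward or outward); longest first, then the placement
    closest to the detected boundaries.  Returns the TSD sequence and the
    implied element start/end (boundaries adjusted onto the duplication)."""
    lo, hi = config.tsd_len_range
    w = config.tsd_search_window
    for tsd_len in range(hi, lo - 1, -1):
        best: tuple[int, int, int, str] | None = None  # (cost, new_start, new_end, tsd)
        for left_shift in range(-w, w + 1):
            # implied element start: the base right after the left TSD copy
            new_start = start + left_shift
            ls = new_start - tsd_len
            if ls < 0:
                continue
            left = seq[ls:new_start]
            if "N" in left:
                continue
            for right_shift in range(-w, w + 1):
                new_end = end + right_shift
                if new_end + tsd_len > len(seq) or new_end <= new_start:
                    continue
                if seq[new_end : new_end + tsd_len] == left:
                    cost = abs(left_shift) + abs(right_shift)
                    if best is None or cost < best[0]:
                        best = (cost, new_start, new_end, left)
        if best is not None:
            return best[3], best[1], best[2]
    return None


def find_ltr_candidates(genome: GenomeSequence, config: LtrSearchConfig | None = None) -> list[LtrElement]:
    """Seed, chain and extend direct-repeat pairs into LTR-RT candidates.

    Candidates are reported left-to-right and non-self-overlapping;
    overlaps resolve to the higher LTR identity, then the longer element.
    N runs never seed or extend.
    """
    config = config or LtrSearchConfig()
    seq = genome.residues
    k = config.seed_k
    n = len(seq)
    if n < 2 * config.min_ltr_len + config.min_internal_distance:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    # seed pairs grouped by diagonal (spacing between repeat copies)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                spacing = positions[b] - positions[a]
                if config.min_internal_distance <= spacing <= config.max_element_len:
                    diagonals[spacing].append(positions[a])
    candidates: list[LtrElement] = []
    for spacing, starts in sorted(diagonals.items()):
        starts.sort()
        # chain seeds on one diagonal into runs no longer than an LTR,
        # splitting at seed gaps too wide to lie within one repeat arm
        runs: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - runs[-1][0] <= config.max_ltr_len and s - runs[-1][-1] <= config.max_seed_gap:
                runs[-1].append(s)
            else:
                runs.append([s])
        for run in runs:
            a0, a1 = run[0], run[-1] + k  # 5' arm seed span
            left = _xdrop_extend(seq, a0, a0 + spacing, -1, config.max_ltr_len)
            right = _xdrop_extend(seq, a1 - 1, a1 - 1 + spacing, +1, config.max_ltr_len)
            s5, e5 = a0 - left, a1 + right
            s3, e3 = s5 + spacing, e5 + spacing
            ltr_len = e5 - s5
            if not config.min_ltr_len <= ltr_len <= config.max_ltr_len:
                continue
            if e5 > s3:  # arms overlap: repeats too close for this LTR size
                continue
            if e3 - s5 > config.max_element_len or e3 > n:
                continue
            tsd_hit = _find_tsd(seq, s5, e3, config)
            if tsd_hit is None:
                continue
            tsd, new_start, new_end = tsd_hit
            # pin the element onto the duplication and derive both repeat
            # arms from the pinned bounds and the seed diagonal: X-drop
            # extension alone truncates divergent arm ends, which would
            # condition the arm pair on local conservation and bias the
            # divergence (hence age) estimate downward
            s5b, e3b = new_start, new_end
            s3b = s5b + spacing
            arm_len = e3b - s3b
            e5b = s5b + arm_len
            if not (
                config.min_ltr_len <= arm_len <= config.max_ltr_len
                and s5b < e5b <= s3b < e3b
            ):
                continue
            res = align_pair(seq[s5b:e5b], seq[s3b:e3b], mode="global")
            if res.identity < config.min_ltr_identity:
                continue
            candidates.append(
                LtrElement(
                    element=Interval(genome.id, s5b, e3b),
                    ltr5=Interval(genome.id, s5b, e5b),
                    ltr3=Interval(genome.id, s3b, e3b),
                    ltr_identity=res.identity,
                    tsd=(tsd, tsd),
                )
            )
    return _resolve_overlaps(candidates)


def _resolve_overlaps(candidates: list[LtrElement]) -> list[LtrElement]:
    """Non-overlapping candidate set: chimeric spans that fully contain a
    smaller candidate are dropped first (a direct-repeat pair bridging two
    family copies always swallows at least one genuine candidate), then
    overlaps resolve to the higher LTR identity, then the longer element."""
    def contains(outer: LtrElement, inner: LtrElement) -> bool:
        return (
            outer.length > inner.length
            and outer.element.start <= inner.element.start
            and inner.element.end <= outer.element.end
        )

    pruned = [c for c in candidates if not any(contains(c, other) for other in candidates)]
    ranked = sorted(pruned, key=lambda c: (-c.ltr_identity, -c.length, c.element.start))
    kept: list[LtrElement] = []
    for cand in ranked:
        if not any(cand.element.overlaps(k.element) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.element.start)
    return kept


def annotate_internal(
    element: LtrElement,
    genome: GenomeSequence,
    profiles: Mapping[str, ScoringProfile],
    min_orf_aa: int = 100,
) -> LtrElement:
    """Record internal ORFs (>= min_orf_aa, all six frames) and their domain
    profile hits.  An internal region shorter than one minimal ORF yields an
    element with an empty ORF list."""
    start, end = element.ltr5.end, element.ltr3.start
    if end - start < 3 * min_orf_aa:
        return replace(element, internal_orfs=(), domain_hits=())
    internal = genome.residues[start:end]
    orfs = tuple(find_orfs(internal, genome.id, min_aa=min_orf_aa, offset=start))
    hits: list[tuple[str, float]] = []
    for orf in orfs:
        for name in sorted(profiles):
            prof = profiles[name]
            hit = score_profile(orf.protein, prof)
            if hit.offset is not None and hit.score >= prof.threshold:
                hits.append((name, float(hit.score)))
    return replace(element, internal_orfs=orfs, domain_hits=tuple(hits))


def filter_and_classify(
    candidates: Sequence[LtrElement],
    genome: GenomeSequence,
    library: RepeatLibrary,
    min_hit_score: float = 100.0,
) -> list[LtrElement]:
    """Homology screen against library entries of order LTR (both strands).

    Candidates whose best local-alignment score falls below
    ``min_hit_score`` are discarded as false positives; the rest take the
    superfamily of the highest-scoring entry (ties: longer alignment, then
    lexicographic library id).
    """
    ltr_entries = [e for e in library.entries if e.order == "LTR"]
    if not ltr_entries:
        raise ValueError("homology filtering requires a non-empty LTR library")
    retained: list[LtrElement] = []
    for cand in candidates:
        seq = genome.residues[cand.element.start : cand.element.end]
        best: tuple[float, int, str] | None = None  # (score, aligned_len, entry id)
        best_superfamily = ""
        for entry in ltr_entries:
            for target in (entry.sequence, reverse_complement(entry.sequence)):
                score = align_score(seq, target, mode="local")
                if score < (best[0] if best else min_hit_score):
                    continue
                res = align_pair(seq, target, mode="local")
                key = (res.score, res.aligned_length, entry.id)
                if (
                    best is None
                    or res.score > best[0]
                    or (res.score == best[0] and res.aligned_length > best[1])
                    or (
                        res.score == best[0]
                        and res.aligned_length == best[1]
                        and entry.id < best[2]
                    )
                ):
                    best = (res.score, res.aligned_length, entry.id)
                    best_superfamily = entry.superfamily
        if best is not None and best[0] >= min_hit_score:
            retained.append(
                replace(cand, classification=best_superfamily, classification_score=best[0])
            )
    return retained
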