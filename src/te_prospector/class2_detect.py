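"""Class II element detection: MITEs and Helitrons.

MITEs are short (50-800 bp) non-autonomous elements bounded by a terminal
inverted repeat (TIR) pair and an exact target-site duplication of 2, 3, 8
or 10 bp.  Detection is k-mer seeded: every k-mer whose reverse complement
occurs downstream within the element-length window seeds a TIR pair, arms
are extended allowing a bounded mismatch fraction, and candidates are kept
when the TSD is present and the confidence score
``tir_identity * min(1, tir_len / 15)`` reaches the threshold.

Helitrons transpose by rolling-circle replication and leave no TSD; their
canonical termini are a 5' TC dinucleotide (host A immediately upstream)
and a 3' CTRR (R = A or G, host T immediately downstream) preceded by a
short palindromic hairpin.  Each terminus is scored additively over those
features with integer weights and a threshold of 6 per terminus; 5'/3' hits
are then paired into elements and clustered greedily at 80 % identity.
Because the bare terminal features are information-poor, pairing is
anchored on a short 5' terminal consensus motif (a stand-in for a trained
family head; user-overridable in config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .align import align_pair
from .library import RepeatLibrary
from .seqio import GenomeSequence, Interval, TeAnnotation, reverse_complement

MITE_TSD_LENGTHS = (2, 3, 8, 10)
DEFAULT_FIVE_PRIME_MOTIF = "TCTCTACTATGC"


# ---------------------------------------------------------------------------
# MITEs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MiteConfig:
    seed_k: int = 9
    min_tir_len: int = 10
    min_element_len: int = 50
    canonical_max_len: int = 650
    max_element_len: int = 800
    tsd_lengths: tuple[int, ...] = MITE_TSD_LENGTHS
    max_tir_mismatch_fraction: float = 0.2
    confidence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.min_element_len < self.canonical_max_len <= self.max_element_len:
            raise ValueError("need min_element_len < canonical_max_len <= max_element_len")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")


@dataclass(frozen=True)
class MiteCandidate:
    element: Interval
    tir5: Interval
    tir3: Interval
    tir_identity: float
    tsd: str
    confidence: float
    canonical: bool  # length within the 50-650 bp canonical window
    family_id: str | None = None

    @property
    def tir_len(self) -> int:
        return self.tir5.length


def mite_confidence(tir_identity: float, tir_len: int) -> float:
    """Confidence = TIR identity saturating-scaled by TIR length / 15."""
    return tir_identity * min(1.0, tir_len / 15.0)


def _extend_tir(seq: str, s5: int, e5: int, s3: int, e3: int, max_mm_frac: float, bound5: int, bound3: int):
    """Grow the TIR arms inward from the seed while the mismatch fraction
    stays within budget, keeping the extension that maximizes the
    confidence score (arms always end on a matching base).  tir5 extends
    right, tir3 extends left (forward coordinates).
    Returns (e5, s3, mismatches)."""
    mismatches = 0
    length = e5 - s5
    best = (e5, s3, 0, length)
    best_conf = mite_confidence(1.0, length)
    while e5 < bound5 and s3 > bound3:
        a, b = seq[e5], seq[s3 - 1]
        if a == "N" or b == "N":
            break
        mm = mismatches + (0 if a == reverse_complement(b) else 1)
        length += 1
        if mm / length > max_mm_frac:
            break
        e5 += 1
        s3 -= 1
        mismatches = mm
        if a == reverse_complement(b):
            conf = mite_confidence(1.0 - mm / length, length)
            if conf > best_conf:
                best = (e5, s3, mismatches, length)
                best_conf = conf
    return best


def _tir_mismatches(seq: str, s5: int, e5: int, s3: int, e3: int) -> int:
    arm5 = seq[s5:e5]
    arm3_rc = reverse_complement(seq[s3:e3])
    return sum(1 for a, b in zip(arm5, arm3_rc) if a != b)


def find_mites(genome: GenomeSequence, config: MiteConfig | None = None) -> list[MiteCandidate]:
    """K-mer seeded inverted-repeat search with exact-TSD validation.

    Candidates are deduplicated per locus (highest confidence wins) and
    reported left-to-right, non-overlapping.
    """
    config = config or MiteConfig()
    seq = genome.residues
    n = len(seq)
    k = config.seed_k
    from collections import defaultdict

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    candidates: list[MiteCandidate] = []
    seen_spans: set[tuple[int, int]] = set()
    for kmer, positions in index.items():
        rc = reverse_complement(kmer)
        partners = index.get(rc)
        if not partners:
            continue
        for i in positions:
            for j in partners:
                # element would span [i, j + k); the rc k-mer is the 3' arm seed
                span = j + k - i
                if span < max(config.min_element_len, 2 * k) or span > config.max_element_len:
                    continue
                s5, e5 = i, i + k
                s3, e3 = j, j + k
                if e5 > s3:  # arms overlap
                    continue
                mid = s3 - ((s3 - e5) // 2)
                e5x, s3x, mism, _ = _extend_tir(
                    seq, s5, e5, s3, e3, config.max_tir_mismatch_fraction, mid, mid
                )
                tir_len = e5x - s5
                if tir_len < config.min_tir_len:
                    continue
                start, end = s5, e3
                if (start, end) in seen_spans:
                    continue
                tsd = None
                for L in sorted(config.tsd_lengths, reverse=True):
                    if start - L < 0 or end + L > n:
                        continue
                    left = seq[start - L : start]
                    if "N" not in left and left == seq[end : end + L]:
                        tsd = left
                        break
                if tsd is None:
                    continue
                identity = 1.0 - mism / tir_len
                conf = mite_confidence(identity, tir_len)
                if conf < config.confidence_threshold:
                    continue
                seen_spans.add((start, end))
                candidates.append(
                    MiteCandidate(
                        element=Interval(genome.id, start, end),
                        tir5=Interval(genome.id, s5, e5x),
                        tir3=Interval(genome.id, s3x, e3),
                        tir_identity=identity,
                        tsd=tsd,
                        confidence=conf,
                        canonical=config.min_element_len
                        <= end - start
                        <= config.canonical_max_len,
                    )
                )
    # per-locus resolution: highest confidence, then longest TIR, then leftmost
    candidates.sort(key=lambda c: (-c.confidence, -c.tir_len, c.element.start))
    kept: list[MiteCandidate] = []
    for cand in candidates:
        if not any(cand.element.overlaps(k2.element) for k2 in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.element.start)
    return kept


def cluster_mite_families(
    candidates: Sequence[MiteCandidate],
    genome: GenomeSequence,
    library: RepeatLibrary | None = None,
) -> tuple[list[MiteCandidate], dict[str, MiteCandidate]]:
    """Group candidates into families (80-80-80 components) and pick one
    representative per family: the member with the best local-alignment
    score against the library, or the longest member (ties: lexicographic
    candidate index) without one."""
    from .evodynamics import cluster_80_80_80

    if not candidates:
        return [], {}
    seqs = {
        str(i): genome.residues[c.element.start : c.element.end]
        for i, c in enumerate(candidates)
    }
    clusters, singletons = cluster_80_80_80(seqs)
    groups = clusters + [[s] for s in singletons]
    groups.sort(key=lambda g: int(g[0]))
    labeled: list[MiteCandidate] = [*candidates]
    representatives: dict[str, MiteCandidate] = {}
    for fam_idx, members in enumerate(groups):
        fam_id = f"MITE_family_{fam_idx}"
        best_key = None
        best_member = None
        for m in members:
            cand = candidates[int(m)]
            labeled[int(m)] = replace(cand, family_id=fam_id)
            if library is not None and len(library) > 0:
                score = max(
                    align_pair(seqs[m], entry.sequence, mode="local").score
                    for entry in library
                )
                key = (score, cand.element.length, -int(m))
            else:
                key = (cand.element.length, -int(m))
            if best_key is None or key > best_key:
                best_key, best_member = key, m
        representatives[fam_id] = labeled[int(best_member)]
    return labeled, representatives


# ---------------------------------------------------------------------------
# Helitrons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HelitronConfig:
    """Terminal-signature weights and structural bounds.

    Scores: 5' = w_tc*[TC at start] + w_flank_a*[A at -1];
    3' = w_ctrr*[CTRR at end] + w_flank_t*[T at +1] + w_hairpin*[hairpin
    whose stem is >= hairpin_min_stem with loop <= hairpin_max_loop ending
    within hairpin_window bp upstream of the CTRR].  A terminus is reported
    at score >= threshold (default 6 per terminus).
    """

    w_tc: int = 4
    w_flank_a: int = 2
    w_ctrr: int = 3
    w_flank_t: int = 1
    w_hairpin: int = 4
    threshold: int = 6
    hairpin_min_stem: int = 10
    hairpin_max_loop: int = 10
    hairpin_window: int = 30
    min_len: int = 500
    max_len: int = 15000
    cluster_identity: float = 0.80
    five_prime_motif: str = DEFAULT_FIVE_PRIME_MOTIF
    min_motif_matches: int = 10

    def __post_init__(self) -> None:
        for w in (self.w_tc, self.w_flank_a, self.w_ctrr, self.w_flank_t, self.w_hairpin):
            if w <= 0:
                raise ValueError("feature weights must be positive")
        if self.threshold > max(
            self.w_tc + self.w_flank_a, self.w_ctrr + self.w_flank_t + self.w_hairpin
        ):
            raise ValueError("threshold exceeds the maximum attainable terminus score")


@dataclass(frozen=True)
class TerminusHit:
    position: int  # 5': element start; 3': element end (exclusive)
    score: int
    features: tuple[str, ...]


def _has_hairpin(seq: str, end: int, config: HelitronConfig) -> bool:
    """Palindromic hairpin (stem >= min, loop <= max) whose 3' stem ends
    within ``hairpin_window`` bp upstream of ``end``."""
    stem = config.hairpin_min_stem
    for stem_end in range(end, max(stem * 2 - 1, end - config.hairpin_window), -1):
        for loop in range(0, config.hairpin_max_loop + 1):
            s2_start = stem_end - stem
            s1_end = s2_start - loop
            s1_start = s1_end - stem
            if s1_start < 0:
                continue
            if reverse_complement(seq[s1_start:s1_end]) == seq[s2_start:stem_end]:
                return True
    return False


def score_helitron_termini(
    genome: GenomeSequence, config: HelitronConfig | None = None
) -> tuple[list[TerminusHit], list[TerminusHit]]:
    """Score every plus-strand position as a putative 5' or 3' terminus.

    Returns (5' hits, 3' hits) with per-feature breakdowns; only positions
    at or above the per-terminus threshold are reported.
    """
    config = config or HelitronConfig()
    seq = genome.residues
    n = len(seq)
    five: list[TerminusHit] = []
    three: list[TerminusHit] = []
    for pos in range(n - 1):
        score = 0
        feats = []
        if seq[pos : pos + 2] == "TC":
            score += config.w_tc
            feats.append("TC")
            if pos > 0 and seq[pos - 1] == "A":
                score += config.w_flank_a
                feats.append("flank_A")
        if score >= config.threshold:
            five.append(TerminusHit(pos, score, tuple(feats)))
    for end in range(4, n + 1):
        score = 0
        feats = []
        tail = seq[end - 4 : end]
        if tail[:2] == "CT" and tail[2] in "AG" and tail[3] in "AG":
            score += config.w_ctrr
            feats.append("CTRR")
            if end < n and seq[end] == "T":
                score += config.w_flank_t
                feats.append("flank_T")
            if _has_hairpin(seq, end - 4, config):
                score += config.w_hairpin
                feats.append("hairpin")
        if score >= config.threshold:
            three.append(TerminusHit(end, score, tuple(feats)))
    return five, three


def _motif_matches(seq: str, pos: int, motif: str) -> int:
    window = seq[pos : pos + len(motif)]
    return sum(1 for a, b in zip(window, motif) if a == b)


def pair_helitrons(
    five_hits: Sequence[TerminusHit],
    three_hits: Sequence[TerminusHit],
    genome: GenomeSequence,
    config: HelitronConfig | None = None,
) -> list[TeAnnotation]:
    """Pair 5'/3' terminus hits into elements and cluster them at 80 %.

    Each 3' hit is anchored to the in-range 5' hit whose leading bases best
    match the terminal consensus motif (minimum ``min_motif_matches``),
    ties to the nearest.  Overlapping pairings resolve best-joint-score
    first, then longer, then leftmost; surviving elements are clustered by
    greedy centroid assignment (longest first) at ``cluster_identity`` and
    annotated with their cluster label.
    """
    config = config or HelitronConfig()
    seq = genome.residues
    anchored = [
        fh
        for fh in five_hits
        if _motif_matches(seq, fh.position, config.five_prime_motif) >= config.min_motif_matches
    ]
    ends = sorted(three_hits, key=lambda h: h.position)
    pairs: list[tuple[int, int, int]] = []  # (start, end, joint score)
    for fh in anchored:
        # best downstream 3' terminus in range: strongest signature, then nearest
        best = None
        for th in ends:
            length = th.position - fh.position
            if length < config.min_len:
                continue
            if length > config.max_len:
                break
            key = (th.score, -length)
            if best is None or key > best[0]:
                best = (key, th)
        if best is not None:
            th = best[1]
            pairs.append((fh.position, th.position, fh.score + th.score))
    pairs.sort(key=lambda p: (-p[2], p[1] - p[0], p[0]))
    kept: list[tuple[int, int, int]] = []
    for s, e, sc in pairs:
        if not any(s < ke and ks < e for ks, ke, _ in kept):
            kept.append((s, e, sc))
    kept.sort()
    # greedy centroid clustering at cluster_identity, longest first
    order = sorted(range(len(kept)), key=lambda i: -(kept[i][1] - kept[i][0]))
    centroids: list[tuple[str, str]] = []  # (label, sequence)
    labels: dict[int, str] = {}
    for i in order:
        s, e, _ = kept[i]
        element_seq = seq[s:e]
        assigned = None
        for label, cseq in centroids:
            res = align_pair(element_seq, cseq, mode="local")
            if res.identity >= config.cluster_identity and res.aligned_length >= 0.8 * min(
                len(element_seq), len(cseq)
            ):
                assigned = label
                break
        if assigned is None:
            assigned = f"Helitron_cluster_{len(centroids)}"
            centroids.append((assigned, element_seq))
        labels[i] = assigned
    return [
        TeAnnotation(
            interval=Interval(genome.id, s, e),
            order="Helitron",
            superfamily=labels[i],
            score=float(sc),
            source="helitron_scan",
        )
        for i, (s, e, sc) in enumerate(kept)
    ]
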