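"""Non-LTR retroelement detection on the LTR-masked genome.

Autonomous non-LTR elements (LINE-like) all encode a reverse transcriptase
(RT); most clades additionally carry an apurinic/apyrimidinic endonuclease
(APE) — only the R2 and CRE clades encode RT alone.  Detection therefore
extracts long ORFs (>= 500 bp by default, sized to catch the APE gene) from
the masked genome and scores their translations against per-clade RT
position-weight matrices; the RT hit is mandatory, the APE hit corroborating.

Profiles here are log-odds PWMs over the 20 amino acids with a uniform 1/20
background.  Toy profiles built from fixed 12-residue marker motifs are
bundled for seven clades plus APE and the LTR-internal domains; users can
supply PWMs derived from curated alignments in the same TSV format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .orfs import Orf, find_orfs
from .seqio import GenomeSequence

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_UNKNOWN_SCORE = -4.0

NONLTR_CLADES = (
    "CRE", "R2", "R1", "I", "Jockey", "L1", "RTE", "CR1", "L2", "RandI", "Rex", "Tad1",
)

# Fixed 12-residue marker motifs: the planted signal of the toy profiles.
RT_MARKERS = {
    "CRE": "WHKDRAPLESVT",
    "I": "FYMGNQCITKWD",
    "Jockey": "LPESHWVRKDAG",
    "L1": "MTCHWQYVGKRE",
    "R1": "KDWNEPFAHLSY",
    "R2": "GQVLWMHTRCIE",
    "RTE": "HSAYWKEMVPDN",
}
APE_MARKER = "NVEWHDGKYSPC"
# Domains annotated inside LTR retrotransposons (shared with ltr_detect).
DOMAIN_MARKERS = {"RT": "WLDKGAQHEVRM", "INT": "YGHPKWESDVLA"}


class ProfileHit(NamedTuple):
    """Best ungapped placement of a profile on a protein; ``offset`` is None
    when the protein is shorter than the profile (defined no-placement)."""

    score: float
    offset: int | None


@dataclass(frozen=True)
class ScoringProfile:
    """Per-position log-odds scores over the 20 amino acids."""

    label: str
    matrix: np.ndarray  # (length, 20)
    threshold: float

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(AA_ALPHABET):
            raise ValueError("matrix must be (length, 20)")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.matrix.argmax(axis=1))


def build_profile(
    label: str,
    motif: str,
    consensus_p: float = 0.7,
    threshold_fraction: float = 0.55,
) -> ScoringProfile:
    """PWM for a fixed motif: consensus probability 0.7 at each position, the
    remainder spread uniformly, log2 odds against a 1/20 background."""
    if not motif or set(motif) - set(AA_ALPHABET):
        raise ValueError(f"motif must be non-empty over {AA_ALPHABET}")
    bg = 1.0 / len(AA_ALPHABET)
    off_p = (1.0 - consensus_p) / (len(AA_ALPHABET) - 1)
    mat = np.full((len(motif), len(AA_ALPHABET)), math.log2(off_p / bg))
    for pos, aa in enumerate(motif):
        mat[pos, _AA_INDEX[aa]] = math.log2(consensus_p / bg)
    prof = ScoringProfile(label, mat, threshold=0.0)
    return ScoringProfile(label, mat, threshold=threshold_fraction * prof.max_score)


def builtin_rt_profiles() -> dict[str, ScoringProfile]:
    """Toy clade-specific RT profiles (planted-signal scale)."""
    return {clade: build_profile(f"RT_{clade}", motif) for clade, motif in RT_MARKERS.items()}


def builtin_ape_profile() -> ScoringProfile:
    return build_profile("APE", APE_MARKER)


def builtin_domain_profiles() -> dict[str, ScoringProfile]:
    """Profiles for domains annotated inside LTR retrotransposons."""
    return {name: build_profile(name, motif) for name, motif in DOMAIN_MARKERS.items()}


def write_profile(profile: ScoringProfile, path: str | Path) -> None:
    """TSV: a header row carrying label and threshold, then one row per
    position with 20 score columns."""
    with open(path, "w") as fh:
        fh.write(f"#label={profile.label}\tthreshold={profile.threshold:.6g}\n")
        fh.write("pos\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, row in enumerate(profile.matrix):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_profile(path: str | Path) -> ScoringProfile:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#label="):
            raise ValueError(f"{path}: missing profile header")
        fields = dict(part.split("=", 1) for part in header.lstrip("#").split("\t"))
        fh.readline()  # column header
        rows = [list(map(float, line.split("\t")[1:])) for line in fh if line.strip()]
    return ScoringProfile(fields["label"], np.array(rows), float(fields["threshold"]))


def score_profile(protein: str, profile: ScoringProfile) -> ProfileHit:
    """Best ungapped placement: max over offsets of per-position score sums.

    Residues outside the 20-letter alphabet score a fixed penalty.  Proteins
    shorter than the profile yield the defined no-placement hit.
    """
    L = profile.length
    n = len(protein)
    if n < L:
        return ProfileHit(float("-inf"), None)
    idx = np.array([_AA_INDEX.get(a, -1) for a in protein])
    ext = np.hstack([profile.matrix, np.full((L, 1), _UNKNOWN_SCORE)])
    # per-position score for each (offset, profile position)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = ext[np.arange(L)[None, :], windows].sum(axis=1)
    best = int(scores.argmax())
    return ProfileHit(float(scores[best]), best)


@dataclass(frozen=True)
class NonLtrElement:
    """A long ORF with a mandatory RT hit, optional APE hit, clade call."""

    orf: Orf
    clade: str
    rt_score: float
    rt_offset: int
    ape_hit: ProfileHit | None = None
    ambiguous: bool = False


def extract_long_orfs(genome: GenomeSequence, min_len: int = 500) -> list[Orf]:
    """Stop-to-stop ORFs of >= ``min_len`` nucleotides, both strands, all
    frames.  Codons containing N translate to X and break ORFs, so nothing
    reported overlaps a hard-masked run."""
    min_aa = -(-min_len // 3)  # ceil
    return find_orfs(genome.residues, genome.id, min_aa=min_aa)


def detect_nonltr(
    genome: GenomeSequence,
    rt_profiles: Mapping[str, ScoringProfile] | None = None,
    ape_profile: ScoringProfile | None = None,
    min_orf_len: int = 500,
) -> list[NonLtrElement]:
    """Call non-LTR elements on an (LTR-masked) genome.

    An ORF becomes an element when at least one clade RT profile scores it
    at or above that profile's threshold; the clade is the highest-scoring
    passing profile (exact ties resolve to the lexicographically first clade
    and are flagged ambiguous).  Elements are sorted by position.
    """
    if rt_profiles is None:
        rt_profiles = builtin_rt_profiles()
        if ape_profile is None:
            ape_profile = builtin_ape_profile()
    if not rt_profiles:
        raise ValueError("at least one clade RT profile is required")
    elements: list[NonLtrElement] = []
    for orf in extract_long_orfs(genome, min_len=min_orf_len):
        passing: dict[str, ProfileHit] = {}
        for clade in sorted(rt_profiles):
            hit = score_profile(orf.protein, rt_profiles[clade])
            if hit.offset is not None and hit.score >= rt_profiles[clade].threshold:
                passing[clade] = hit
        if not passing:
            continue
        best_score = max(h.score for h in passing.values())
        winners = [c for c, h in passing.items() if h.score == best_score]
        clade = sorted(winners)[0]
        ape_hit = None
        if ape_profile is not None:
            cand = score_profile(orf.protein, ape_profile)
            if cand.offset is not None and cand.score >= ape_profile.threshold:
                ape_hit = cand
        elements.append(
            NonLtrElement(
                orf=orf,
                clade=clade,
                rt_score=passing[clade].score,
                rt_offset=passing[clade].offset,
                ape_hit=ape_hit,
                ambiguous=len(winners) > 1,
            )
        )
    elements.sort(key=lambda e: (e.orf.interval.start, e.orf.interval.end))
    return elements
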