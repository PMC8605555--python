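"""Sequence, interval and annotation plumbing shared by every detector.

Genomes are held as plain uppercase ``ACGTN`` strings; ambiguity codes are
collapsed to ``N`` on ingest and ``N`` never seeds or extends a match in any
detector.  All coordinates are 0-based half-open internally and converted to
1-based inclusive only at GFF3/TSV serialization time.  Minus-strand loci are
stored on the forward coordinate system with a strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

TE_ORDERS = ("LTR", "LINE", "SINE", "DNA", "Helitron", "MITE", "Unclassified")

_CLEAN = re.compile(r"[^ACGTN]")


class FastaFormatError(ValueError):
    """Raised for files that are not parseable FASTA."""


def normalize_residues(raw: str) -> str:
    """Uppercase, map U->T and collapse anything outside ACGTN to N."""
    seq = raw.upper().replace("U", "T")
    return _CLEAN.sub("N", seq)


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N} with a soft-mask track.

    ``soft_mask`` stores lowercase-on-output runs as merged, sorted
    (start, end) pairs so the in-memory alphabet contract stays uppercase.
    """

    id: str
    residues: str
    soft_mask: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains residues outside ACGTN: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TeAnnotation:
    """A classified repeat interval shared by all detectors and the reporter."""

    interval: Interval
    order: str
    superfamily: str
    score: float
    source: str

    def __post_init__(self) -> None:
        if self.order not in TE_ORDERS:
            raise ValueError(f"unknown TE order {self.order!r}")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.order != "Unclassified" and not self.superfamily:
            raise ValueError("superfamily required for classified annotations")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read plain or line-wrapped FASTA into normalized GenomeSequence records.

    Residues are uppercased, U becomes T, and any non-ACGTN character becomes
    N.  Record order is preserved.  Raises :class:`FastaFormatError` for an
    empty file or content before the first header, naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FastaFormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FastaFormatError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'"
            )
    records = [
        GenomeSequence(id=rec.id, residues=normalize_residues(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    """Write FASTA; soft-masked runs are emitted in lowercase."""
    with open(path, "w") as fh:
        for g in genomes:
            residues = g.residues
            if g.soft_mask:
                buf = list(residues)
                for s, e in g.soft_mask:
                    buf[s:e] = residues[s:e].lower()
                residues = "".join(buf)
            fh.write(f">{g.id}\n")
            for i in range(0, len(residues), width):
                fh.write(residues[i : i + width] + "\n")


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of (start, end) pairs as merged sorted tuples."""
    merged: list[list[int]] = []
    for s, e in sorted(pairs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def mask_intervals(
    genome: GenomeSequence, intervals: Sequence[Interval], mode: str = "hard"
) -> GenomeSequence:
    """Mask the covered residues of ``genome``.

    Hard masking replaces residues with N; soft masking records the runs on
    the genome's mask track (lowercased only when written out).  Length never
    changes and the operation is idempotent for a fixed interval set.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    for iv in intervals:
        if iv.seq_id != genome.id:
            raise ValueError(f"interval {iv} does not belong to sequence {genome.id!r}")
        if iv.end > genome.length:
            raise ValueError(f"interval {iv} out of bounds for length {genome.length}")
    runs = merge_intervals((iv.start, iv.end) for iv in intervals)
    if not runs:
        return genome
    if mode == "hard":
        buf = list(genome.residues)
        for s, e in runs:
            buf[s:e] = "N" * (e - s)
        return replace(genome, residues="".join(buf))
    combined = merge_intervals(list(genome.soft_mask) + list(runs))
    return replace(genome, soft_mask=combined)


def masked_fraction(genome: GenomeSequence) -> float:
    return genome.residues.count("N") / max(1, genome.length)


def write_annotations(
    annotations: Sequence[TeAnnotation], path: str | Path, format: str = "BED"
) -> None:
    """Serialize annotations as BED6, GFF3 or a RepeatMasker-``.out``-style TSV.

    BED is 0-based half-open; GFF3 and the TSV are 1-based inclusive.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3", "TSV"):
        raise ValueError(f"unsupported format {format!r}")
    with open(path, "w") as fh:
        if fmt == "BED":
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for a in annotations:
                iv = a.interval
                name = f"{a.order}:{a.superfamily or '.'}"
                fh.write(
                    f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{a.score:g}\t{iv.strand}\n"
                )
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for i, a in enumerate(annotations):
                iv = a.interval
                attrs = (
                    f"ID=te{i};Name={a.superfamily or a.order};"
                    f"order={a.order};superfamily={a.superfamily or '.'};"
                    f"Target={a.superfamily or a.order}"
                )
                fh.write(
                    f"{iv.seq_id}\t{a.source}\tdispersed_repeat\t{iv.start + 1}\t{iv.end}\t"
                    f"{a.score:g}\t{iv.strand}\t.\t{attrs}\n"
                )
        else:
            fh.write("score\tseq\tbegin\tend\tstrand\torder\tsuperfamily\tsource\n")
            for a in annotations:
                iv = a.interval
                fh.write(
                    f"{a.score:g}\t{iv.seq_id}\t{iv.start + 1}\t{iv.end}\t{iv.strand}\t"
                    f"{a.order}\t{a.superfamily or '.'}\t{a.source}\n"
                )


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
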