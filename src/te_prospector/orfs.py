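"""Stop-to-stop open reading frame extraction over all six frames.

ORFs are maximal stop-free codon runs (no start-codon requirement), the
convention of classic ORF-extraction tools.  Codons containing N translate
to X and break ORFs, so masked (N-run) regions never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .seqio import Interval, reverse_complement


@dataclass(frozen=True)
class Orf:
    """An ORF on the forward coordinate system of its source sequence.

    ``frame`` is 1..3 on the forward strand and -1..-3 on the reverse strand;
    ``protein`` is the translated amino-acid sequence (no terminal stop).
    """

    interval: Interval
    frame: int
    protein: str


def translate_frame(seq: str, offset: int) -> str:
    usable = len(seq) - offset
    usable -= usable % 3
    if usable <= 0:
        return ""
    return str(Seq(seq[offset : offset + usable]).translate())


def _frame_orfs(protein: str) -> list[tuple[int, int]]:
    """Codon-index half-open runs of residues free of stops and X."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, aa in enumerate(protein):
        if aa in "*X":
            if start is not None:
                runs.append((start, i))
                start = None
        elif start is None:
            start = i
    if start is not None:
        runs.append((start, len(protein)))
    return runs


def find_orfs(seq: str, seq_id: str, min_aa: int = 100, offset: int = 0) -> list[Orf]:
    """All stop-to-stop ORFs of at least ``min_aa`` residues, both strands.

    ``offset`` shifts reported coordinates, for callers scanning a slice of a
    larger sequence.  Results are sorted by forward-strand start position.
    """
    n = len(seq)
    out: list[Orf] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for f in range(3):
            protein = translate_frame(s, f)
            for cs, ce in _frame_orfs(protein):
                if ce - cs < min_aa:
                    continue
                nt_start = f + 3 * cs
                nt_end = f + 3 * ce
                if strand == "+":
                    start, end = nt_start, nt_end
                    frame = f + 1
                else:
                    start, end = n - nt_end, n - nt_start
                    frame = -(f + 1)
                out.append(
                    Orf(
                        Interval(seq_id, offset + start, offset + end, strand),
                        frame,
                        protein[cs:ce],
                    )
                )
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.frame))
    return out
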