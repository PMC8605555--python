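"""Labeled repeat libraries: consensus/exemplar sequences with classification.

FASTA headers use the ``id#Order/Superfamily`` labeling convention of
repeat-library tooling; entries without a tag ingest as Unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import TE_ORDERS, normalize_residues


@dataclass(frozen=True)
class RepeatEntry:
    id: str
    sequence: str
    order: str
    superfamily: str
    provenance: str = "external"


@dataclass(frozen=True)
class RepeatLibrary:
    """An ordered collection of labeled repeat exemplars with unique ids."""

    entries: tuple[RepeatEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("library entry ids must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, str, str, str]], provenance: str = "external"
    ) -> "RepeatLibrary":
        return cls(
            tuple(
                RepeatEntry(i, normalize_residues(s), o, f, provenance)
                for i, s, o, f in entries
            )
        )

    @classmethod
    def from_fasta(cls, path: str | Path, provenance: str = "external") -> "RepeatLibrary":
        from .seqio import read_fasta

        entries = []
        for rec in read_fasta(path):
            order, superfamily = "Unclassified", ""
            if "#" in rec.id:
                base, tag = rec.id.split("#", 1)
                if "/" in tag:
                    order, superfamily = tag.split("/", 1)
                else:
                    order = tag
                if order not in TE_ORDERS:
                    order, superfamily = "Unclassified", ""
            entries.append(RepeatEntry(rec.id, rec.residues, order, superfamily, provenance))
        return cls(tuple(entries))

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f">{e.id}\n")
                for i in range(0, len(e.sequence), width):
                    fh.write(e.sequence[i : i + width] + "\n")


def dedup_library(entries: Sequence[RepeatEntry]) -> tuple[RepeatLibrary, int]:
    """Keep the first occurrence of each exact sequence (input order).

    Reverse complements are *not* considered duplicates.  Returns the
    deduplicated library and the number of entries removed.
    """
    seen: set[str] = set()
    kept: list[RepeatEntry] = []
    for e in entries:
        if e.sequence in seen:
            continue
        seen.add(e.sequence)
        kept.append(e)
    return RepeatLibrary(tuple(kept)), len(entries) - len(kept)
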