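"""Seeded synthetic genomes with planted, truth-labeled transposable elements.

The generator exists so every detector in the toolkit can be exercised
without genome downloads: it writes an i.i.d. background (no repeats, so
false positives are attributable to the detectors rather than the fixture)
and plants elements that satisfy each detector's structural definition:

* LTR retrotransposons: 5'LTR + internal + 3'LTR where both LTRs descend
  from one ancestral LTR, each evolved d/2 under HKY85(kappa, pi) so the
  expected pairwise LTR divergence is d — matching the dating model's
  assumption that LTRs are identical at insertion.  The internal region
  carries an ORF of >= 100 codons encoding the RT marker motif, and the
  insertion duplicates a host target site (TSD) verbatim on both flanks.
* MITEs: a perfect terminal inverted repeat pair around a short interior,
  flanked by an exact TSD of length 2, 3, 8 or 10, total length 50-800 bp.
* Helitrons: canonical termini — A | TC ... hairpin ... CTRR | T — with a
  bundled 12 bp 5' terminal consensus standing in for a trained family head.
* LINE surrogates: a single >= 500 bp ORF carrying a clade RT marker motif
  plus the APE marker.

Truth files give each planted interval, its kind and family, and for LTR
elements the planted divergence with its implied age d / (2 r) years under
the default rate model (r = 2.5e-8 per generation / 5-year generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from . import evodynamics
from .hky import evolve
from .nonltr_detect import APE_MARKER, DOMAIN_MARKERS, RT_MARKERS
from .seqio import GenomeSequence, Interval, reverse_complement

ELEMENT_KINDS = ("LTR_RT", "MITE", "HELITRON", "LINE")

MITE_TSD_LENGTHS = (2, 3, 8, 10)
HELITRON_FIVE_PRIME_MOTIF = "TCTCTACTATGC"

_DEFAULT_SUPERFAMILY = {
    "LTR_RT": ("LTR", ("ERVL", "ERV1", "ERVL-MaLR", "ERV2")),
    "MITE": ("MITE", ("hAT-toy", "Tc1-toy")),
    "HELITRON": ("Helitron", ("Helitron_DR", "Helitron_GA")),
    "LINE": ("LINE", None),  # superfamily = clade
}

_CODON_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODON_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODON_BY_AA.values():
    codons.sort()
_AA_CHOICES = sorted(_CODON_BY_AA)


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: one element kind, its copy count and shape parameters.

    ``divergence`` may be a scalar or a per-copy sequence (cycled); it is
    the expected pairwise LTR divergence d, planted symmetrically (each LTR
    evolves d/2).  ``n_families`` splits the copies over independently drawn
    ancestral elements; copies within a family share their ancestor.
    """

    element_kind: str
    count: int
    ltr_len: int = 400
    internal_len: int = 2000
    tir_len: int = 15
    element_len: int = 180
    helitron_len: int = 2500
    hairpin_stem: int = 12
    hairpin_loop: int = 5
    line_len: int = 1600
    orf_aa: int = 280
    tsd_len: int = 5
    mite_tsd_len: int = 3
    divergence: float | tuple[float, ...] = 0.05
    kappa: float = 4.0
    base_frequencies: tuple[float, float, float, float] = (0.295, 0.205, 0.205, 0.295)
    n_families: int = 1
    clade: str = "L1"

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.element_kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        for d in self.divergences:
            if not 0 <= d < 0.75:
                raise ValueError(f"divergence {d} outside [0, 0.75) (saturation)")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        pi = np.asarray(self.base_frequencies)
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.element_kind == "MITE" and self.mite_tsd_len not in MITE_TSD_LENGTHS:
            raise ValueError(f"MITE TSD length must be one of {MITE_TSD_LENGTHS}")

    @property
    def divergences(self) -> tuple[float, ...]:
        if isinstance(self.divergence, (int, float)):
            return (float(self.divergence),)
        return tuple(float(d) for d in self.divergence)


@dataclass(frozen=True)
class TruthRecord:
    """One planted occurrence: the acceptance oracle for the detectors."""

    element_id: str
    interval: Interval
    element_kind: str
    family_id: str
    d: float = 0.0
    tsd: str = ""

    @property
    def age_years(self) -> float:
        r = evodynamics.MU_PER_GENERATION / evodynamics.GENERATION_YEARS
        return self.d / (2.0 * r)


@dataclass
class SyntheticGenome:
    genome: GenomeSequence
    truth: list[TruthRecord]
    library_entries: list[tuple[str, str, str, str]]  # (id, sequence, order, superfamily)
    files: dict[str, Path] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_background(length: int, gc: float, seed: int | np.random.Generator) -> GenomeSequence:
    """I.i.d. background with P(G) + P(C) = gc; deterministic per seed."""
    if length <= 0:
        raise ValueError("background length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GenomeSequence("background", _random_seq(rng, length, gc))


def _random_orf(rng: np.random.Generator, n_codons: int, markers: Sequence[str]) -> str:
    """Stop-free codon run encoding the marker motifs at spaced offsets,
    bounded by TAA stops so stop-to-stop extraction recovers it exactly."""
    protein = list(rng.choice(_AA_CHOICES, size=n_codons))
    offset = 10
    for motif in markers:
        protein[offset : offset + len(motif)] = list(motif)
        offset += len(motif) + 20
    codons = [_CODON_BY_AA[aa][rng.integers(len(_CODON_BY_AA[aa]))] for aa in protein]
    return "TAA" + "".join(codons) + "TAA"


def simulate_ltr_element(
    spec: PlantSpec,
    rng: np.random.Generator,
    d: float | None = None,
    ancestor: tuple[str, str] | None = None,
) -> tuple[str, dict]:
    """One full-length LTR-RT: 5'LTR + internal + 3'LTR.

    Both LTRs descend from one ancestral LTR, each evolved d/2 under
    HKY85(kappa, pi).  Returns the element sequence and a metadata dict with
    the planted divergence and component intervals (element-local).
    """
    if spec.element_kind != "LTR_RT":
        raise ValueError("spec must describe an LTR_RT plant")
    d = spec.divergences[0] if d is None else d
    if not 0 <= d < 0.75:
        raise ValueError(f"divergence {d} at or beyond saturation")
    pi = spec.base_frequencies
    if ancestor is None:
        gc = pi[1] + pi[2]
        ltr_anc = _random_seq(rng, spec.ltr_len, gc)
        orf = _random_orf(rng, max(120, spec.orf_aa // 2), [DOMAIN_MARKERS["RT"]])
        pad = spec.internal_len - len(orf)
        if pad < 0:
            raise ValueError("internal_len too small for the planted ORF")
        ancestor = (ltr_anc, _random_seq(rng, pad // 2, gc), orf, _random_seq(rng, pad - pad // 2, gc))
    ltr_anc, pre, orf, post = ancestor
    ltr5 = evolve(ltr_anc, d / 2.0, spec.kappa, pi, rng)
    ltr3 = evolve(ltr_anc, d / 2.0, spec.kappa, pi, rng)
    # non-coding internal sequence drifts with the copy; the ORF is conserved
    internal = evolve(pre, d / 2.0, spec.kappa, pi, rng) + orf + evolve(post, d / 2.0, spec.kappa, pi, rng)
    element = ltr5 + internal + ltr3
    meta = {
        "d": d,
        "ltr_len": len(ltr_anc),
        "ltr5": (0, len(ltr_anc)),
        "ltr3": (len(element) - len(ltr_anc), len(element)),
        "ancestor": ancestor,
    }
    return element, meta


def simulate_mite(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """A perfect-TIR MITE of the configured length (50-800 bp window)."""
    interior_len = spec.element_len - 2 * spec.tir_len
    if interior_len < 0:
        raise ValueError("element_len must cover two TIRs")
    tir = _random_seq(rng, spec.tir_len)
    element = tir + _random_seq(rng, interior_len) + reverse_complement(tir)
    return element, {"tir_len": spec.tir_len, "tsd_len": spec.mite_tsd_len}


def simulate_helitron(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """Canonical Helitron core: 5' TC head motif ... hairpin ... CTRR.

    The A and T host flanks are added at planting time; the returned core
    starts with TC and ends with CTRR.
    """
    stem = _random_seq(rng, spec.hairpin_stem)
    hairpin = stem + _random_seq(rng, spec.hairpin_loop) + reverse_complement(stem)
    tail = hairpin + _random_seq(rng, 10) + "CT" + "".join(rng.choice(["A", "G"], size=2))
    mid_len = spec.helitron_len - len(HELITRON_FIVE_PRIME_MOTIF) - len(tail)
    if mid_len < 0:
        raise ValueError("helitron_len too small for the terminal signatures")
    return HELITRON_FIVE_PRIME_MOTIF + _random_seq(rng, mid_len) + tail, {}


def simulate_line(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """LINE surrogate: one long ORF with the clade RT marker and APE marker."""
    if spec.clade not in RT_MARKERS:
        raise ValueError(f"no bundled RT marker for clade {spec.clade!r}")
    orf = _random_orf(rng, spec.orf_aa, [RT_MARKERS[spec.clade], APE_MARKER])
    pad = spec.line_len - len(orf)
    if pad < 0:
        raise ValueError("line_len too small for the ORF")
    element = _random_seq(rng, pad // 2) + orf + _random_seq(rng, pad - pad // 2)
    return element, {"clade": spec.clade}


def _build_payloads(specs: Sequence[PlantSpec], rng: np.random.Generator) -> list[dict]:
    payloads: list[dict] = []
    counters = {k: 0 for k in ELEMENT_KINDS}
    for spec in specs:
        order, superfams = _DEFAULT_SUPERFAMILY[spec.element_kind]
        ancestors: dict[int, tuple] = {}
        for copy in range(spec.count):
            fam = copy % max(1, spec.n_families)
            idx = counters[spec.element_kind]
            counters[spec.element_kind] += 1
            if spec.element_kind == "LTR_RT":
                d = spec.divergences[copy % len(spec.divergences)]
                anc = ancestors.get(fam)
                seq, meta = simulate_ltr_element(spec, rng, d=d, ancestor=anc)
                ancestors[fam] = meta["ancestor"]
                anc = meta["ancestor"]
                fam_seq = anc[0] + anc[1] + anc[2] + anc[3] + anc[0]
                tsd_len = spec.tsd_len
            elif spec.element_kind == "MITE":
                if fam not in ancestors:
                    ancestors[fam] = simulate_mite(spec, rng)
                seq, meta = ancestors[fam]
                fam_seq = seq
                tsd_len = spec.mite_tsd_len
            elif spec.element_kind == "HELITRON":
                if fam not in ancestors:
                    ancestors[fam] = simulate_helitron(spec, rng)
                seq, meta = ancestors[fam]
                fam_seq = seq
                tsd_len = 0
            else:  # LINE
                if fam not in ancestors:
                    anc_orf = simulate_line(spec, rng)
                    ancestors[fam] = anc_orf
                seq, meta = ancestors[fam]
                fam_seq = seq
                tsd_len = 0
            if superfams is None:
                superfamily = spec.clade
            else:
                superfamily = superfams[fam % len(superfams)]
            payloads.append(
                {
                    "kind": spec.element_kind,
                    "element_id": f"{spec.element_kind.lower()}_{idx}",
                    "family_id": f"{spec.element_kind}_fam{fam}",
                    "seq": seq,
                    "meta": meta,
                    "tsd_len": tsd_len,
                    "order": order,
                    "superfamily": superfamily,
                    "family_seq": fam_seq,
                    "flanks": ("A", "T") if spec.element_kind == "HELITRON" else ("", ""),
                }
            )
    return payloads


def generate_genome(
    background_length: int,
    plants: Sequence[PlantSpec],
    seed: int,
    gc: float = 0.41,
    seq_id: str = "synth1",
    out_dir: str | Path | None = None,
    min_gap: int = 150,
) -> SyntheticGenome:
    """Background plus non-overlapping planted elements, with truth files.

    Insertion points are uniform over slots that keep ``min_gap`` background
    bases between plants.  TSD-forming elements duplicate the host bases at
    the insertion point verbatim on both sides.  With ``out_dir`` set, the
    genome FASTA, truth BED, truth-age TSV and a labeled reference library
    FASTA are written (byte-identical for identical specs and seed).
    """
    rng = np.random.default_rng(seed)
    background = generate_background(background_length, gc, rng).residues
    payloads = _build_payloads(plants, rng)
    rng.shuffle(payloads)
    margin = 100
    capacity = background_length - 2 * margin - (len(payloads) - 1) * min_gap if payloads else 0
    inserted_bp = sum(len(p["seq"]) for p in payloads)
    if payloads and (capacity < len(payloads) or inserted_bp > background_length):
        raise ValueError("requested plant content exceeds genome capacity")
    if payloads:
        slots = margin + np.sort(rng.choice(capacity, size=len(payloads), replace=False))
        slots = slots + np.arange(len(payloads)) * min_gap
    else:
        slots = np.array([], dtype=int)

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    cursor = 0  # position in background coordinates
    offset = 0  # cumulative inserted length
    for pos, payload in zip(slots, payloads):
        pos = int(pos)
        pieces.append(background[cursor:pos])
        tsd_len = payload["tsd_len"]
        tsd = background[pos : pos + tsd_len] if tsd_len else ""
        left, right = payload["flanks"]
        insert = tsd + left + payload["seq"] + right + tsd
        start = pos + offset + tsd_len + len(left)
        end = start + len(payload["seq"])
        pieces.append(insert)
        # the host TSD bases are duplicated: skip them once in the background
        cursor = pos + tsd_len
        offset += len(insert) - tsd_len
        truth.append(
            TruthRecord(
                element_id=payload["element_id"],
                interval=Interval(seq_id, start, end),
                element_kind=payload["kind"],
                family_id=payload["family_id"],
                d=payload["meta"].get("d", 0.0),
                tsd=tsd,
            )
        )
    pieces.append(background[cursor:])
    genome = GenomeSequence(seq_id, "".join(pieces))

    seen: dict[str, tuple[str, str, str, str]] = {}
    for payload in payloads:
        fam = payload["family_id"]
        if fam not in seen:
            entry_id = f"{fam}#{payload['order']}/{payload['superfamily']}"
            seen[fam] = (entry_id, payload["family_seq"], payload["order"], payload["superfamily"])
    library_entries = [seen[k] for k in sorted(seen)]
    truth.sort(key=lambda t: t.interval.start)

    result = SyntheticGenome(genome=genome, truth=truth, library_entries=library_entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .seqio import write_fasta

        genome_path = out_dir / "genome.fasta"
        write_fasta([genome], genome_path)
        bed_path = out_dir / "truth.bed"
        with open(bed_path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for t in truth:
                fh.write(
                    f"{t.interval.seq_id}\t{t.interval.start}\t{t.interval.end}\t"
                    f"{t.element_kind}:{t.element_id}\t0\t+\n"
                )
        ages_path = out_dir / "truth_ages.tsv"
        with open(ages_path, "w") as fh:
            fh.write("element_id\td\tage_years\n")
            for t in truth:
                if t.element_kind == "LTR_RT":
                    fh.write(f"{t.element_id}\t{t.d:.6g}\t{t.age_years:.6g}\n")
        lib_path = out_dir / "reference_library.fasta"
        with open(lib_path, "w") as fh:
            for entry_id, seq, _, _ in library_entries:
                fh.write(f">{entry_id}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        result.files = {
            "genome": genome_path,
            "truth_bed": bed_path,
            "truth_ages": ages_path,
            "library": lib_path,
        }
    return result


def standard_fixture_specs(
    n_ltr: int = 10, n_mite: int = 10, n_helitron: int = 5, n_line: int = 5
) -> list[PlantSpec]:
    """The standard test condition: LTR-RTs at d <= 0.10, MITEs, canonical
    Helitrons and LINE surrogates on a 100 kb background."""
    return [
        PlantSpec(
            "LTR_RT",
            n_ltr,
            divergence=tuple(0.01 * (i + 1) for i in range(min(10, max(1, n_ltr)))),
            n_families=2,
        ),
        PlantSpec("MITE", n_mite, n_families=2),
        PlantSpec("HELITRON", n_helitron, n_families=2),
        PlantSpec("LINE", n_line, n_families=1),
    ]


def standard_fixture(seed: int, out_dir: str | Path | None = None) -> SyntheticGenome:
    return generate_genome(100_000, standard_fixture_specs(), seed=seed, out_dir=out_dir)
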