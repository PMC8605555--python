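"""Library assembly, homology annotation/masking and landscape summaries.

The assembled repeat library (structural exemplars plus any external
labeled library) is applied to a genome by seeded local alignment: shared
k-mers (default 11, low-complexity seeds excluded) between a library entry
and the genome nominate windows that are refined by affine local alignment;
hits scoring at or above the Smith-Waterman cutoff (default 225 under the
pinned +2/-3/-5/-2 scheme) become annotations, overlaps resolve best-score
first, and the genome is returned hard-masked over the retained hits.

``run_pipeline`` orchestrates the whole toolkit: structural LTR discovery,
homology filtering, LTR masking, non-LTR detection, MITE/Helitron scans,
library assembly with exact-sequence dedup, genome annotation, family
clustering, gene-conversion-aware dating, and summary tables.  Every stage
writes its artifact; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import class2_detect, evodynamics, ltr_detect, nonltr_detect, synthetic
from .align import align_pair
from .library import RepeatEntry, RepeatLibrary, dedup_library
from .seqio import (
    GenomeSequence,
    Interval,
    TeAnnotation,
    mask_intervals,
    read_fasta,
    reverse_complement,
    write_annotations,
    write_fasta,
)

__all__ = [
    "MaskConfig",
    "AnnotationSummary",
    "RepeatLibrary",
    "RepeatEntry",
    "dedup_library",
    "annotate_genome",
    "summarize",
    "run_pipeline",
]


@dataclass(frozen=True)
class MaskConfig:
    """Seeded local-alignment masking parameters.

    ``min_sw_score`` is the minimum Smith-Waterman score under the pinned
    scoring scheme (+2 match / -3 mismatch / -5 open / -2 extend); the
    default 225 corresponds to a ~113 bp perfect match.  Low-complexity
    seeds (Shannon entropy < 1 bit/base) never nominate windows when
    ``exclude_low_complexity`` is set.
    """

    seed_k: int = 11
    min_sw_score: float = 225.0
    exclude_low_complexity: bool = True
    window_margin: int = 200
    min_window_seeds: int = 3  # even a minimal 85%-identity hit carries ~10 seeds

    def __post_init__(self) -> None:
        if self.min_sw_score <= 0:
            raise ValueError("min_sw_score must be > 0")


def seed_entropy(seed: str) -> float:
    """Shannon entropy in bits/base over the seed's nucleotide composition."""
    counts = [seed.count(b) for b in "ACGT"]
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts if c)


def _genome_index(seq: str, k: int, exclude_low_complexity: bool) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index[kmer].append(i)
    if exclude_low_complexity:
        index = {k2: v for k2, v in index.items() if seed_entropy(k2) >= 1.0}
    return index


@dataclass(frozen=True)
class _Hit:
    start: int
    end: int
    score: float
    entry: RepeatEntry
    strand: str


def annotate_genome(
    genome: GenomeSequence,
    library: RepeatLibrary,
    config: MaskConfig | None = None,
) -> tuple[list[TeAnnotation], GenomeSequence]:
    """Annotate and hard-mask a genome against a labeled repeat library.

    Returns the retained, non-overlapping annotations (best score first at
    conflicts; ties to the longer hit, then the library id) and the masked
    genome.
    """
    config = config or MaskConfig()
    if len(library) == 0:
        raise ValueError("annotation requires a non-empty library")
    seq = genome.residues
    index = _genome_index(seq, config.seed_k, config.exclude_low_complexity)
    k = config.seed_k
    hits: list[_Hit] = []
    # longest entries first; loci already covered by an accepted hit are not
    # re-aligned against every near-identical library relative
    covered = np.zeros(len(seq), dtype=bool)
    ordered = sorted(library, key=lambda e: (-len(e.sequence), e.id))
    for entry in ordered:
        for strand in "+-":
            query = entry.sequence if strand == "+" else reverse_complement(entry.sequence)
            if len(query) < k:
                continue
            # genome positions seeded by this entry, merged into windows;
            # seeds inside an already-accepted hit are redundant
            positions: list[tuple[int, int]] = []  # (implied entry start, seed pos)
            for off in range(len(query) - k + 1):
                kmer = query[off : off + k]
                for pos in index.get(kmer, ()):
                    if not covered[pos]:
                        positions.append((pos - off, pos))
            if not positions:
                continue
            positions.sort()
            margin = config.window_margin
            span = len(query)
            # cluster seeds whose implied entry starts agree within the margin:
            # genuine (even diverged) hits pile up, random seeds stay isolated
            windows: list[tuple[int, int, list[int]]] = []
            cluster = [positions[0]]
            for p in positions[1:]:
                if p[0] - cluster[-1][0] <= margin:
                    cluster.append(p)
                else:
                    windows.append((cluster[0][0], cluster[-1][0] + span, [c[1] for c in cluster]))
                    cluster = [p]
            windows.append((cluster[0][0], cluster[-1][0] + span, [c[1] for c in cluster]))
            # most-seeded windows first, so the direct placement of a repeat
            # is aligned before its diagonal echoes, which then skip
            windows.sort(key=lambda w: (-len(w[2]), w[0]))
            for ws, we, seed_pos in windows:
                if len(seed_pos) < config.min_window_seeds:
                    continue
                live = int(np.count_nonzero(~covered[np.asarray(seed_pos)]))
                if live < config.min_window_seeds:
                    continue
                # a hit at the score floor spans >= ~113 bp; seeds confined
                # to a shorter stretch (e.g. one short shared motif) cannot
                # support one
                if max(seed_pos) - min(seed_pos) < 40:
                    continue
                lo = max(0, ws - margin)
                hi = min(len(seq), we + margin)
                if hi <= lo:
                    continue
                res = align_pair(seq[lo:hi], query, mode="local")
                if res.score >= config.min_sw_score:
                    hits.append(
                        _Hit(lo + res.a_range[0], lo + res.a_range[1], res.score, entry, strand)
                    )
                    covered[lo + res.a_range[0] : lo + res.a_range[1]] = True
    hits.sort(key=lambda h: (-h.score, -(h.end - h.start), h.entry.id, h.start))
    kept: list[_Hit] = []
    for h in hits:
        if not any(h.start < o.end and o.start < h.end for o in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    annotations = [
        TeAnnotation(
            interval=Interval(genome.id, h.start, h.end, h.strand),
            order=h.entry.order,
            superfamily=h.entry.superfamily or h.entry.order,
            score=h.score,
            source="homology_mask",
        )
        for h in kept
    ]
    masked = mask_intervals(genome, [a.interval for a in annotations], mode="hard")
    return annotations, masked


@dataclass(frozen=True)
class AnnotationSummary:
    """Copy number, footprint and genome percentage per (order, superfamily)."""

    table: pd.DataFrame
    genome_length: int

    @property
    def total_bp(self) -> int:
        return int(self.table.loc[self.table["superfamily"] == "Total", "bp"].iloc[-1])


def summarize(annotations: Sequence[TeAnnotation], genome_length: int) -> AnnotationSummary:
    """Aggregate non-overlapping annotations into the landscape table.

    Rows are (order, superfamily) with copy number, total bp and percent of
    the genome (2 decimals), plus per-order subtotals and a Total row.
    """
    ivs = sorted(annotations, key=lambda a: (a.interval.seq_id, a.interval.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.interval.overlaps(b.interval):
            raise ValueError(f"overlapping annotations: {a.interval} / {b.interval}")
    rows: dict[tuple[str, str], list[float]] = defaultdict(lambda: [0, 0])
    for a in annotations:
        key = (a.order, a.superfamily or ".")
        rows[key][0] += 1
        rows[key][1] += a.interval.length
    out = []
    for order in sorted({o for o, _ in rows}):
        fams = {f: v for (o, f), v in rows.items() if o == order}
        for fam in sorted(fams):
            n, bp = fams[fam]
            out.append((order, fam, int(n), int(bp), round(100.0 * bp / genome_length, 2)))
        n = sum(v[0] for v in fams.values())
        bp = sum(v[1] for v in fams.values())
        out.append((order, "Subtotal", int(n), int(bp), round(100.0 * bp / genome_length, 2)))
    n = sum(v[0] for v in rows.values())
    bp = sum(v[1] for v in rows.values())
    out.append(("All", "Total", int(n), int(bp), round(100.0 * bp / genome_length, 2)))
    table = pd.DataFrame(out, columns=["order", "superfamily", "copies", "bp", "percent"])
    return AnnotationSummary(table=table, genome_length=genome_length)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: str | Path | Mapping, output_dir: str | Path | None = None) -> Path:
    """Run the full identification/annotation pipeline from a YAML config.

    Stages: (synthetic genome) -> LTR detection -> homology filter/classify
    -> LTR masking -> non-LTR detection -> MITE + Helitron detection ->
    library assembly + dedup -> genome annotation/masking -> 80-80-80
    clustering, gene conversion, dating -> summary + age tables; an
    optional auxiliary library re-annotates the unmasked remainder.
    Deterministic for fixed config + seed.  Returns the output directory.
    """
    cfg = _load_config(config)
    out = Path(output_dir or cfg.get("output_dir", "te_prospector_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    log_lines = [f"seed={seed}", f"config_hash={_config_hash(cfg)}"]

    # --- inputs -----------------------------------------------------------
    stage = "input"
    try:
        if "genome" in cfg:
            genome = read_fasta(cfg["genome"])[0]
            truth = []
        elif "synthetic" in cfg:
            syn_cfg = cfg["synthetic"]
            specs = [
                synthetic.PlantSpec(**spec) for spec in syn_cfg.get("plants", [])
            ] or synthetic.standard_fixture_specs()
            syn = synthetic.generate_genome(
                int(syn_cfg.get("length", 100_000)),
                specs,
                seed=seed,
                gc=float(syn_cfg.get("gc", 0.41)),
                out_dir=out,
            )
            genome = syn.genome
            truth = syn.truth
            if "reference_library" not in cfg:
                cfg["reference_library"] = str(syn.files["library"])
        else:
            raise ValueError("config needs either a 'genome' path or a 'synthetic' block")
        if "reference_library" not in cfg:
            raise ValueError("config needs a 'reference_library' FASTA")
        reference = RepeatLibrary.from_fasta(cfg["reference_library"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"genome={genome.id} length={genome.length} plants={len(truth)}")

    # --- LTR stage --------------------------------------------------------
    stage = "ltr"
    try:
        ltr_cfg = ltr_detect.LtrSearchConfig(**cfg.get("ltr", {}))
        candidates = ltr_detect.find_ltr_candidates(genome, ltr_cfg)
        profiles = nonltr_detect.builtin_domain_profiles()
        candidates = [
            ltr_detect.annotate_internal(c, genome, profiles, min_orf_aa=ltr_cfg.min_orf_aa)
            for c in candidates
        ]
        elements = ltr_detect.filter_and_classify(
            candidates, genome, reference, min_hit_score=float(cfg.get("min_hit_score", 100.0))
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"ltr_candidates={len(candidates)} ltr_retained={len(elements)}")
    ltr_annotations = [
        TeAnnotation(e.element, "LTR", e.classification, e.classification_score, "ltr_detect")
        for e in elements
    ]
    write_annotations(ltr_annotations, out / "ltr_elements.gff3", format="GFF3")

    # --- non-LTR stage on the LTR-masked genome ---------------------------
    stage = "nonltr"
    try:
        masked_for_nonltr = mask_intervals(genome, [e.element for e in elements], mode="hard")
        nonltr_elements = nonltr_detect.detect_nonltr(
            masked_for_nonltr, min_orf_len=int(cfg.get("nonltr", {}).get("min_orf_len", 500))
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"nonltr_elements={len(nonltr_elements)}")
    nonltr_annotations = [
        TeAnnotation(e.orf.interval, "LINE", e.clade, e.rt_score, "nonltr_detect")
        for e in nonltr_elements
    ]
    write_annotations(nonltr_annotations, out / "nonltr_elements.gff3", format="GFF3")

    # --- Class II stage ---------------------------------------------------
    stage = "class2"
    try:
        mite_cfg = class2_detect.MiteConfig(**cfg.get("mite", {}))
        mites = class2_detect.find_mites(genome, mite_cfg)
        mites, mite_reps = class2_detect.cluster_mite_families(mites, genome, reference)
        hel_cfg = class2_detect.HelitronConfig(**cfg.get("helitron", {}))
        five, three = class2_detect.score_helitron_termini(genome, hel_cfg)
        helitrons = class2_detect.pair_helitrons(five, three, genome, hel_cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"mites={len(mites)} mite_families={len(mite_reps)} helitrons={len(helitrons)}")
    mite_annotations = [
        TeAnnotation(m.element, "MITE", m.family_id or "MITE", m.confidence, "mite_detect")
        for m in mites
    ]
    write_annotations(mite_annotations, out / "mites.gff3", format="GFF3")
    write_annotations(helitrons, out / "helitrons.gff3", format="GFF3")
    with open(out / "mite_families.tsv", "w") as fh:
        fh.write("family_id\trepresentative_locus\tmembers\n")
        for fam_id in sorted(mite_reps):
            rep = mite_reps[fam_id]
            members = sum(1 for m in mites if m.family_id == fam_id)
            fh.write(f"{fam_id}\t{rep.element.start}-{rep.element.end}\t{members}\n")

    # --- library assembly -------------------------------------------------
    stage = "library"
    try:
        entries: list[RepeatEntry] = []
        for i, e in enumerate(elements):
            entries.append(
                RepeatEntry(
                    f"LTR_element_{i}#LTR/{e.classification}",
                    genome.residues[e.element.start : e.element.end],
                    "LTR",
                    e.classification,
                    "ltr_detect",
                )
            )
        for i, e in enumerate(nonltr_elements):
            iv = e.orf.interval
            entries.append(
                RepeatEntry(
                    f"nonLTR_element_{i}#LINE/{e.clade}",
                    genome.residues[iv.start : iv.end],
                    "LINE",
                    e.clade,
                    "nonltr_detect",
                )
            )
        for fam_id in sorted(mite_reps):
            rep = mite_reps[fam_id]
            entries.append(
                RepeatEntry(
                    f"{fam_id}#MITE/{fam_id}",
                    genome.residues[rep.element.start : rep.element.end],
                    "MITE",
                    fam_id,
                    "mite_detect",
                )
            )
        seen_clusters = set()
        for h in helitrons:
            if h.superfamily in seen_clusters:
                continue
            seen_clusters.add(h.superfamily)
            entries.append(
                RepeatEntry(
                    f"{h.superfamily}#Helitron/{h.superfamily}",
                    genome.residues[h.interval.start : h.interval.end],
                    "Helitron",
                    h.superfamily,
                    "helitron_scan",
                )
            )
        entries.extend(reference.entries)
        lib, removed = dedup_library(entries)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"library_entries={len(lib)} duplicates_removed={removed}")
    lib.to_fasta(out / "library.fasta")

    # --- annotation / masking --------------------------------------------
    stage = "annotate"
    try:
        mask_cfg = MaskConfig(**cfg.get("mask", {}))
        annotations, masked = annotate_genome(genome, lib, mask_cfg)
        aux_path = cfg.get("aux_library")
        if aux_path:
            aux = RepeatLibrary.from_fasta(aux_path)
            extra, masked = annotate_genome(masked, aux, mask_cfg)
            annotations = sorted(
                annotations + extra, key=lambda a: (a.interval.seq_id, a.interval.start)
            )
        summary = summarize(annotations, genome.length)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"annotations={len(annotations)} masked_bp={summary.total_bp}")
    write_annotations(annotations, out / "annotations.tsv", format="TSV")
    write_annotations(annotations, out / "annotations.bed", format="BED")
    write_fasta([masked], out / "masked_genome.fasta")
    summary.table.to_csv(out / "summary.tsv", sep="\t", index=False)

    # --- clustering, gene conversion, dating ------------------------------
    stage = "dating"
    try:
        geneconv_cfg = cfg.get("geneconv", {})
        ages = date_ltr_elements(
            elements,
            genome,
            n_permutations=int(geneconv_cfg.get("n_permutations", 2000)),
            alpha=float(geneconv_cfg.get("alpha", 0.05)),
            seed=seed,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    log_lines.append(f"dated_elements={len(ages)}")
    with open(out / "ages.tsv", "w") as fh:
        fh.write("element_id\tcluster\td_raw\td_corrected\tkappa\tage_my\tflags\n")
        for eid, cluster_id, est in ages:
            fh.write(
                f"{eid}\t{cluster_id}\t{est.d_raw:.6f}\t{est.d_corrected:.6f}\t"
                f"{est.kappa:.4f}\t{est.age_my:.4f}\t{','.join(est.flags) or '.'}\n"
            )
    # age histogram binned at 0.5 My on the uncorrected divergences
    bin_my = 0.5
    counts: dict[int, int] = defaultdict(int)
    for _, _, est in ages:
        if "saturated" not in est.flags:
            r = est.mu_per_generation / est.generation_years
            counts[int((est.d_raw / (2 * r)) / (bin_my * 1e6))] += 1
    with open(out / "age_histogram.tsv", "w") as fh:
        fh.write("bin_start_my\tbin_end_my\tcount\n")
        for b in sorted(counts):
            fh.write(f"{b * bin_my:.1f}\t{(b + 1) * bin_my:.1f}\t{counts[b]}\n")

    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out


def date_ltr_elements(
    elements: Sequence[ltr_detect.LtrElement],
    genome: GenomeSequence,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[tuple[str, str, evodynamics.AgeEstimate]]:
    """Cluster full elements (80-80-80), then date each element's LTR pair
    within its cluster context with gene-conversion correction."""
    if not elements:
        return []
    seqs = {
        f"elt{i}": genome.residues[e.element.start : e.element.end]
        for i, e in enumerate(elements)
    }
    clusters, singletons = evodynamics.cluster_80_80_80(seqs)
    membership: dict[str, str] = {}
    for ci, members in enumerate(clusters):
        for m in members:
            membership[m] = f"cluster_{ci}"
    for s in singletons:
        membership[s] = "singleton"
    by_cluster: dict[str, list[str]] = defaultdict(list)
    for eid, cl in membership.items():
        by_cluster[cl].append(eid)
    results = []
    for i, element in enumerate(elements):
        eid = f"elt{i}"
        ltr5 = genome.residues[element.ltr5.start : element.ltr5.end]
        ltr3 = genome.residues[element.ltr3.start : element.ltr3.end]
        res = align_pair(ltr5, ltr3, mode="global")
        a5, a3 = res.a_aligned, res.b_aligned
        cluster_id = membership[eid]
        context: list[str] = []
        if cluster_id != "singleton" and len(by_cluster[cluster_id]) >= 3:
            for other in by_cluster[cluster_id]:
                if other == eid:
                    continue
                j = int(other[3:])
                o5 = genome.residues[elements[j].ltr5.start : elements[j].ltr5.end]
                aligned = align_pair(a5.replace("-", ""), o5, mode="global")
                # project the context LTR onto the pair alignment columns
                proj = _project(a5, aligned.a_aligned, aligned.b_aligned)
                context.append(proj)
        scan = evodynamics.detect_pair_tracts(
            a5, a3, context, element_id=eid,
            n_permutations=n_permutations, alpha=alpha, seed=seed + i,
        )
        corr = evodynamics.corrected_divergence(a5, a3, scan.tracts)
        flags = []
        if corr.fallback:
            flags.append("tracts_cover_alignment")
        if corr.saturated:
            flags.append("saturated")
        if scan.no_context:
            flags.append("no_context")
        est = evodynamics.estimate_age(
            eid, corr.d_corrected, d_raw=corr.d_raw, kappa=corr.kappa, flags=flags
        )
        results.append((eid, cluster_id, est))
    return results


def _project(pair_row: str, aligned_ref: str, aligned_other: str) -> str:
    """Map an outgroup sequence onto the columns of a pair alignment row.

    ``aligned_ref``/``aligned_other`` align the ungapped pair row to the
    outgroup; columns of the pair alignment where the reference is gapped
    get gaps, others take the outgroup residue aligned to that reference
    base (or a gap where the outgroup has none).
    """
    # residue index of ref -> outgroup char
    ref_to_other: dict[int, str] = {}
    ri = 0
    for rc, oc in zip(aligned_ref, aligned_other):
        if rc != "-":
            ref_to_other[ri] = oc if oc != "-" else "-"
            ri += 1
    out = []
    ri = 0
    for c in pair_row:
        if c == "-":
            out.append("-")
        else:
            out.append(ref_to_other.get(ri, "-"))
            ri += 1
    return "".join(out)
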