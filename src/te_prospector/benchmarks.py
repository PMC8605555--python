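"""End-to-end benchmark computations on seeded synthetic genomes.

These routines regenerate their inputs from scratch (via the synthetic
module), run the detectors or the whole pipeline, and measure recovery,
dating accuracy and statistical calibration.  They back the acceptance
checks and the worked examples.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from . import class2_detect, evodynamics, ltr_detect, nonltr_detect
from .annotate import date_ltr_elements, run_pipeline
from .evaluate import boundary_error, recall
from .hky import evolve
from .seqio import Interval
from .synthetic import PlantSpec, generate_genome, standard_fixture


def structural_recall(seeds: Sequence[int], max_boundary_error: int = 10) -> dict[str, tuple[int, int]]:
    """Per-class (recovered, total) of each structural detector on the
    standard fixture across seeds."""
    totals = {k: [0, 0] for k in ("LTR_RT", "MITE", "HELITRON", "LINE")}

    def add(kind, h, t):
        totals[kind][0] += h
        totals[kind][1] += t

    for seed in seeds:
        syn = standard_fixture(seed)
        cands = ltr_detect.find_ltr_candidates(syn.genome)
        add("LTR_RT", *recall(syn.truth, [c.element for c in cands], "LTR_RT", max_boundary_error))
        mites = class2_detect.find_mites(syn.genome)
        add("MITE", *recall(syn.truth, [m.element for m in mites], "MITE", max_boundary_error))
        five, three = class2_detect.score_helitron_termini(syn.genome)
        hels = class2_detect.pair_helitrons(five, three, syn.genome)
        add("HELITRON", *recall(syn.truth, [h.interval for h in hels], "HELITRON", max_boundary_error))
        lines = nonltr_detect.detect_nonltr(syn.genome)
        truth_lines = [t for t in syn.truth if t.element_kind == "LINE"]
        hit = sum(
            any(
                e.orf.interval.start >= t.interval.start
                and e.orf.interval.end <= t.interval.end
                for e in lines
            )
            for t in truth_lines
        )
        add("LINE", hit, len(truth_lines))
    return {k: (v[0], v[1]) for k, v in totals.items()}


def end_to_end_recall(
    seeds: Sequence[int], work_dir: str | Path, max_boundary_error: int = 10
) -> tuple[int, int]:
    """(recovered, total) planted elements of all classes recovered by the
    full pipeline's final annotation set."""
    work_dir = Path(work_dir)
    hit = tot = 0
    for seed in seeds:
        cfg = {
            "seed": int(seed),
            "synthetic": {"length": 100_000},
            "geneconv": {"n_permutations": 300},
        }
        out = run_pipeline(cfg, output_dir=work_dir / f"e2e_{seed}")
        syn = standard_fixture(int(seed))
        detected = []
        with open(out / "annotations.bed") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                detected.append(Interval(f[0], int(f[1]), int(f[2])))
        for t in syn.truth:
            # LINE surrogates are recovered by their coding ORF, which sits
            # inside the planted element; match those by containment
            if t.element_kind == "LINE":
                if any(
                    d.start >= t.interval.start and d.end <= t.interval.end
                    and d.length >= 500
                    for d in detected
                ):
                    hit += 1
            elif any(boundary_error(d, t.interval) <= max_boundary_error for d in detected):
                hit += 1
            tot += 1
    return hit, tot


def dating_regression(seed: int, n_elements: int = 20) -> dict[str, float]:
    """Regress estimated insertion ages on planted truth ages.

    Plants ``n_elements`` LTR-RTs with divergences cycling 0.01..0.10,
    runs structural detection plus cluster-aware dating, and fits an
    ordinary least-squares line through the matched (truth, estimate)
    age pairs (in My).  LTRs are 1.2 kb: the sampling noise of a pairwise
    distance scales as sqrt(d / L), so dating accuracy is a property of
    full-length LTRs, not of arbitrarily short repeats.
    """
    divergences = tuple(0.01 * (i % 10 + 1) for i in range(n_elements))
    spec = PlantSpec(
        "LTR_RT", n_elements, divergence=divergences, n_families=2, ltr_len=1200
    )
    syn = generate_genome(180_000, [spec], seed=seed)
    cands = ltr_detect.find_ltr_candidates(syn.genome)
    ages = date_ltr_elements(cands, syn.genome, n_permutations=300, seed=seed)
    by_candidate = {eid: est for eid, _, est in ages}
    rate_per_year = evodynamics.MU_PER_GENERATION / evodynamics.GENERATION_YEARS
    pairs = []
    for t in syn.truth:
        for i, c in enumerate(cands):
            if boundary_error(c.element, t.interval) <= 10:
                est = by_candidate[f"elt{i}"]
                # default reporting convention: ages from the unaltered
                # divergence (the corrected value is emitted alongside)
                age_my = est.d_raw / (2 * rate_per_year) / 1e6
                pairs.append((t.age_years / 1e6, age_my))
                break
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return {"slope": float(slope), "r2": r2, "n": len(pairs), "total": n_elements}


def geneconv_null_fp_rate(
    n_pairs: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    n_permutations: int = 1000,
    d_pair: float = 0.05,
) -> float:
    """Fraction of uniformly diverged (tract-free) LTR pairs for which at
    least one gene-conversion tract is accepted at the given alpha."""
    rng = np.random.default_rng(seed)
    pi = [0.25] * 4
    fp = 0
    for i in range(n_pairs):
        anc = "".join(rng.choice(list("ACGT"), size=400))
        a = evolve(anc, d_pair / 2, 2.0, pi, rng)
        b = evolve(anc, d_pair / 2, 2.0, pi, rng)
        ctx = [evolve(anc, 0.12, 2.0, pi, rng) for _ in range(2)]
        scan = evodynamics.detect_pair_tracts(
            a, b, ctx, n_permutations=n_permutations, alpha=alpha, seed=seed + i + 1
        )
        fp += bool(scan.tracts)
    return fp / n_pairs


def determinism_check(work_dir: str | Path, seed: int = 5) -> bool:
    """Two pipeline runs with identical config and seed must produce
    byte-identical summary and age tables."""
    work_dir = Path(work_dir)
    cfg = {
        "seed": int(seed),
        "geneconv": {"n_permutations": 200},
        "synthetic": {
            "length": 40_000,
            "plants": [
                {"element_kind": "LTR_RT", "count": 3, "divergence": [0.02, 0.06, 0.04]},
                {"element_kind": "MITE", "count": 3},
                {"element_kind": "HELITRON", "count": 2},
                {"element_kind": "LINE", "count": 2},
            ],
        },
    }
    out1 = run_pipeline(cfg, output_dir=work_dir / "det_run1")
    out2 = run_pipeline(cfg, output_dir=work_dir / "det_run2")
    names = ("summary.tsv", "ages.tsv")
    return all((out1 / n).read_bytes() == (out2 / n).read_bytes() for n in names)
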