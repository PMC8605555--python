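"""Structural LTR-RT discovery, internal annotation, homology filtering."""

import numpy as np
import pytest

from te_prospector.evaluate import recall
from te_prospector.library import RepeatLibrary
from te_prospector.ltr_detect import (
    LtrElement,
    LtrSearchConfig,
    annotate_internal,
    filter_and_classify,
    find_ltr_candidates,
)
from te_prospector.nonltr_detect import builtin_domain_profiles
from te_prospector.seqio import GenomeSequence, Interval
from te_prospector.synthetic import PlantSpec, generate_background, generate_genome


def _single_ltr_genome(divergence, seed=0, ltr_len=300, internal_len=2000, tsd_len=5):
    spec = PlantSpec(
        "LTR_RT",
        1,
        ltr_len=ltr_len,
        internal_len=internal_len,
        tsd_len=tsd_len,
        divergence=divergence,
    )
    return generate_genome(20_000, [spec], seed=seed)


class TestFindLtrCandidates:
    def test_planted_element_recovered_with_tight_boundaries(self):
        syn = _single_ltr_genome(0.0, seed=2)
        truth = syn.truth[0]
        cands = find_ltr_candidates(syn.genome)
        assert len(cands) == 1
        c = cands[0]
        assert abs(c.element.start - truth.interval.start) <= 5
        assert abs(c.element.end - truth.interval.end) <= 5
        assert c.tsd is not None and len(c.tsd[0]) >= 4

    def test_background_yields_no_candidates(self):
        """i.i.d. background over 10 seeds: no direct-repeat pair with TSD
        survives the default config."""
        total = 0
        for s in range(10):
            total += len(find_ltr_candidates(generate_background(50_000, 0.41, 100 + s)))
        assert total == 0

    def test_low_identity_pair_not_reported(self):
        """LTR identity ~0.70 (divergence far beyond the 0.85 floor)."""
        syn = _single_ltr_genome(0.5, seed=3)
        cands = find_ltr_candidates(syn.genome)
        truth = syn.truth[0]
        assert not any(c.element.overlaps(truth.interval) for c in cands)

    def test_recall_on_standard_condition(self, std_genomes):
        """>= 90% of planted intact elements (d <= 0.10) recovered with
        boundary error <= 10 bp over 5 seeds."""
        hit = tot = 0
        for syn in std_genomes.values():
            cands = find_ltr_candidates(syn.genome)
            h, t = recall(syn.truth, [c.element for c in cands], kind="LTR_RT")
            hit, tot = hit + h, tot + t
        assert hit / tot >= 0.90

    def test_reported_elements_satisfy_invariants(self, std_genomes):
        cfg = LtrSearchConfig()
        for syn in list(std_genomes.values())[:2]:
            for c in find_ltr_candidates(syn.genome, cfg):
                assert c.ltr5.end <= c.ltr3.start
                assert cfg.min_ltr_len <= c.ltr5.length <= cfg.max_ltr_len
                assert cfg.min_ltr_len <= c.ltr3.length <= cfg.max_ltr_len
                assert c.ltr_identity >= cfg.min_ltr_identity
                assert c.tsd[0] == c.tsd[1]
                assert c.length <= cfg.max_element_len

    def test_candidates_sorted_and_non_overlapping(self, std_genomes):
        cands = find_ltr_candidates(std_genomes[1].genome)
        for a, b in zip(cands, cands[1:]):
            assert a.element.start <= b.element.start
            assert not a.element.overlaps(b.element)


class TestAnnotateInternal:
    def test_planted_orf_and_rt_domain_found(self):
        syn = _single_ltr_genome(0.0, seed=4)
        cand = find_ltr_candidates(syn.genome)[0]
        out = annotate_internal(cand, syn.genome, builtin_domain_profiles())
        assert out.internal_orfs
        assert any(name == "RT" for name, _ in out.domain_hits)

    def test_random_internal_region_has_no_domain_hits(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        element = LtrElement(
            element=Interval("g", 0, 4000),
            ltr5=Interval("g", 0, 300),
            ltr3=Interval("g", 3700, 4000),
            ltr_identity=1.0,
        )
        out = annotate_internal(element, GenomeSequence("g", seq), builtin_domain_profiles())
        assert out.domain_hits == ()

    def test_short_internal_region_gives_empty_orf_list(self):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        element = LtrElement(
            element=Interval("g", 0, 800),
            ltr5=Interval("g", 0, 300),
            ltr3=Interval("g", 500, 800),
            ltr_identity=1.0,
        )
        out = annotate_internal(element, GenomeSequence("g", seq), builtin_domain_profiles())
        assert out.internal_orfs == ()


class TestFilterAndClassify:
    @pytest.fixture
    def planted(self):
        syn = _single_ltr_genome(0.02, seed=6)
        cand = find_ltr_candidates(syn.genome)[0]
        return syn, cand

    def test_homologous_candidate_retained_and_classified(self, planted):
        syn, cand = planted
        lib = RepeatLibrary.from_entries(
            [("ex#LTR/ERVL", syn.library_entries[0][1], "LTR", "ERVL")]
        )
        kept = filter_and_classify([cand], syn.genome, lib)
        assert len(kept) == 1 and kept[0].classification == "ERVL"

    def test_unrelated_candidate_dropped(self, planted):
        syn, cand = planted
        rng = np.random.default_rng(12)
        lib = RepeatLibrary.from_entries(
            [("decoy#LTR/ERV1", "".join(rng.choice(list("ACGT"), size=1000)), "LTR", "ERV1")]
        )
        assert filter_and_classify([cand], syn.genome, lib) == []

    def test_equal_score_tie_breaks_to_longer_alignment(self, planted):
        syn, cand = planted
        region = syn.genome.residues[cand.element.start : cand.element.start + 200]
        # entry A: 100 bp exact (score 200); entry B: 110 bp with 4 interior
        # mismatches (106*2 - 4*3 = 200) -> same score, longer alignment
        entry_a = region[:100]
        b = list(region[:110])
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for pos in (20, 40, 60, 80):
            b[pos] = flip[b[pos]]
        lib = RepeatLibrary.from_entries(
            [
                ("a_short#LTR/ERV1", entry_a, "LTR", "ERV1"),
                ("b_long#LTR/ERVL", "".join(b), "LTR", "ERVL"),
            ]
        )
        kept = filter_and_classify([cand], syn.genome, lib, min_hit_score=150)
        assert kept[0].classification == "ERVL"

    def test_empty_library_errors(self, planted):
        syn, cand = planted
        lib = RepeatLibrary.from_entries([("x#MITE/hAT", "ACGTACGT" * 20, "MITE", "hAT")])
        with pytest.raises(ValueError):
            filter_and_classify([cand], syn.genome, lib)

    def test_retention_monotone_in_score_cutoff(self, std_genomes):
        syn = std_genomes[1]
        cands = find_ltr_candidates(syn.genome)
        lib = RepeatLibrary.from_entries(syn.library_entries)
        counts = [
            len(filter_and_classify(cands, syn.genome, lib, min_hit_score=s))
            for s in (50, 200, 1000, 4000)
        ]
        assert counts == sorted(counts, reverse=True)
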