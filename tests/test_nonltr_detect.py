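"""Long-ORF extraction and RT/APE profile scoring for non-LTR elements."""

import numpy as np
import pytest

from te_prospector.evaluate import overlap_recall
from te_prospector.nonltr_detect import (
    AA_ALPHABET,
    RT_MARKERS,
    ProfileHit,
    ScoringProfile,
    build_profile,
    builtin_ape_profile,
    builtin_rt_profiles,
    detect_nonltr,
    extract_long_orfs,
    read_profile,
    score_profile,
    write_profile,
)
from te_prospector.seqio import GenomeSequence, Interval, mask_intervals
from te_prospector.synthetic import PlantSpec, generate_background, generate_genome


class TestExtractLongOrfs:
    def test_planted_orf_reported_with_frame_and_bounds(self, std_genomes):
        syn = std_genomes[1]
        lines = [t for t in syn.truth if t.element_kind == "LINE"]
        orfs = extract_long_orfs(syn.genome)
        for t in lines:
            inside = [
                o
                for o in orfs
                if o.interval.start >= t.interval.start and o.interval.end <= t.interval.end
            ]
            assert inside, f"no long ORF inside planted LINE at {t.interval.start}"
            assert all(o.interval.length >= 500 for o in inside)
            assert all(o.frame in (1, 2, 3, -1, -2, -3) for o in inside)

    def test_short_orf_excluded_at_default(self):
        # 480 bp ORF (160 codons) bounded by stops: below the 500 bp floor
        rng = np.random.default_rng(0)
        from te_prospector.synthetic import _random_orf

        orf = _random_orf(rng, 160, [])
        pad = "".join(rng.choice(list("ACGT"), size=200))
        genome = GenomeSequence("g", pad + orf + pad)
        planted_len = 160 * 3
        assert not any(o.interval.length == planted_len for o in extract_long_orfs(genome))
        # positive control: a lower floor recovers it
        assert any(
            o.interval.length == planted_len
            for o in extract_long_orfs(genome, min_len=400)
        )

    def test_fully_masked_genome_is_empty(self):
        genome = GenomeSequence("g", "N" * 3000)
        assert extract_long_orfs(genome) == []

    def test_no_orf_overlaps_masked_run(self, std_genomes):
        syn = std_genomes[2]
        block = Interval(syn.genome.id, 10_000, 60_000)
        masked = mask_intervals(syn.genome, [block], mode="hard")
        for o in extract_long_orfs(masked):
            assert not o.interval.overlaps(block)


class TestScoreProfile:
    @pytest.fixture
    def profile(self):
        return build_profile("RT_test", RT_MARKERS["L1"])

    def test_consensus_attains_matrix_maximum(self, profile):
        hit = score_profile(profile.consensus, profile)
        assert hit.score == pytest.approx(profile.max_score)
        assert hit.offset == 0

    def test_single_substitution_scores_strictly_lower(self, profile):
        consensus = profile.consensus
        mutated = ("A" if consensus[0] != "A" else "C") + consensus[1:]
        assert score_profile(mutated, profile).score < profile.max_score

    def test_consensus_ranks_first_among_random_placements(self, profile):
        rng = np.random.default_rng(1)
        random_scores = []
        for _ in range(1000):
            seq = "".join(rng.choice(list(AA_ALPHABET), size=profile.length))
            random_scores.append(score_profile(seq, profile).score)
        assert max(random_scores) < profile.max_score

    def test_shorter_than_profile_is_defined_no_placement(self, profile):
        hit = score_profile("MK", profile)
        assert hit == ProfileHit(float("-inf"), None)

    def test_embedded_motif_located(self, profile):
        protein = "G" * 30 + profile.consensus + "G" * 30
        hit = score_profile(protein, profile)
        assert hit.offset == 30 and hit.score == pytest.approx(profile.max_score)


def test_profile_tsv_round_trip(tmp_path):
    prof = build_profile("RT_L1", RT_MARKERS["L1"])
    path = tmp_path / "rt_l1.tsv"
    write_profile(prof, path)
    back = read_profile(path)
    assert back.label == prof.label
    assert back.threshold == pytest.approx(prof.threshold, rel=1e-5)
    np.testing.assert_allclose(back.matrix, prof.matrix, rtol=1e-5)


class TestDetectNonLtr:
    def test_planted_l1_detected_and_classified(self, std_genomes):
        syn = std_genomes[1]
        elements = detect_nonltr(syn.genome)
        lines = [t for t in syn.truth if t.element_kind == "LINE"]
        for t in lines:
            hit = [
                e
                for e in elements
                if e.orf.interval.start >= t.interval.start
                and e.orf.interval.end <= t.interval.end
            ]
            assert hit and hit[0].clade == "L1"
            assert hit[0].ape_hit is not None  # APE marker planted alongside

    def test_random_genome_yields_nothing(self):
        for s in range(5):
            bg = generate_background(50_000, 0.41, 300 + s)
            assert detect_nonltr(bg) == []

    def test_masking_respected(self, std_genomes):
        syn = std_genomes[1]
        lines = [t.interval for t in syn.truth if t.element_kind == "LINE"]
        masked = mask_intervals(syn.genome, lines, mode="hard")
        elements = detect_nonltr(masked)
        for e in elements:
            assert not any(e.orf.interval.overlaps(iv) for iv in lines)

    def test_profile_order_invariance(self, std_genomes):
        syn = std_genomes[2]
        profiles = builtin_rt_profiles()
        fwd = detect_nonltr(syn.genome, profiles, builtin_ape_profile())
        rev = detect_nonltr(
            syn.genome, dict(reversed(list(profiles.items()))), builtin_ape_profile()
        )
        assert [(e.orf.interval, e.clade) for e in fwd] == [
            (e.orf.interval, e.clade) for e in rev
        ]

    def test_equal_scores_tie_to_lexicographic_clade_with_flag(self):
        """An ORF carrying two clade markers verbatim scores both profiles at
        their maxima (equal by construction) -> first clade, flagged."""
        rng = np.random.default_rng(5)
        from te_prospector.synthetic import _random_orf

        orf = _random_orf(rng, 200, [RT_MARKERS["RTE"], RT_MARKERS["Jockey"]])
        pad = "".join(rng.choice(list("ACGT"), size=100))
        genome = GenomeSequence("g", pad + orf + pad)
        elements = detect_nonltr(genome)
        assert len(elements) == 1
        assert elements[0].clade == "Jockey"  # lexicographically before RTE
        assert elements[0].ambiguous

    def test_no_profiles_is_configuration_error(self):
        with pytest.raises(ValueError):
            detect_nonltr(GenomeSequence("g", "ACGT" * 300), rt_profiles={})

    def test_recall_on_planted_orfs(self):
        """>= 90% of marker-bearing planted ORFs recovered, 5 seeds x 10."""
        hit = tot = 0
        for seed in range(5):
            syn = generate_genome(
                40_000, [PlantSpec("LINE", 10, n_families=2)], seed=800 + seed
            )
            elements = detect_nonltr(syn.genome)
            h, t = overlap_recall(
                syn.truth, [e.orf.interval for e in elements], kind="LINE", min_overlap=0.3
            )
            hit, tot = hit + h, tot + t
        assert tot == 50 and hit / tot >= 0.90

    def test_elements_sorted_by_position(self, std_genomes):
        elements = detect_nonltr(std_genomes[3].genome)
        starts = [e.orf.interval.start for e in elements]
        assert starts == sorted(starts)
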