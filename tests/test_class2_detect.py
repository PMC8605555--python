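"""MITE inverted-repeat detection and Helitron terminal-signature scoring."""

import numpy as np
import pytest

from te_prospector.class2_detect import (
    HelitronConfig,
    MiteConfig,
    cluster_mite_families,
    find_mites,
    mite_confidence,
    pair_helitrons,
    score_helitron_termini,
)
from te_prospector.evaluate import recall
from te_prospector.seqio import GenomeSequence, reverse_complement
from te_prospector.synthetic import (
    HELITRON_FIVE_PRIME_MOTIF,
    PlantSpec,
    generate_background,
    generate_genome,
)


def _mite_genome(tir_len=14, tsd="TAA", total=180, seed=0):
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=3000))
    tir = "".join(rng.choice(list("ACGT"), size=tir_len))
    interior = "".join(rng.choice(list("ACGT"), size=total - 2 * tir_len))
    element = tir + interior + reverse_complement(tir)
    pos = 1500
    seq = bg[:pos] + tsd + element + tsd + bg[pos:]
    start = pos + len(tsd)
    return GenomeSequence("g", seq), start, start + total


class TestFindMites:
    def test_planted_mite_detected(self):
        genome, start, end = _mite_genome(tir_len=14, tsd="TAA", total=180)
        cands = [c for c in find_mites(genome) if c.element.start == start]
        assert cands, "planted MITE not found"
        c = cands[0]
        assert c.element.end == end
        assert len(c.tsd) == 3
        assert c.confidence >= 0.9

    def test_element_below_length_floor_rejected(self):
        genome, start, end = _mite_genome(tir_len=15, tsd="TA", total=40)
        assert not any(c.element.start == start for c in find_mites(genome))

    def test_self_consistency_of_emitted_candidates(self, std_genomes):
        """Re-validating every emitted candidate from raw sequence
        reproduces its stored TIR mismatch structure, TSD and confidence."""
        cfg = MiteConfig()
        for syn in list(std_genomes.values())[:2]:
            seq = syn.genome.residues
            for c in find_mites(syn.genome, cfg):
                arm5 = seq[c.tir5.start : c.tir5.end]
                arm3 = seq[c.tir3.start : c.tir3.end]
                assert len(arm5) == len(arm3) == c.tir_len
                mism = sum(
                    1 for a, b in zip(arm5, reverse_complement(arm3)) if a != b
                )
                assert mism / c.tir_len <= cfg.max_tir_mismatch_fraction
                assert c.tir_identity == pytest.approx(1 - mism / c.tir_len)
                L = len(c.tsd)
                assert L in cfg.tsd_lengths
                s, e = c.element.start, c.element.end
                assert seq[s - L : s] == c.tsd == seq[e : e + L]
                assert c.confidence == pytest.approx(
                    mite_confidence(c.tir_identity, c.tir_len)
                )
                assert c.confidence >= cfg.confidence_threshold

    def test_planted_recall(self, std_genomes):
        hit = tot = 0
        for syn in std_genomes.values():
            cands = find_mites(syn.genome)
            h, t = recall(syn.truth, [c.element for c in cands], kind="MITE")
            hit, tot = hit + h, tot + t
        assert hit / tot >= 0.90

    def test_background_emissions_stay_below_planted_confidence(self):
        """The confidence score separates structure from chance: planted
        perfect-TIR MITEs score 1.0 while i.i.d.-background emissions stay
        clearly lower (their TIRs arise from ~9 bp chance seeds)."""
        confs = []
        for s in range(5):
            bg = generate_background(50_000, 0.41, 200 + s)
            confs += [c.confidence for c in find_mites(bg)]
        assert all(c < 0.95 for c in confs)
        genome, start, _ = _mite_genome(tir_len=15)
        planted = [c for c in find_mites(genome) if c.element.start == start]
        assert planted and planted[0].confidence == 1.0


class TestMiteFamilies:
    def test_five_copies_form_one_family(self):
        syn = generate_genome(30_000, [PlantSpec("MITE", 5, n_families=1)], seed=3)
        cands = find_mites(syn.genome)
        labeled, reps = cluster_mite_families(cands, syn.genome)
        starts = {t.interval.start for t in syn.truth}
        planted = [c for c in labeled if c.element.start in starts]
        assert len(planted) == 5
        assert len({c.family_id for c in planted}) == 1

    def test_unrelated_mites_form_separate_families(self):
        syn = generate_genome(30_000, [PlantSpec("MITE", 2, n_families=2)], seed=4)
        cands = find_mites(syn.genome)
        labeled, _ = cluster_mite_families(cands, syn.genome)
        starts = {t.interval.start for t in syn.truth}
        planted = [c for c in labeled if c.element.start in starts]
        assert len({c.family_id for c in planted}) == 2

    def test_empty_candidates_give_empty_output(self):
        labeled, reps = cluster_mite_families([], GenomeSequence("g", "ACGT" * 100))
        assert labeled == [] and reps == {}


class TestHelitronTermini:
    def test_canonical_five_prime_scores_six(self):
        # A | TC : w_tc + w_flank_a = 4 + 2 = 6
        genome = GenomeSequence("g", "GGGGATCGGGGGGGGG")
        five, _ = score_helitron_termini(genome)
        assert any(h.position == 5 and h.score == 6 for h in five)

    def test_ctgg_without_hairpin_scores_at_most_four(self):
        # CTGG is a CTRR; without a hairpin the 3' score is 3 (+1 with T) < 6
        genome = GenomeSequence("g", "G" * 60 + "CTGG" + "T" + "G" * 20)
        _, three = score_helitron_termini(genome)
        assert three == []

    def test_full_canonical_three_prime_scores_eight(self):
        rng = np.random.default_rng(6)
        stem = "".join(rng.choice(list("ACGT"), size=12))
        hairpin = stem + "AACCG" + reverse_complement(stem)
        seq = "G" * 40 + hairpin + "ACGTACGTAC" + "CTAG" + "T" + "G" * 20
        _, three = score_helitron_termini(GenomeSequence("g", seq))
        assert any(h.score == 8 and set(h.features) == {"CTRR", "flank_T", "hairpin"} for h in three)

    def test_scores_are_bounded_integers(self, std_genomes):
        cfg = HelitronConfig()
        five, three = score_helitron_termini(std_genomes[1].genome, cfg)
        assert all(isinstance(h.score, int) for h in five + three)
        assert all(h.score <= cfg.w_tc + cfg.w_flank_a for h in five)
        assert all(h.score <= cfg.w_ctrr + cfg.w_flank_t + cfg.w_hairpin for h in three)

    def test_raising_threshold_never_increases_hits(self, std_genomes):
        genome = std_genomes[1].genome
        counts = []
        for thr in (6, 7, 8):
            cfg = HelitronConfig(threshold=thr)
            five, three = score_helitron_termini(genome, cfg)
            counts.append(len(five) + len(three))
        assert counts == sorted(counts, reverse=True)

    def test_threshold_above_max_is_invalid(self):
        with pytest.raises(ValueError):
            HelitronConfig(threshold=9)


class TestPairHelitrons:
    def test_planted_helitron_recovered_with_tight_boundaries(self):
        syn = generate_genome(20_000, [PlantSpec("HELITRON", 1)], seed=5)
        t = syn.truth[0]
        five, three = score_helitron_termini(syn.genome)
        anns = pair_helitrons(five, three, syn.genome)
        assert len(anns) == 1
        assert abs(anns[0].interval.start - t.interval.start) <= 5
        assert abs(anns[0].interval.end - t.interval.end) <= 5

    def test_five_prime_without_reachable_three_prime_dropped(self):
        seq = "GGGA" + HELITRON_FIVE_PRIME_MOTIF + "G" * 300
        five, three = score_helitron_termini(GenomeSequence("g", seq))
        assert five and not three
        assert pair_helitrons(five, three, GenomeSequence("g", seq)) == []

    def test_identical_plants_share_one_cluster(self):
        syn = generate_genome(30_000, [PlantSpec("HELITRON", 3, n_families=1)], seed=6)
        five, three = score_helitron_termini(syn.genome)
        anns = pair_helitrons(five, three, syn.genome)
        assert len(anns) == 3
        assert len({a.superfamily for a in anns}) == 1

    def test_planted_recall(self, std_genomes):
        hit = tot = 0
        for syn in std_genomes.values():
            five, three = score_helitron_termini(syn.genome)
            anns = pair_helitrons(five, three, syn.genome)
            h, t = recall(syn.truth, [a.interval for a in anns], kind="HELITRON")
            hit, tot = hit + h, tot + t
        assert hit / tot >= 0.90
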