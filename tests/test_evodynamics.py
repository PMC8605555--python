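"""Alignment, 80-80-80 clustering, HKY85 distances, gene conversion, dating."""

import numpy as np
import pytest

from te_prospector.evodynamics import (
    ClusterRule,
    GeneConversionTract,
    align_pair,
    cluster_80_80_80,
    compare_length_distributions,
    corrected_divergence,
    detect_gene_conversion,
    detect_pair_tracts,
    estimate_age,
    hky85_distance,
    related_80_80_80,
)
from te_prospector.hky import evolve


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestAlignPair:
    def test_self_alignment(self):
        res = align_pair("ACGT", "ACGT")
        assert res.identity == 1.0 and res.aligned_length == 4

    def test_local_all_mismatch_is_empty(self):
        """No single-base match exists, so the best local score is 0 and the
        alignment is empty (exhaustive DP over the 4x4 grid has no positive
        cell)."""
        res = align_pair("AAAA", "TTTT", mode="local")
        assert res.score == 0.0 and res.aligned_length == 0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")

    def test_score_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = _random_seq(rng, 60), _random_seq(rng, 50)
            for mode in ("global", "local"):
                assert align_pair(a, b, mode).score == align_pair(b, a, mode).score

    def test_identity_symmetric_for_homologous_pairs(self):
        """Identity is argument-order invariant wherever the optimal
        alignment is unambiguous (homologous pairs); unrelated short pairs
        can have co-optimal tracebacks with differing column counts."""
        rng = np.random.default_rng(1)
        for _ in range(30):
            anc = _random_seq(rng, 200)
            a = evolve(anc, 0.05, 2.0, [0.25] * 4, rng)
            b = evolve(anc, 0.05, 2.0, [0.25] * 4, rng)
            assert align_pair(a, b, "local").identity == pytest.approx(
                align_pair(b, a, "local").identity
            )


def _closure_partition(n, edge):
    """Independent oracle: boolean-matrix transitive closure."""
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            adj[i, j] = adj[j, i] = edge(i, j)
    reach = adj.copy()
    for _ in range(n):
        reach = reach | (reach @ reach)
    groups = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = sorted(np.nonzero(reach[i])[0].tolist())
        seen.update(comp)
        groups.append([str(j) for j in comp])
    return groups


class TestCluster808080:
    def test_identical_pair_clusters(self):
        clusters, singles = cluster_80_80_80(["A" * 50 + "CGT" * 17, "A" * 50 + "CGT" * 17])
        assert clusters == [["0", "1"]] and singles == []

    def test_79_bp_identical_pair_stays_single(self):
        """Even perfect identity fails the 80 bp aligned-length minimum."""
        seq = "ACGTTGCA" * 9 + "ACGTTGC"  # 79 bp
        assert len(seq) == 79
        clusters, singles = cluster_80_80_80([seq, seq])
        assert clusters == [] and singles == ["0", "1"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ancestors = [_random_seq(rng, 120) for _ in range(3)]
        seqs = []
        for _ in range(12):
            pick = rng.integers(4)
            if pick < 3:
                seqs.append(evolve(ancestors[pick], 0.05, 2.0, [0.25] * 4, rng))
            else:
                seqs.append(_random_seq(rng, 120))
        rule = ClusterRule()
        clusters, singles = cluster_80_80_80(seqs, rule)
        got = sorted([sorted(c, key=int) for c in clusters] + [[s] for s in singles])
        want = sorted(
            _closure_partition(12, lambda i, j: related_80_80_80(seqs[i], seqs[j], rule))
        )
        assert got == want


class TestHky85Distance:
    def test_identical_pair_is_exactly_zero(self):
        seq = "ACGT" * 125
        assert hky85_distance(seq, seq).d == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        anc = _random_seq(rng, 400)
        a = evolve(anc, 0.05, 3.0, [0.25] * 4, rng)
        b = evolve(anc, 0.05, 3.0, [0.25] * 4, rng)
        assert hky85_distance(a, b).d == pytest.approx(hky85_distance(b, a).d, abs=1e-6)

    def test_jukes_cantor_limit(self):
        """Equal base frequencies, transition fraction 1/3 of differences
        (the JC expectation), p-distance 0.10: the HKY85 ML distance must
        sit within 0.005 of -(3/4) ln(1 - (4/3) 0.10) = 0.10732."""
        a = "ACGT" * 150
        b = list(a)
        ti = {"A": "G", "G": "A", "C": "T", "T": "C"}
        tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for k in range(60):
            site = 10 * k
            b[site] = ti[a[site]] if k % 3 == 0 else tv[a[site]]
        est = hky85_distance(a, "".join(b))
        assert est.d == pytest.approx(0.10732, abs=0.005)

    def test_parameter_recovery(self):
        """Pairs simulated at d=0.05, kappa=4: the mean estimate lands
        within 3 s.e. of the truth."""
        rng = np.random.default_rng(11)
        pi = [0.25] * 4
        ds = []
        for _ in range(200):
            anc = _random_seq(rng, 800)
            x = evolve(anc, 0.025, 4.0, pi, rng)
            y = evolve(anc, 0.025, 4.0, pi, rng)
            ds.append(hky85_distance(x, y).d)
        se = np.std(ds, ddof=1) / np.sqrt(len(ds))
        assert abs(np.mean(ds) - 0.05) <= 3 * se

    def test_saturated_pair_flagged(self):
        rng = np.random.default_rng(2)
        a = _random_seq(rng, 300)
        b = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[c] for c in a)
        est = hky85_distance(a, b)
        assert est.saturated


def _null_pair(rng, d_pair=0.05, d_out=0.12, length=400, n_context=2):
    anc = _random_seq(rng, length)
    pi = [0.25] * 4
    a = evolve(anc, d_pair / 2, 2.0, pi, rng)
    b = evolve(anc, d_pair / 2, 2.0, pi, rng)
    ctx = [evolve(anc, d_out, 2.0, pi, rng) for _ in range(n_context)]
    return a, b, ctx


class TestGeneConversion:
    def test_uniform_divergence_rarely_calls_tracts(self):
        rng = np.random.default_rng(21)
        hits = 0
        for i in range(20):
            a, b, ctx = _null_pair(rng)
            scan = detect_pair_tracts(a, b, ctx, n_permutations=500, seed=100 + i)
            hits += bool(scan.tracts)
        assert hits <= 3  # ~alpha-level false positives on 20 null pairs

    def test_planted_tract_detected(self):
        """An identical 200-column tract inside ~8%-diverged LTRs is found
        and overlaps >= 80% of the planted columns."""
        rng = np.random.default_rng(33)
        anc = _random_seq(rng, 600)
        pi = [0.25] * 4
        a = evolve(anc, 0.04, 2.0, pi, rng)
        b = evolve(anc, 0.04, 2.0, pi, rng)
        # gene conversion homogenizes columns 200..400 (copy a over b)
        b = b[:200] + a[200:400] + b[400:]
        ctx = [evolve(anc, 0.12, 2.0, pi, rng) for _ in range(3)]
        scan = detect_pair_tracts(a, b, ctx, n_permutations=2000, seed=7)
        assert scan.tracts
        tract = max(scan.tracts, key=lambda t: t.score)
        overlap = min(tract.end_col, 400) - max(tract.start_col, 200)
        assert overlap >= 0.8 * 200  # covers >= 80% of the planted columns

    def test_fewer_than_three_supporting_sites_rejected(self):
        """A candidate segment supported by only 2 informative matches is
        never accepted."""
        # pair matches everywhere; context differs at just 2 columns
        a = "ACGT" * 50
        ctx = [a[:50] + "T" + a[51:100] + "C" + a[101:]]
        assert ctx[0] != a
        scan = detect_pair_tracts(a, a, ctx, n_permutations=200, seed=1)
        assert scan.tracts == ()

    def test_cluster_below_three_members_flagged(self):
        scan = detect_gene_conversion(
            {"x": "ACGT", "y": "ACGT"}, {"e": ("x", "y")}, n_permutations=10
        )
        assert scan.no_context and scan.tracts == ()


class TestCorrectedDivergence:
    def test_no_tracts_keeps_raw(self):
        rng = np.random.default_rng(3)
        anc = _random_seq(rng, 400)
        a = evolve(anc, 0.03, 2.0, [0.25] * 4, rng)
        res = corrected_divergence(anc, a, [])
        assert res.d_corrected == res.d_raw

    def test_linear_scaling_outside_tract(self):
        """Identical tract covering half the columns halves the raw distance;
        correction restores the outside-tract rate."""
        rng = np.random.default_rng(4)
        anc = _random_seq(rng, 1000)
        pi = [0.25] * 4
        b = evolve(anc[:500], 0.062, 2.0, pi, rng) + anc[500:]
        tract = GeneConversionTract("e", 500, 1000, 10, 5.0, 0.01)
        res = corrected_divergence(anc, b, [tract])
        assert res.d_raw == pytest.approx(0.03, abs=0.012)
        assert res.d_corrected == pytest.approx(0.062, abs=0.02)
        assert res.d_corrected > res.d_raw * 1.5

    def test_tract_covering_everything_falls_back(self):
        a = "ACGT" * 100
        tract = GeneConversionTract("e", 0, 400, 10, 5.0, 0.01)
        res = corrected_divergence(a, a, [tract])
        assert res.fallback and res.d_corrected == res.d_raw


class TestEstimateAge:
    def test_zero_divergence_zero_age(self):
        assert estimate_age("e", 0.0).age_years == 0.0

    def test_one_percent_is_one_million_years(self):
        est = estimate_age("e", 0.01)
        assert est.age_years == pytest.approx(1.0e6)
        assert est.age_my == pytest.approx(1.0)

    def test_linearity(self):
        assert estimate_age("e", 0.025).age_my == pytest.approx(2.5)

    def test_negative_divergence_errors(self):
        with pytest.raises(ValueError):
            estimate_age("e", -0.01)


class TestLengthComparison:
    def test_kruskal_wallis_hand_example(self):
        """{1,2,3} vs {4,5,6}: H = 12/(6*7) * (6*3.5^2... ) = 27/7 = 3.857."""
        res = compare_length_distributions({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.h == pytest.approx(27 / 7, abs=1e-9)

    def test_identical_groups_have_zero_t(self):
        res = compare_length_distributions({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        t, _ = res.pairwise[("a", "b")]
        assert t == pytest.approx(0.0)

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        groups = {
            "a": rng.normal(0, 1, 12).tolist(),
            "b": rng.normal(0.5, 1, 15).tolist(),
            "c": rng.normal(1, 2, 9).tolist(),
        }
        h0 = compare_length_distributions(groups).h
        for f in (np.exp, lambda x: np.asarray(x) ** 3, lambda x: 2 * np.asarray(x) + 1):
            transformed = {k: list(f(np.array(v))) for k, v in groups.items()}
            assert compare_length_distributions(transformed).h == pytest.approx(h0)

    def test_small_group_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            compare_length_distributions({"a": [1, 2, 3], "tiny": [4]})
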