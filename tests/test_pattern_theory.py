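"""Site-pattern classes, exact class probabilities, the short-branch
inequalities, and the exact finite-length ML-topology distribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sba.models import JCModel, jc_match_prob
from sba.pattern_theory import (
    INFORMATIVE,
    PatternClass,
    PatternCounts,
    PatternProbs,
    check_sd1_inequalities,
    classify_column,
    count_patterns,
    exact_mle_distribution,
    favored_topology,
    prob_resolved,
    quartet_class_probs,
    star_class_probs,
)
from sba.trees import QuartetTopology


class TestClassify:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", PatternClass.XXXX),
            ("AACC", PatternClass.XXYY),
            ("ACAC", PatternClass.XYXY),
            ("ACCA", PatternClass.XYYX),
            ("AAAC", PatternClass.XXXY),
            ("CAAA", PatternClass.YXXX),
            ("ACGT", PatternClass.XYZW),
            ("AACG", PatternClass.XXYZ),
            ("CAAG", PatternClass.YXXZ),
        ],
    )
    def test_examples(self, column, expected):
        assert classify_column(column) == expected

    def test_unknown_symbol_raises(self):
        with pytest.raises(ValueError):
            classify_column("AAX-")

    @given(
        st.lists(st.integers(0, 3), min_size=4, max_size=4),
        st.permutations([0, 1, 2, 3]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_base_relabeling(self, column, perm):
        """The class depends only on the equality structure, so permuting
        the nucleotide alphabet never changes it."""
        relabeled = [perm[b] for b in column]
        assert classify_column(column) == classify_column(relabeled)

    def test_class_member_counts(self):
        from itertools import product

        counts = {c: 0 for c in PatternClass}
        for tup in product("ACGT", repeat=4):
            counts[classify_column(tup)] += 1
        assert counts[PatternClass.XXXX] == 4
        assert counts[PatternClass.XXYY] == 12
        assert counts[PatternClass.XYXZ] == 24
        assert counts[PatternClass.XYZW] == 24
        assert sum(counts.values()) == 256


class TestCounting:
    def test_hand_tally(self):
        # columns: AAAA -> xxxx, ACC? rows are taxa: S1=AAC S2=AAC S3=ACA S4=ACA
        rows = np.array(
            [[0, 0, 1], [0, 0, 1], [0, 1, 0], [0, 1, 0]], dtype=np.int8
        )
        counts = count_patterns(rows)
        assert counts.K == 3
        assert counts[PatternClass.XXXX] == 1
        assert counts[PatternClass.XXYY] == 2

    def test_identical_rows_all_xxxx(self, rng):
        row = rng.integers(0, 4, size=50)
        counts = count_patterns(np.tile(row, (4, 1)))
        assert counts[PatternClass.XXXX] == 50

    def test_column_permutation_invariant(self, rng):
        m = rng.integers(0, 4, size=(4, 80))
        perm = rng.permutation(80)
        assert np.array_equal(count_patterns(m).omega, count_patterns(m[:, perm]).omega)

    def test_gap_columns_excluded(self):
        m = np.array([[0, 4], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        counts = count_patterns(m)
        assert counts.K == 1


def brute_force_quartet_probs(t0, t1, t2, t3, t4):
    """Independent oracle: full enumeration over both internal-node states
    (16 combinations) and all 256 leaf tuples for the T2 quartet with S1
    (t1), S3 (t3) on one internal node and S2 (t2), S4 (t4) on the other."""
    jc = JCModel()
    p0 = jc.transition_matrix(t0)
    m1, m2, m3, m4 = (jc.transition_matrix(t) for t in (t1, t2, t3, t4))
    out = np.zeros(15)
    from sba.pattern_theory import _TUPLE_CLASS

    joint = np.zeros(256)
    for u in range(4):
        for v in range(4):
            w_uv = 0.25 * p0[u, v]
            block = np.einsum("w,x,y,z->wxyz", m1[u], m2[v], m3[u], m4[v]).reshape(256)
            joint += w_uv * block
    for flat, pr in enumerate(joint):
        out[_TUPLE_CLASS[flat]] += pr
    return out


class TestStarProbs:
    def test_zero_lengths_degenerate(self):
        p = star_class_probs(0, 0, 0, 0)
        assert p[PatternClass.XXXX] == pytest.approx(1.0, abs=1e-14)

    def test_equal_tips_informative_classes_equal(self):
        p = star_class_probs(0.05, 0.05, 0.05, 0.05)
        vals = [p[c] for c in INFORMATIVE]
        assert vals[0] == pytest.approx(vals[1], abs=1e-14)
        assert vals[0] == pytest.approx(vals[2], abs=1e-14)

    def test_short_pair_dominates(self):
        # t1 <= t2 < t3 <= t4: the class pairing the two short branches wins
        p = star_class_probs(0.0001, 0.0001, 0.01, 0.01)
        assert p[PatternClass.XXYY] > p[PatternClass.XYXY]
        assert p[PatternClass.XXYY] > p[PatternClass.XYYX]

    def test_sums_to_one(self):
        p = star_class_probs(0.3, 0.02, 0.11, 0.77)
        assert p.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            star_class_probs(-0.1, 0.1, 0.1, 0.1)


class TestQuartetProbs:
    def test_t0_zero_equals_star(self):
        star = star_class_probs(0.0001, 0.01, 0.0001, 0.01)
        quartet = quartet_class_probs(0.0, 0.0001, 0.01, 0.0001, 0.01)
        assert np.allclose(quartet.p, star.p, atol=1e-12)

    def test_long_internal_supports_true_tree(self):
        p = quartet_class_probs(10.0, 0.05, 0.05, 0.05, 0.05)
        assert p[PatternClass.XYXY] > p[PatternClass.XXYY]
        assert p[PatternClass.XYXY] > p[PatternClass.XYYX]
        assert favored_topology(p) == QuartetTopology.T2

    @pytest.mark.parametrize(
        "params",
        [
            (0.1, 0.02, 0.3, 0.07, 0.5),
            (0.001, 0.0001, 0.01, 0.0001, 0.01),
            (2.0, 1.0, 0.2, 0.01, 0.9),
        ],
    )
    def test_matches_full_enumeration(self, params):
        expected = brute_force_quartet_probs(*params)
        assert np.allclose(quartet_class_probs(*params).p, expected, atol=1e-13)


class TestFavoredTopology:
    def test_short_pair_star_favors_t1(self):
        p = star_class_probs(0.0001, 0.0001, 0.01, 0.01)
        assert favored_topology(p) == QuartetTopology.T1

    def test_equal_tips_tie_is_star(self):
        p = star_class_probs(0.01, 0.01, 0.01, 0.01)
        assert favored_topology(p) == QuartetTopology.STAR


class TestProbResolved:
    def test_scalar_values(self):
        assert prob_resolved(0.0, 100) == 0.0
        assert prob_resolved(0.3, 1) == pytest.approx(0.3)
        assert prob_resolved(0.01, 1000) == pytest.approx(1 - 0.99**1000, rel=1e-12)
        assert prob_resolved(0.01, 1000) > 0.9999

    def test_monotone(self):
        assert prob_resolved(0.01, 200) > prob_resolved(0.01, 100)
        assert prob_resolved(0.02, 100) > prob_resolved(0.01, 100)


class TestExactMLEDistribution:
    def test_k1_equals_class_probs(self):
        p = star_class_probs(0.0001, 0.01, 0.0001, 0.01)
        dist = exact_mle_distribution(p, 1)
        assert dist[QuartetTopology.T1] == pytest.approx(p[PatternClass.XXYY], abs=1e-12)
        assert dist[QuartetTopology.T2] == pytest.approx(p[PatternClass.XYXY], abs=1e-12)
        assert dist[QuartetTopology.T3] == pytest.approx(p[PatternClass.XYYX], abs=1e-12)
        assert dist[QuartetTopology.STAR] == pytest.approx(1 - p.lam, abs=1e-12)

    def test_symmetry_equal_tips(self):
        p = star_class_probs(0.05, 0.05, 0.05, 0.05)
        dist = exact_mle_distribution(p, 37)
        assert dist[QuartetTopology.T1] == pytest.approx(dist[QuartetTopology.T2], abs=1e-12)
        assert dist[QuartetTopology.T2] == pytest.approx(dist[QuartetTopology.T3], abs=1e-12)

    def test_sums_to_one_and_random_tie_rule(self):
        p = star_class_probs(0.02, 0.3, 0.11, 0.4)
        star_dist = exact_mle_distribution(p, 60, tie_rule="star")
        rand_dist = exact_mle_distribution(p, 60, tie_rule="random")
        assert sum(star_dist.values()) == pytest.approx(1.0, abs=1e-9)
        assert rand_dist[QuartetTopology.STAR] == 0.0
        # random tie rule redistributes exactly the star mass
        moved = sum(rand_dist[t] - star_dist[t] for t in list(QuartetTopology)[:3])
        assert moved == pytest.approx(star_dist[QuartetTopology.STAR], abs=1e-9)

    def test_bias_grows_with_length(self):
        p = star_class_probs(0.0001, 0.01, 0.0001, 0.01)
        probs = [exact_mle_distribution(p, K)[QuartetTopology.T2] for K in (1, 10, 100)]
        assert probs[0] < probs[1] < probs[2]

    def test_cap_enforced(self):
        p = star_class_probs(0.05, 0.05, 0.05, 0.05)
        with pytest.raises(ValueError, match="Monte Carlo"):
            exact_mle_distribution(p, 500)

    def test_matches_monte_carlo(self, rng):
        """Exact composition sum vs direct multinomial simulation of the
        count-argmax rule."""
        p = star_class_probs(0.0001, 0.01, 0.0001, 0.01)
        K, n_sims = 50, 200_000
        exact = exact_mle_distribution(p, K, tie_rule="star")
        cat = np.array([p[c] for c in INFORMATIVE] + [1 - p.lam])
        draws = rng.multinomial(K, cat, size=n_sims)[:, :3]
        mx = draws.max(axis=1)
        winners = (draws == mx[:, None]) & (mx[:, None] > 0)
        unique = winners.sum(axis=1) == 1
        for i, topo in enumerate((QuartetTopology.T1, QuartetTopology.T2, QuartetTopology.T3)):
            est = (winners[:, i] & unique).mean()
            se = np.sqrt(max(exact[topo] * (1 - exact[topo]), 1e-12) / n_sims)
            assert abs(est - exact[topo]) < 3 * se + 1e-4


class TestSD1Inequalities:
    def test_random_draws_uninformative_dominates(self, rng):
        for _ in range(1000):
            t = rng.uniform(0.0001, 1.0, size=4)
            report = check_sd1_inequalities(*t)
            assert report["uninformative_exceeds_informative"]

    def test_short_pair_premise_implies_xxyy_dominates(self, rng):
        for _ in range(200):
            t = np.sort(rng.uniform(0.0001, 1.0, size=4))
            report = check_sd1_inequalities(*t)
            assert report["short_pair_premise"] == (max(t[:2]) < min(t[2:]))
            if report["short_pair_premise"]:
                assert report["xxyy_dominates"]

    def test_equal_lengths_margins_vanish(self):
        report = check_sd1_inequalities(0.01, 0.01, 0.01, 0.01)
        assert abs(report["xxyy_minus_xyxy"]) < 1e-14
        assert abs(report["xxyy_minus_xyyx"]) < 1e-14


class TestContainers:
    def test_probs_validation(self):
        with pytest.raises(ValueError):
            PatternProbs(p=np.full(15, 0.5))
        with pytest.raises(ValueError):
            PatternCounts(omega=np.ones(15, dtype=int), K=10)

    def test_tsv_serialization(self):
        p = star_class_probs(0.05, 0.05, 0.05, 0.05)
        text = p.to_tsv()
        assert text.startswith("xxxx\t")
        assert "lambda\t" in text
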