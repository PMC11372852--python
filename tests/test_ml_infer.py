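"""ML engine: pruning likelihood vs exact pattern theory, branch-length
optimization, quartet inference, tie handling, and the NJ+NNI search."""

import math

import numpy as np
import pytest

from sba.ml_infer import (
    MIN_BRANCH_LENGTH,
    jc_distance,
    loglik,
    ml_quartet,
    ml_search,
    ml_tree,
    optimize_branch_lengths,
)
from sba.models import JCModel, sample_gtr_params
from sba.pattern_theory import classify_column, quartet_class_probs
from sba.seqsim import Alignment, make_identical_alignment, simulate_alignment
from sba.trees import QuartetTopology, is_monophyletic, parse_newick, quartet_topology

LABELS = ["S1", "S2", "S3", "S4"]

_CLASS_MEMBERS = [4, 12, 12, 12, 12, 12, 12, 12, 24, 24, 24, 24, 24, 24, 24]


def column_alignment(bases: str) -> Alignment:
    return Alignment.from_sequences(LABELS, list(bases))


class TestLoglik:
    def test_single_uniform_column_zero_lengths(self):
        t = parse_newick("((S1:0,S2:0):0,S3:0,S4:0);")
        value = loglik(t, column_alignment("AAAA"), JCModel())
        assert value == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("column", ["AAAA", "AACC", "ACAC", "ACCA", "ACGT", "AAAC", "CAGA"])
    def test_single_column_matches_class_probability(self, column):
        """exp(pruning loglik) for one column equals the per-member
        probability implied by the exact class probabilities (the T2
        quartet carries S1, S3 on one internal node)."""
        t0, t1, t2, t3, t4 = 0.07, 0.02, 0.3, 0.11, 0.4
        tree = parse_newick(f"((S1:{t1},S3:{t3}):{t0},S2:{t2},S4:{t4});")
        probs = quartet_class_probs(t0, t1, t2, t3, t4)
        cls = classify_column(column)
        expected = probs[cls] / _CLASS_MEMBERS[cls]
        value = loglik(tree, column_alignment(column), JCModel())
        assert math.exp(value) == pytest.approx(expected, abs=1e-10)

    def test_duplicating_columns_doubles_loglik(self, rng):
        t = parse_newick("((S1:0.1,S2:0.2):0.05,S3:0.15,S4:0.3);")
        aln = simulate_alignment(t, JCModel(), 100, rng)
        double = Alignment(LABELS, np.hstack([aln.matrix, aln.matrix]))
        assert loglik(t, double, JCModel()) == pytest.approx(
            2 * loglik(t, aln, JCModel()), rel=1e-12
        )

    def test_label_mismatch_raises(self, rng):
        t = parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        aln = make_identical_alignment(10, rng)
        with pytest.raises(ValueError):
            loglik(t, aln, JCModel())


class TestOptimizeBranchLengths:
    def test_identical_sequences_hit_lower_bound(self, rng):
        aln = make_identical_alignment(200, rng)
        topo = parse_newick("((S1:0.1,S2:0.1):0.1,S3:0.1,S4:0.1);")
        fit = optimize_branch_lengths(topo, aln, JCModel())
        for node in fit.tree.postorder():
            if node.parent is not None:
                assert node.length < 1e-8

    def test_parameter_recovery(self, rng):
        truth = parse_newick("((S1:0.08,S3:0.12):0.1,S2:0.2,S4:0.15);")
        aln = simulate_alignment(truth, JCModel(), 100_000, rng)
        fit = optimize_branch_lengths(truth, aln, JCModel())
        est = {n.label or "internal": n.length for n in fit.tree.postorder() if n.parent is not None}
        for node in truth.postorder():
            if node.parent is None:
                continue
            key = node.label or "internal"
            assert est[key] == pytest.approx(node.length, rel=0.10)
        # optimality: at least as good as the generating lengths
        assert fit.loglik >= loglik(truth, aln, JCModel()) - 1e-6


class TestMLQuartet:
    def test_identical_sequences_star_tie(self, rng):
        aln = make_identical_alignment(100, rng)
        fit = ml_quartet(aln, JCModel(), tie_rule="star", rng=rng)
        assert fit.topology == QuartetTopology.STAR
        assert len(fit.candidate_logliks) == 3

    def test_single_informative_column(self):
        # one xxyy site: the grouping (S1,S2) wins outright under JC
        fit = ml_quartet(column_alignment("AACC"), JCModel(), tie_rule="star")
        assert fit.topology == QuartetTopology.T1

    def test_consistency_long_internal(self, rng):
        truth = parse_newick("((S1:0.05,S3:0.05):0.1,S2:0.05,S4:0.05);")
        hits = 0
        for _ in range(30):
            aln = simulate_alignment(truth, JCModel(), 1000, rng).take(LABELS)
            fit = ml_quartet(aln, JCModel(), rng=rng)
            hits += fit.topology == QuartetTopology.T2
        assert hits >= 28

    def test_reported_loglik_is_of_reported_tree(self, rng):
        model = sample_gtr_params(rng)
        truth = parse_newick("((S1:0.05,S2:0.1):0.07,S3:0.02,S4:0.2);")
        aln = simulate_alignment(truth, model, 300, rng)
        fit = ml_quartet(aln, model, rng=rng)
        assert fit.loglik == pytest.approx(loglik(fit.tree, aln, model), abs=1e-8)
        assert fit.loglik == max(fit.candidate_logliks.values())

    def test_fair_tie_uniformity(self, rng):
        """On identical sequences, the random tie rule picks each topology
        at 1/3 (within 3 s.e.) — the fairness contract the engine must
        satisfy where shell programs show algorithmic bias."""
        n = 450
        counts = {t: 0 for t in QuartetTopology}
        for _ in range(n):
            aln = make_identical_alignment(30, rng)
            counts[ml_quartet(aln, JCModel(), tie_rule="random", rng=rng).topology] += 1
        se = math.sqrt((1 / 3) * (2 / 3) / n)
        for t in (QuartetTopology.T1, QuartetTopology.T2, QuartetTopology.T3):
            assert abs(counts[t] / n - 1 / 3) < 3 * se


class TestMLSearch:
    def test_agrees_with_quartet_engine(self, rng):
        truth = parse_newick("((S1:0.05,S3:0.05):0.1,S2:0.05,S4:0.05);")
        for _ in range(10):
            aln = simulate_alignment(truth, JCModel(), 500, rng).take(LABELS)
            t_search = quartet_topology(ml_search(aln, JCModel()).tree, LABELS)
            t_quartet = ml_quartet(aln, JCModel(), rng=rng).topology
            assert t_search == t_quartet

    def test_recovers_8_taxon_tree(self, rng):
        truth = parse_newick(
            "((A:0.05,(S1:0.05,S2:0.05):0.05):0.05,B:0.05,"
            "((S4:0.05,S5:0.05):0.05,S6:0.05):0.05);"
        )
        hits = 0
        for _ in range(10):
            aln = simulate_alignment(truth, JCModel(), 2000, rng)
            fit = ml_search(aln, JCModel())
            hits += fit.tree.bipartitions() == truth.bipartitions()
        assert hits >= 9

    def test_taxon_order_invariance(self, rng):
        truth = parse_newick("((S1:0.05,S3:0.05):0.1,S2:0.05,S4:0.05);")
        aln = simulate_alignment(truth, JCModel(), 500, rng)
        shuffled = aln.take(["S4", "S2", "S1", "S3"])
        t1 = ml_search(aln, JCModel()).tree.bipartitions()
        t2 = ml_search(shuffled, JCModel()).tree.bipartitions()
        assert t1 == t2


class TestJCDistance:
    def test_identical_and_scalar(self):
        a = np.array([0, 1, 2, 3] * 10, dtype=np.int8)
        assert jc_distance(a, a) == 0.0
        b = a.copy()
        b[:4] = (b[:4] + 1) % 4  # 10% mismatches
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert jc_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_clamped(self, rng):
        a = rng.integers(0, 4, size=3000, dtype=np.int8)
        b = rng.integers(0, 4, size=3000, dtype=np.int8)
        assert jc_distance(a, b) == 10.0

    def test_all_gap_raises(self):
        g = np.full(10, 4, dtype=np.int8)
        with pytest.raises(ValueError):
            jc_distance(g, g)


class TestMLTreePipeline:
    def test_duplicate_pair_grouped(self, rng):
        """Two identical rows are re-attached as a cherry: the attraction
        mechanism that resolves likelihood-flat alignments."""
        base = rng.integers(0, 4, size=100, dtype=np.int8)
        s2 = base.copy()
        s2[rng.choice(100, 2, replace=False)] = (s2[:2] + 1) % 4
        s4 = base.copy()
        s4[rng.choice(100, 3, replace=False)] = (s4[:3] + 2) % 4
        aln = Alignment(LABELS, np.stack([base, s2, base, s4]))
        fit = ml_tree(aln, JCModel(), rng=rng)
        assert fit.topology == QuartetTopology.T2
        assert fit.internal_length < 1e-5

    def test_distinct_sequences_defer_to_quartet_ml(self, rng):
        truth = parse_newick("((S1:0.05,S3:0.05):0.1,S2:0.05,S4:0.05);")
        aln = simulate_alignment(truth, JCModel(), 1000, rng).take(LABELS)
        fit = ml_tree(aln, JCModel(), rng=rng)
        assert fit.topology == ml_quartet(aln, JCModel(), rng=rng).topology

    def test_8_taxon_duplicates_grouped(self, rng):
        t8 = parse_newick(
            "((A:0.0001,((S1:0.05,S2:0.05):0.05,S3:0.05):0.05):0.0001,"
            "B:0.0001,((S4:0.05,S5:0.05):0.05,S6:0.05):0.05);"
        )
        model = sample_gtr_params(rng)
        aln = simulate_alignment(t8, model, 300, rng)
        if np.array_equal(aln.row("A"), aln.row("B")):  # overwhelmingly likely
            fit = ml_tree(aln, model, rng=rng)
            assert is_monophyletic(fit.tree, {"A", "B"})
            assert fit.loglik == pytest.approx(loglik(fit.tree, aln, model), abs=1e-8)
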