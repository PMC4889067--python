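"""Feature partitions and the class-size-penalized Bayes factor."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import nembf as nb

from conftest import uniform_matrix


def brute_force_log_bf(probs, labels, in_group_a, in_group_b):
    """Independent oracle: plain-probability sums over ALL digraphs.

    Enumerates every digraph, closes it with networkx, deduplicates by
    closure, splits by "any closure edge between the groups", and sums the
    exact product-form marginals without log-space tricks.
    """
    k = len(labels)
    offdiag = [(i, j) for i in range(k) for j in range(k) if i != j]
    closures = {}
    for mask in itertools.product([False, True], repeat=len(offdiag)):
        adj = np.zeros((k, k), dtype=bool)
        for (i, j), on in zip(offdiag, mask):
            adj[i, j] = on
        g = nx.from_numpy_array(adj.astype(int), create_using=nx.DiGraph)
        c = nx.to_numpy_array(
            nx.transitive_closure(g, reflexive=True), nodelist=range(k), dtype=bool
        )
        closures[c.tobytes()] = c

    ia = [labels.index(x) for x in in_group_a]
    ib = [labels.index(x) for x in in_group_b]
    sums = {True: 0.0, False: 0.0}
    counts = {True: 0, False: 0}
    for c in closures.values():
        has_cross = bool(c[np.ix_(ia, ib)].any() or c[np.ix_(ib, ia)].any())
        marginal = 1.0
        for row in probs:
            row_sum = 0.0
            for attach in range(k):
                prod = 1.0
                for j in range(k):
                    prod *= row[j] if c[j, attach] else 1.0 - row[j]
                row_sum += prod / k
            marginal *= row_sum
        sums[has_cross] += marginal
        counts[has_cross] += 1
    return math.log(counts[False] / counts[True] * sums[True] / sums[False])


class TestFeatureSpec:
    def test_cross_group_requires_disjoint_groups(self):
        with pytest.raises(ValueError, match="disjoint"):
            nb.FeatureSpec("cross_group_edge", {"A"}, {"A", "B"})

    def test_edge_endpoints_must_differ(self):
        with pytest.raises(ValueError, match="distinct"):
            nb.FeatureSpec("edge_present", edge=("A", "A"))

    def test_unknown_labels_detected_at_evaluation(self):
        f = nb.FeatureSpec("edge_present", edge=("A", "Z"))
        t = nb.Topology.from_edges(("A", "B"), [("A", "B")], close=True)
        with pytest.raises(KeyError, match="Z"):
            f.matches(t)

    def test_reachability_counts_as_edge(self):
        # A -> B -> C: the closure contains A -> C, so the predicate sees it
        t = nb.Topology.from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")])
        assert nb.FeatureSpec("edge_present", edge=("A", "C")).matches(t)

    def test_direction_modes(self):
        t = nb.Topology.from_edges(("A", "B"), [("A", "B")], close=True)
        spec = lambda mode: nb.FeatureSpec(
            "cross_group_edge", {"A"}, {"B"}, direction_mode=mode
        )
        assert spec("either").matches(t)
        assert spec("a_to_b").matches(t)
        assert not spec("b_to_a").matches(t)


class TestPartition:
    def test_k2_edge_present_partition(self, k2_topologies):
        part = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_present", edge=("A", "B"))
        )
        assert (part.n_f, part.n_fbar) == (2, 2)
        for t in part.in_class:  # A->B and the mutual-edge preorder
            assert t.adjacency[0, 1]
        for t in part.out_class:
            assert not t.adjacency[0, 1]

    def test_case_study_geometry(self, case_study_partition):
        # topologies with no edge between the groups factor as ordered
        # pairs of 2-node preorders: 4 x 4 = 16; the rest of 355 is 339
        assert case_study_partition.n_fbar == 16
        assert case_study_partition.n_f == 339
        assert case_study_partition.log_penalty == pytest.approx(
            math.log(16 / 339), abs=0
        )

    def test_edge_absent_is_the_complement_swap(self, k2_topologies):
        present = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_present", edge=("A", "B"))
        )
        absent = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_absent", edge=("A", "B"))
        )
        key = lambda ts: sorted(nb.canonical_key(t) for t in ts)
        assert key(present.in_class) == key(absent.out_class)
        assert key(present.out_class) == key(absent.in_class)

    def test_empty_class_is_an_error(self, k2_topologies):
        always = nb.FeatureSpec("custom_predicate", predicate=lambda t: True)
        with pytest.raises(ValueError, match="empty"):
            nb.partition_topologies(k2_topologies, always)


class TestLogBayesFactor:
    def test_uninformative_matrix_gives_exactly_zero(self, case_study_partition):
        m = uniform_matrix(nb.case_study_labels(), 25)
        r = nb.log_bayes_factor(m, case_study_partition)
        assert abs(r.log_bf) < 1e-10

    def test_decomposition_identity(self, case_study_partition):
        rng = np.random.default_rng(2)
        labels = nb.case_study_labels()
        probs = rng.uniform(0.05, 0.95, size=(10, 4))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(10)), labels, probs)
        r = nb.log_bayes_factor(m, case_study_partition)
        assert r.log_bf == r.log_penalty + r.log_sum_f - r.log_sum_fbar
        assert (r.n_f, r.n_fbar, r.n_genes) == (339, 16, 10)

    @pytest.mark.parametrize("k,groups", [(2, ({"A"}, {"B"})), (3, ({"A"}, {"B", "C"}))])
    def test_matches_brute_force_oracle(self, k, groups):
        rng = np.random.default_rng(100 + k)
        labels = tuple("ABC"[:k])
        probs = rng.uniform(0.1, 0.9, size=(4, k))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(4)), labels, probs)
        feature = nb.FeatureSpec("cross_group_edge", *groups)
        part = nb.partition_topologies(nb.enumerate_closed(k, labels), feature)
        ours = nb.log_bayes_factor(m, part).log_bf
        oracle = brute_force_log_bf(
            probs, list(labels), sorted(groups[0]), sorted(groups[1])
        )
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_swapping_classes_flips_the_sign(self, k2_topologies):
        rng = np.random.default_rng(8)
        probs = rng.uniform(0.1, 0.9, size=(5, 2))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(5)), ("A", "B"), probs)
        present = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_present", edge=("A", "B"))
        )
        absent = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_absent", edge=("A", "B"))
        )
        assert nb.log_bayes_factor(m, present).log_bf == pytest.approx(
            -nb.log_bayes_factor(m, absent).log_bf, abs=1e-12
        )

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(77)
        labels = ("A", "B", "C")
        probs = rng.uniform(0.1, 0.9, size=(6, 3))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(6)), labels, probs)
        feature = nb.FeatureSpec("cross_group_edge", {"A"}, {"B", "C"})
        part = nb.partition_topologies(nb.enumerate_closed(3, labels), feature)
        base = nb.log_bayes_factor(m, part).log_bf

        renamed = {"A": "X", "B": "Y", "C": "Z"}
        labels2 = tuple(renamed[lab] for lab in labels)
        m2 = nb.EffectMatrix(m.gene_ids, labels2, probs)
        feature2 = nb.FeatureSpec("cross_group_edge", {"X"}, {"Y", "Z"})
        part2 = nb.partition_topologies(nb.enumerate_closed(3, labels2), feature2)
        assert nb.log_bayes_factor(m2, part2).log_bf == pytest.approx(base, abs=1e-12)

    def test_uninformative_rows_do_not_move_the_bayes_factor(self, k2_topologies):
        rng = np.random.default_rng(55)
        probs = rng.uniform(0.1, 0.9, size=(4, 2))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(4)), ("A", "B"), probs)
        padded = nb.EffectMatrix(
            m.gene_ids + ("f1", "f2"), ("A", "B"),
            np.vstack([probs, np.full((2, 2), 0.5)]),
        )
        part = nb.partition_topologies(
            k2_topologies, nb.FeatureSpec("edge_present", edge=("A", "B"))
        )
        assert nb.log_bayes_factor(m, part).log_bf == pytest.approx(
            nb.log_bayes_factor(padded, part).log_bf, abs=1e-10
        )


class TestPosteriors:
    def test_posterior_odds_definition(self):
        r = nb.BayesFactorResult(
            log_bf=math.log(3.0), log_sum_f=0, log_sum_fbar=0,
            log_penalty=0, n_f=1, n_fbar=1, n_genes=1,
        )
        assert nb.posterior_class_odds(r, prior_odds=2.0) == pytest.approx(6.0)
        with pytest.raises(ValueError, match="positive"):
            nb.posterior_class_odds(r, prior_odds=0.0)

    def test_strong_evidence_threshold_exceeds_1000_to_1(self):
        r = nb.BayesFactorResult(
            log_bf=10.0, log_sum_f=0, log_sum_fbar=0,
            log_penalty=0, n_f=1, n_fbar=1, n_genes=1,
        )
        assert nb.posterior_class_odds(r, prior_odds=1.0) > 1000

    def test_uniform_posterior_on_uninformative_data(self, k2_topologies):
        m = uniform_matrix(("A", "B"), 3)
        post = nb.topology_posteriors(m, k2_topologies)
        np.testing.assert_allclose(post, 0.25, atol=1e-12)
        assert post.sum() == pytest.approx(1.0, abs=1e-10)

    def test_single_topology_gets_probability_one(self, k2_topologies):
        m = uniform_matrix(("A", "B"), 3)
        post = nb.topology_posteriors(m, k2_topologies[:1])
        assert post[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_normalization(self, k2_topologies):
        rng = np.random.default_rng(31)
        probs = rng.uniform(0.1, 0.9, size=(4, 2))
        m = nb.EffectMatrix(tuple(f"g{i}" for i in range(4)), ("A", "B"), probs)
        post = nb.topology_posteriors(m, k2_topologies)
        raw = np.array([
            math.exp(nb.topology_log_marginal(m, t)) for t in k2_topologies
        ])
        np.testing.assert_allclose(post, raw / raw.sum(), atol=1e-10)
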