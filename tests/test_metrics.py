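"""Evaluation statistics against independent oracles."""

import itertools

import numpy as np
import pytest

from hypergrn.data import ClusterLabeling, GroundTruthNetwork
from hypergrn.grn import RankedEdgeList
from hypergrn.metrics import (
    auprc_ratio,
    clustering_scores,
    embed_and_cluster,
    epr,
    nes,
    overlap_coefficient,
)


def ranking_to_edge_list(pairs, scores=None):
    n = len(pairs)
    scores = scores if scores is not None else [float(n - i) for i in range(n)]
    edges = sorted(((r, t, s) for (r, t), s in zip(pairs, scores)),
                   key=lambda e: (-e[2], e[0], e[1]))
    return RankedEdgeList(edges)


@pytest.fixture
def tiny_truth():
    return GroundTruthNetwork(edges={("g0", "g1"), ("g1", "g2")},
                              gene_universe={"g0", "g1", "g2"})


def brute_force_epr(ordered_pairs, truth_edges, P):
    """Independent implementation straight from the definition."""
    K = len(truth_edges)
    tp = sum(1 for p in ordered_pairs[:K] if p in truth_edges)
    return (tp / K) / (K / P)


def brute_force_auprc(ordered_pairs, truth_edges, P):
    """Trapezoidal area walking the full ranking one prediction at a time."""
    K = len(truth_edges)
    tp = 0
    recalls, precisions = [0.0], [1.0 if ordered_pairs[0] in truth_edges else 0.0]
    for k, pair in enumerate(ordered_pairs, start=1):
        tp += pair in truth_edges
        precisions.append(tp / k)
        recalls.append(tp / K)
    precisions[0] = precisions[1]
    area = 0.0
    for i in range(1, len(recalls)):
        area += (recalls[i] - recalls[i - 1]) * \
                (precisions[i] + precisions[i - 1]) / 2
    return area


class TestEprAuprc:
    def test_perfect_ranking_attains_maximum(self, tiny_truth):
        pairs = [("g0", "g1"), ("g1", "g2"), ("g0", "g2"), ("g1", "g0"),
                 ("g2", "g0"), ("g2", "g1")]
        pred = ranking_to_edge_list(pairs)
        assert epr(pred, tiny_truth) == pytest.approx(6 / 2)  # P/K
        assert auprc_ratio(pred, tiny_truth) == pytest.approx(6 / 2)

    def test_worst_ranking_epr_zero(self, tiny_truth):
        pairs = [("g0", "g2"), ("g1", "g0"), ("g2", "g0"), ("g2", "g1"),
                 ("g0", "g1"), ("g1", "g2")]
        assert epr(ranking_to_edge_list(pairs), tiny_truth) == 0.0

    def test_reversed_perfect_auprc_ratio_below_one(self):
        genes = [f"g{i}" for i in range(5)]
        all_pairs = [(a, b) for a in genes for b in genes if a != b]
        truth = GroundTruthNetwork(edges=set(all_pairs[:4]),
                                   gene_universe=set(genes))
        reversed_pairs = all_pairs[::-1]
        assert auprc_ratio(ranking_to_edge_list(reversed_pairs), truth) < 1.0

    def test_exhaustive_equivalence_on_three_genes(self, tiny_truth):
        """Both statistics agree exactly with brute-force enumeration over
        all 720 rankings of the 6 candidate pairs."""
        genes = ["g0", "g1", "g2"]
        all_pairs = [(a, b) for a in genes for b in genes if a != b]
        for perm in itertools.permutations(all_pairs):
            pred = ranking_to_edge_list(list(perm))
            assert epr(pred, tiny_truth) == pytest.approx(
                brute_force_epr(list(perm), tiny_truth.edges, 6), abs=1e-12)
            assert auprc_ratio(pred, tiny_truth) == pytest.approx(
                brute_force_auprc(list(perm), tiny_truth.edges, 6) / (2 / 6),
                abs=1e-12)

    def test_tf_universe_restricts_denominator(self):
        truth = GroundTruthNetwork(edges={("tf", "g1")},
                                   gene_universe={"tf", "g1", "g2"},
                                   tf_universe={"tf"})
        pred = ranking_to_edge_list([("tf", "g1"), ("tf", "g2")])
        # P = |TF| * |genes| - self pairs = 1 * 3 - 1 = 2
        assert epr(pred, truth) == pytest.approx(2 / 1)

    def test_random_ranking_epr_mean_is_one(self, rng):
        genes = [f"g{i}" for i in range(5)]
        all_pairs = [(a, b) for a in genes for b in genes if a != b]
        truth = GroundTruthNetwork(edges=set(all_pairs[:5]),
                                   gene_universe=set(genes))
        vals = []
        for _ in range(2000):
            perm = [all_pairs[i] for i in rng.permutation(len(all_pairs))]
            vals.append(epr(ranking_to_edge_list(perm), truth))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 4 * se

    def test_empty_truth_rejected(self):
        truth = GroundTruthNetwork(edges=set(), gene_universe={"a", "b"})
        with pytest.raises(ValueError):
            epr(ranking_to_edge_list([("a", "b")]), truth)


class TestOverlapCoefficient:
    def test_identical_sets(self):
        assert overlap_coefficient({"g1", "g2", "g3"}, {"g1", "g2", "g3"}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_coefficient({"g1", "g2"}, {"g3", "g4"}) == 0.0

    def test_partial_overlap_by_hand(self):
        assert overlap_coefficient({"a", "b", "c"}, {"b", "c", "d"}) == \
            pytest.approx(2 / 3)

    def test_symmetric_and_one_for_subsets(self, rng):
        universe = [f"g{i}" for i in range(20)]
        for _ in range(20):
            a = set(rng.choice(universe, rng.integers(1, 15), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 15), replace=False))
            assert overlap_coefficient(a, b) == overlap_coefficient(b, a)
        sub = set(list(a)[:2])
        assert overlap_coefficient(sub, a) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})


def independent_clustering_scores(r, p):
    """Contingency-table implementations written from the definitions."""
    r, p = np.asarray(r), np.asarray(p)
    n = len(r)
    cats_r, cats_p = np.unique(r), np.unique(p)
    C = np.zeros((len(cats_r), len(cats_p)))
    for i, cr in enumerate(cats_r):
        for j, cp in enumerate(cats_p):
            C[i, j] = np.sum((r == cr) & (p == cp))
    Pr, Pp = C.sum(1) / n, C.sum(0) / n

    def ent(probs):
        probs = probs[probs > 0]
        return -np.sum(probs * np.log(probs))

    Hr, Hp = ent(Pr), ent(Pp)
    mi = 0.0
    for i in range(len(cats_r)):
        for j in range(len(cats_p)):
            if C[i, j] > 0:
                pij = C[i, j] / n
                mi += pij * np.log(pij / (Pr[i] * Pp[j]))
    nmi = mi / ((Hr + Hp) / 2) if (Hr + Hp) > 0 else 1.0
    # conditional entropies for homogeneity/completeness
    h_r_given_p = 0.0
    for j in range(len(cats_p)):
        col = C[:, j]
        tot = col.sum()
        if tot > 0:
            h_r_given_p -= np.sum(col[col > 0] / n
                                  * np.log(col[col > 0] / tot))
    h_p_given_r = 0.0
    for i in range(len(cats_r)):
        row = C[i, :]
        tot = row.sum()
        if tot > 0:
            h_p_given_r -= np.sum(row[row > 0] / n
                                  * np.log(row[row > 0] / tot))
    hom = 1.0 if Hr == 0 else 1.0 - h_r_given_p / Hr
    com = 1.0 if Hp == 0 else 1.0 - h_p_given_r / Hp
    # adjusted Rand from pair counts
    from scipy.special import comb
    sum_ij = np.sum([comb(c, 2) for c in C.ravel()])
    sum_i = np.sum([comb(c, 2) for c in C.sum(1)])
    sum_j = np.sum([comb(c, 2) for c in C.sum(0)])
    total = comb(n, 2)
    expected = sum_i * sum_j / total
    maximum = (sum_i + sum_j) / 2
    ari = 1.0 if maximum == expected else (sum_ij - expected) / (maximum - expected)
    return {"nmi": nmi, "ari": ari, "hom": hom, "com": com}


class TestClusteringScores:
    def _labelings(self, r, p):
        ids = [f"e{i}" for i in range(len(r))]
        return (ClusterLabeling(ids, p), ClusterLabeling(ids, r))

    def test_perfect_agreement_all_ones(self, rng):
        r = rng.integers(0, 4, 30)
        pred, ref = self._labelings(r, r)
        assert all(v == pytest.approx(1.0)
                   for v in clustering_scores(pred, ref).values())

    def test_label_permutation_invariance(self, rng):
        r = rng.integers(0, 3, 40)
        p = rng.integers(0, 3, 40)
        base = clustering_scores(*self._labelings(r, p))
        permuted = clustering_scores(*self._labelings(r, (p + 1) % 3))
        for key in base:
            assert base[key] == pytest.approx(permuted[key])

    def test_single_cluster_vs_balanced_reference(self):
        r = np.array([0] * 10 + [1] * 10)
        p = np.zeros(20, dtype=int)
        scores = clustering_scores(*self._labelings(r, p))
        assert scores["com"] == pytest.approx(1.0)
        assert scores["hom"] == pytest.approx(0.0)

    def test_matches_independent_implementation(self, rng):
        for _ in range(50):
            r = rng.integers(0, rng.integers(2, 5), 30)
            p = rng.integers(0, rng.integers(2, 5), 30)
            mine = clustering_scores(*self._labelings(r, p))
            oracle = independent_clustering_scores(r, p)
            for key in mine:
                assert mine[key] == pytest.approx(oracle[key], abs=1e-10), key

    def test_entity_mismatch_rejected(self):
        a = ClusterLabeling(["x", "y"], [0, 1])
        b = ClusterLabeling(["x", "z"], [0, 1])
        with pytest.raises(ValueError):
            clustering_scores(a, b)


class TestNes:
    def test_motif_at_mean_scores_zero(self):
        assert nes(0.2, [0.1, 0.2, 0.3]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert nes(0.3, [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        aucs = rng.uniform(0, 1, 20)
        assert nes(aucs[0] + 5.0, aucs + 5.0) == pytest.approx(
            nes(aucs[0], aucs))

    def test_one_sd_above_mean_is_exactly_one(self, rng):
        aucs = rng.uniform(0, 1, 50)
        target = aucs.mean() + aucs.std(ddof=1)
        assert nes(target, aucs) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            nes(0.5, [0.5])
        with pytest.raises(ValueError):
            nes(0.5, [0.5, 0.5])


class TestEmbedAndCluster:
    def test_two_separated_blobs_recovered(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(60, 5)),
                            rng.normal(12, 1, size=(60, 5))])
        truth = np.array([0] * 60 + [1] * 60)
        lab = embed_and_cluster(X, 2, seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, lab.labels) == 1.0

    def test_narrow_latent_skips_pca(self, rng):
        X = np.concatenate([rng.normal(0, 1, size=(40, 3)),
                            rng.normal(10, 1, size=(40, 3))])
        lab = embed_and_cluster(X, 2, seed=1)
        assert lab.n_clusters == 2

    def test_same_seed_identical_labels(self, rng):
        X = rng.normal(size=(80, 12))
        l1 = embed_and_cluster(X, 3, seed=5)
        l2 = embed_and_cluster(X, 3, seed=5)
        np.testing.assert_array_equal(l1.labels, l2.labels)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="nearest-neighbor"):
            embed_and_cluster(rng.normal(size=(10, 4)), 2, seed=0)
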