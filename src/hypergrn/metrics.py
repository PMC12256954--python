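"""Evaluation statistics: EPR, AUPRC ratio, overlap coefficient, clustering
agreement scores, NES, and the latent-embedding clustering pipeline.

EPR (early precision ratio) and the AUPRC ratio both compare a ranked edge
prediction to the random baseline over the evaluable pair universe: all
ordered (TF, gene) pairs without self-pairs when a TF universe is declared,
otherwise all ordered gene pairs without self-pairs.  With K true edges and
P evaluable pairs, a random ranking has expected early precision K/P, so

    EPR = (TP among top-K) / K  /  (K / P),
    AUPRC ratio = AUPRC(full ranking) / (K / P),

where the AUPRC is the trapezoidal area under the precision-recall points of
the full deterministic ranking (ties broken by regulator/target lexical
order, pairs missing from the prediction scored 0).
"""

from __future__ import annotations

import logging
import random as _pyrandom
from pathlib import Path

import igraph
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import (
    adjusted_rand_score,
    completeness_score,
    homogeneity_score,
    normalized_mutual_info_score,
)
from sklearn.neighbors import NearestNeighbors

from .data import ClusterLabeling, GroundTruthNetwork
from .grn import RankedEdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "epr",
    "auprc_ratio",
    "overlap_coefficient",
    "clustering_scores",
    "nes",
    "embed_and_cluster",
    "read_truth_network",
    "read_labels",
]


def _pair_universe(truth: GroundTruthNetwork) -> list[tuple[str, str]]:
    genes = sorted(truth.gene_universe)
    regs = sorted(truth.tf_universe) if truth.tf_universe is not None else genes
    return [(r, t) for r in regs for t in genes if r != t]


def _ranked_universe_scores(predicted: RankedEdgeList, truth: GroundTruthNetwork
                            ) -> tuple[np.ndarray, int]:
    """Deterministically ranked 0/1 truth labels over the evaluable universe."""
    universe = _pair_universe(truth)
    if not universe:
        raise ValueError("empty evaluable pair universe")
    pairset = set(universe)
    missing = truth.edges - pairset
    if missing:
        raise ValueError(f"truth edges outside the evaluable universe: "
                         f"{sorted(missing)[:5]}")
    scores = {p: 0.0 for p in universe}
    for reg, tgt, s in predicted.edges:
        if (reg, tgt) in pairset:
            scores[(reg, tgt)] = s
    ordered = sorted(universe, key=lambda p: (-scores[p], p[0], p[1]))
    y = np.fromiter(((p in truth.edges) for p in ordered), dtype=float)
    return y, len(universe)


def epr(predicted: RankedEdgeList, truth: GroundTruthNetwork) -> float:
    """Odds ratio of true positives among the top-K predictions vs random,
    K = number of ground-truth edges."""
    K = truth.n_edges
    if K == 0:
        raise ValueError("ground-truth network has no edges")
    y, P = _ranked_universe_scores(predicted, truth)
    tp = float(y[:K].sum())
    return tp * P / (K * K)


def auprc_ratio(predicted: RankedEdgeList, truth: GroundTruthNetwork) -> float:
    """Trapezoidal AUPRC of the full ranking divided by the K/P baseline."""
    K = truth.n_edges
    if K == 0:
        raise ValueError("ground-truth network has no edges")
    y, P = _ranked_universe_scores(predicted, truth)
    cum = np.cumsum(y)
    ranks = np.arange(1, P + 1)
    precision = cum / ranks
    recall = cum / K
    # prepend the recall-zero point at the first precision value
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    auprc = float(np.trapezoid(precision, recall))
    return auprc / (K / P)


def overlap_coefficient(set_a, set_b) -> float:
    """|A n B| / min(|A|, |B|); 1 for identical sets, 0 for disjoint ones."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def clustering_scores(pred: ClusterLabeling, ref: ClusterLabeling) -> dict:
    """NMI (arithmetic-mean normalization), ARI, homogeneity, completeness of
    a predicted labeling against a reference over the same entities."""
    if set(pred.entity_ids) != set(ref.entity_ids):
        raise ValueError("labelings cover different entity sets")
    order = {e: i for i, e in enumerate(ref.entity_ids)}
    p = np.empty(len(order), dtype=np.int64)
    for e, lab in zip(pred.entity_ids, pred.labels):
        p[order[e]] = lab
    r = ref.labels
    return {
        "nmi": float(normalized_mutual_info_score(r, p, average_method="arithmetic")),
        "ari": float(adjusted_rand_score(r, p)),
        "hom": float(homogeneity_score(r, p)),
        "com": float(completeness_score(r, p)),
    }


def nes(auc_motif: float, all_aucs) -> float:
    """Normalized enrichment score: z-score of a motif's AUC against the
    distribution of all motif AUCs (sample sd, denominator N-1)."""
    aucs = np.asarray(list(all_aucs), dtype=float)
    if aucs.size < 2:
        raise ValueError("need at least two AUCs for an enrichment score")
    sd = float(aucs.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation across AUCs")
    return (float(auc_motif) - float(aucs.mean())) / sd


def _louvain(graph: igraph.Graph, resolution: float, seed: int) -> list[int]:
    _pyrandom.seed(seed)  # python-igraph draws randomness from the random module
    return graph.community_multilevel(resolution=resolution).membership


def embed_and_cluster(latent: np.ndarray, n_target_clusters: int, seed: int = 0,
                      entity_ids: list[str] | None = None,
                      n_neighbors: int = 30, n_pcs: int = 10,
                      max_iter: int = 30) -> ClusterLabeling:
    """Cluster cells in a latent space the way embeddings are evaluated:
    reduce to ``n_pcs`` principal components when the width exceeds them,
    build a ``n_neighbors``-nearest-neighbor graph (Euclidean), and run
    Louvain community detection, binary-searching the resolution on
    [1e-3, 10] until the cluster count matches ``n_target_clusters`` (or the
    interval collapses, in which case the closest count is returned with a
    warning).
    """
    X = np.asarray(latent, dtype=np.float64)
    m = X.shape[0]
    if m <= n_target_clusters:
        raise ValueError("need more cells than target clusters")
    if m < n_neighbors + 1:
        raise ValueError(f"need at least {n_neighbors + 1} cells for a "
                         f"{n_neighbors}-nearest-neighbor graph")
    if entity_ids is None:
        entity_ids = [f"c{i}" for i in range(m)]
    if X.shape[1] > n_pcs:
        X = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    graph = igraph.Graph(n=m, edges=sorted(edges))

    lo, hi = 1e-3, 10.0
    best: tuple[int, list[int]] | None = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        membership = _louvain(graph, mid, seed)
        k = len(set(membership))
        gap = abs(k - n_target_clusters)
        if best is None or gap < best[0]:
            best = (gap, membership)
        if k == n_target_clusters:
            return ClusterLabeling(entity_ids, membership)
        if k < n_target_clusters:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    logger.warning("resolution search did not reach %d clusters; returning the "
                   "closest labeling (off by %d)", n_target_clusters, best[0])
    return ClusterLabeling(entity_ids, best[1])


def read_truth_network(path: str | Path, tf_list: list[str] | None = None,
                       gene_universe=None) -> GroundTruthNetwork:
    """Read a regulator<TAB>target edge list (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["regulator", "target"],
                     usecols=[0, 1])
    edges = {(str(r), str(t)) for r, t in df.itertuples(index=False)}
    return GroundTruthNetwork(
        edges=edges,
        gene_universe=set(gene_universe or ()),
        tf_universe=set(tf_list) if tf_list is not None else None,
    )


def read_labels(path: str | Path) -> ClusterLabeling:
    """Read an entity<TAB>label file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["entity", "label"])
    codes, _ = pd.factorize(df["label"])
    return ClusterLabeling([str(e) for e in df["entity"]], codes)
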