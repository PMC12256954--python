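"""Core containers: expression matrices, hypergraphs, causal matrices.

The canonical stored orientation of an expression matrix is cells x genes.
The gene encoder consumes the gene-node view (genes x cells), exposed
explicitly as ``Hypergraph.node_features``; the cell (hyperedge) view is its
transpose.  Every function states which view it consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGES = ("raw", "filtered", "normalized")


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with identifiers.

    ``stage`` tracks provenance through the preprocessing pipeline:
    ``raw`` (counts as read), ``filtered`` (after sparsity filters / gene
    selection) and ``normalized`` (log1p + per-gene z-score).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.cell_ids) != m or len(self.gene_ids) != n:
            raise ValueError(
                f"identifier/shape mismatch: {m}x{n} values, "
                f"{len(self.cell_ids)} cells, {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != m:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain NaN or Inf")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("raw", "filtered") and np.any(self.values < 0):
            raise ValueError(f"{self.stage} expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Hypergraph:
    """Incidence structure linking gene-nodes to cell-hyperedges.

    ``incidence`` is cells x genes binary (1 iff the raw expression is
    positive).  ``node_features`` is genes x cells, the gene-node view of the
    normalized matrix; ``hyperedge_features`` is its transpose.  The
    hyperedge weight matrix is the identity by default (no prior knowledge of
    cell relationships) and is stored only as an optional override.
    """

    incidence: np.ndarray
    node_features: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    hyperedge_weights: np.ndarray | None = None

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=np.float64)
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if not np.isin(self.incidence, (0.0, 1.0)).all():
            raise ValueError("incidence must be binary")
        m, n = self.incidence.shape
        if self.node_features.shape != (n, m):
            raise ValueError(
                "node_features must be genes x cells matching the incidence"
            )

    @property
    def hyperedge_features(self) -> np.ndarray:
        """Cells x genes view; always the transpose of node_features."""
        return self.node_features.T

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_genes(self) -> int:
        return self.incidence.shape[1]

    def weights(self) -> np.ndarray:
        if self.hyperedge_weights is None:
            return np.eye(self.n_cells)
        return self.hyperedge_weights


@dataclass
class CausalMatrix:
    """Gene x gene causal interaction matrix; the GRN estimate.

    Convention: ``values[i, j]`` scores the influence of gene ``i``
    (regulator) on gene ``j`` (target).  The diagonal is identically zero.
    """

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("causal matrix must be square and match gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("causal matrix contains non-finite entries")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("causal matrix diagonal must be zero")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.values.T))))


@dataclass
class GaussianLatent:
    """Mean/std pair parameterizing a diagonal Gaussian posterior."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have identical shapes")
        if not (np.all(np.isfinite(self.std)) and np.all(self.std > 0)):
            raise ValueError("std must be strictly positive and finite")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("mean contains non-finite entries")


@dataclass
class ClusterLabeling:
    """Integer cluster labels over a set of entities."""

    entity_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.entity_ids) != self.labels.shape[0]:
            raise ValueError("one label per entity required")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity identifiers")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class GroundTruthNetwork:
    """Reference regulator -> target edge set used for evaluation."""

    edges: set[tuple[str, str]]
    gene_universe: set[str] = field(default_factory=set)
    tf_universe: set[str] | None = None

    def __post_init__(self):
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        if any(a == b for a, b in self.edges):
            raise ValueError("ground-truth network must not contain self-edges")
        genes_in_edges = {g for e in self.edges for g in e}
        self.gene_universe = set(self.gene_universe) | genes_in_edges
        if self.tf_universe is not None:
            self.tf_universe = set(self.tf_universe)
            missing = {a for a, _ in self.edges} - self.tf_universe
            if missing:
                raise ValueError(f"edges originate from non-TF genes: {sorted(missing)[:5]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)
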