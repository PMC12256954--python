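"""Synthetic scRNA-seq data with a known regulatory network.

Expression is generated from the linear SEM the model assumes: exogenous
Gaussian noise per cell and gene is propagated through ``(I - A^T)^{-1}``
along the gene axis, so the gene-gene covariance of the latent values is
``noise_sd^2 ((I - A^T)^{-1}) ((I - A^T)^{-1})^T``.  The latent values are
made non-negative with a softplus (preserving rank information, unlike
clipping) and zeroed independently with the dropout probability to emulate
the sparsity of single-cell counts.  A block-structured variant adds
cell-cluster / gene-module mean shifts for clustering fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (
    CausalMatrix,
    ClusterLabeling,
    ExpressionMatrix,
    GroundTruthNetwork,
)

__all__ = ["SyntheticDataset", "simulate_grn", "simulate_expression",
           "simulate_clustered"]


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    truth_A: CausalMatrix | None
    truth_edges: GroundTruthNetwork | None
    cell_labels: ClusterLabeling | None
    gene_module_labels: ClusterLabeling | None
    seed: int
    sem_values: np.ndarray | None = None  # pre-shift SEM draws, for diagnostics

    def write(self, out_dir: str | Path, format: str = "csv") -> None:
        """Write expression, truth edges, labels and a parameter manifest."""
        from .io_preprocess import write_expression

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        suffix = {"csv": "csv", "tsv": "tsv", "mtx_triplet": "mtx"}[format]
        write_expression(self.expression, out_dir / f"expression.{suffix}", format)
        if self.truth_edges is not None:
            lines = [f"{r}\t{t}" for r, t in sorted(self.truth_edges.edges)]
            (out_dir / "truth_edges.tsv").write_text("\n".join(lines) + "\n")
        for labeling, name in ((self.cell_labels, "cell_labels.tsv"),
                               (self.gene_module_labels, "gene_module_labels.tsv")):
            if labeling is not None:
                lines = [f"{e}\t{l}" for e, l in
                         zip(labeling.entity_ids, labeling.labels)]
                (out_dir / name).write_text("\n".join(lines) + "\n")
        manifest = {
            "seed": self.seed,
            "n_cells": self.expression.n_cells,
            "n_genes": self.expression.n_genes,
            "n_truth_edges": self.truth_edges.n_edges if self.truth_edges else 0,
            "format": format,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def simulate_grn(n_genes: int, density: float = 0.05,
                 weight_range: tuple[float, float] = (0.5, 1.5),
                 seed: int | np.random.Generator = 0,
                 max_spectral_radius: float = 0.8) -> CausalMatrix:
    """Random sparse causal matrix: off-diagonal entries are non-zero with
    probability ``density``, magnitudes uniform in ``weight_range`` with
    random sign, and the matrix is rescaled so the spectral radius of A^T is
    at most ``max_spectral_radius`` (guaranteeing (I - A^T) is invertible).
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    lo, hi = weight_range
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi for the weight range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random((n_genes, n_genes)) < density
    np.fill_diagonal(mask, False)
    mag = rng.uniform(lo, hi, size=(n_genes, n_genes))
    sign = rng.choice([-1.0, 1.0], size=(n_genes, n_genes))
    A = np.where(mask, sign * mag, 0.0)
    radius = np.max(np.abs(np.linalg.eigvals(A.T)))
    if radius > max_spectral_radius:
        if not np.isfinite(radius):
            raise ValueError("cannot rescale a degenerate matrix")
        A *= max_spectral_radius / radius
    return CausalMatrix(A, [f"g{i}" for i in range(n_genes)])


def _truth_from_matrix(A: CausalMatrix) -> GroundTruthNetwork:
    regs, tgts = np.nonzero(A.values)
    edges = {(A.gene_ids[i], A.gene_ids[j]) for i, j in zip(regs, tgts)}
    return GroundTruthNetwork(edges=edges, gene_universe=set(A.gene_ids))


def simulate_expression(A: CausalMatrix, n_cells: int, noise_sd: float = 1.0,
                        dropout: float = 0.2,
                        seed: int | np.random.Generator = 0) -> SyntheticDataset:
    """Draw expression from the SEM: ``latent = Z (I - A)^{-1}`` with
    ``Z ~ N(0, noise_sd^2)`` per cell x gene, softplus to non-negative
    values, then independent dropout zeroing.
    """
    if A.spectral_radius() >= 1:
        raise ValueError("spectral radius of A^T must be < 1")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    seed_int = seed if isinstance(seed, int) else 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = A.n_genes
    z = rng.normal(0.0, noise_sd, size=(n_cells, n))
    latent = z @ np.linalg.inv(np.eye(n) - A.values)
    raw = np.logaddexp(0.0, latent)  # softplus, > 0 everywhere
    keep = rng.random(raw.shape) >= dropout
    raw = raw * keep
    expr = ExpressionMatrix(raw, [f"c{i}" for i in range(n_cells)],
                            list(A.gene_ids), stage="raw")
    return SyntheticDataset(expression=expr, truth_A=A,
                            truth_edges=_truth_from_matrix(A),
                            cell_labels=None, gene_module_labels=None,
                            seed=seed_int, sem_values=latent)


def simulate_clustered(n_cells: int, n_genes: int, k_clusters: int = 2,
                       k_modules: int = 2, effect_size: float = 5.0,
                       noise_sd: float = 1.0,
                       seed: int | np.random.Generator = 0) -> SyntheticDataset:
    """Block-structured dataset: cells in cluster c over-express the genes of
    module ``c mod k_modules`` by ``effect_size`` on top of Gaussian noise.
    Labels for both axes are packaged for clustering benchmarks.
    """
    if k_clusters < 2:
        raise ValueError("need at least 2 cell clusters")
    if not 1 <= k_modules <= n_genes:
        raise ValueError("k_modules must be between 1 and n_genes")
    if k_clusters > n_cells:
        raise ValueError("more clusters than cells")
    seed_int = seed if isinstance(seed, int) else 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cell_lab = np.arange(n_cells) % k_clusters
    gene_lab = np.arange(n_genes) % k_modules
    shift = np.where(gene_lab[None, :] == (cell_lab[:, None] % k_modules),
                     effect_size, 0.0)
    latent = rng.normal(0.0, noise_sd, size=(n_cells, n_genes)) + shift
    raw = np.logaddexp(0.0, latent)
    expr = ExpressionMatrix(raw, [f"c{i}" for i in range(n_cells)],
                            [f"g{i}" for i in range(n_genes)], stage="raw")
    return SyntheticDataset(
        expression=expr, truth_A=None, truth_edges=None,
        cell_labels=ClusterLabeling(expr.cell_ids, cell_lab),
        gene_module_labels=ClusterLabeling(expr.gene_ids, gene_lab),
        seed=seed_int, sem_values=latent,
    )
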