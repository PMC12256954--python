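"""The preprocessing pipeline on a small raw matrix.

Filters sparse genes/cells, keeps the most variable genes, log/z-normalizes,
and assembles the gene-cell hypergraph whose incidence records which gene is
expressed in which cell.
"""

import numpy as np

import hypergrn as hg
from hypergrn.data import ExpressionMatrix
from hypergrn.io_preprocess import (
    build_hypergraph, filter_cells_genes, normalize, select_top_variable_genes,
)

rng = np.random.default_rng(0)
raw_counts = rng.poisson(1.2, size=(200, 120)).astype(float)
raw_counts[:, 100:] = 0.0  # 20 genes silent everywhere
X = ExpressionMatrix(raw_counts, [f"cell{i}" for i in range(200)],
                     [f"gene{j}" for j in range(120)])
print(f"raw: {X.n_cells} cells x {X.n_genes} genes")

X = filter_cells_genes(X, min_frac=0.01)
print(f"after >1% sparsity filter: {X.n_cells} cells x {X.n_genes} genes "
      "(silent genes dropped)")

X = select_top_variable_genes(X, n_top=50)
print(f"after variance ranking: {X.n_genes} most-variable genes kept")

import dataclasses
X = dataclasses.replace(X, stage="raw")
norm = normalize(X)
print(f"normalized: per-gene mean {norm.values.mean(axis=0).max():.1e}, "
      f"sd {norm.values.std(axis=0)[0]:.2f} (log1p + z-score)")

hgraph = build_hypergraph(X, norm)
print(f"hypergraph: incidence {hgraph.incidence.shape} with "
      f"{hgraph.incidence.mean():.0%} of gene-cell memberships present; "
      "each cell is a hyperedge joining the genes it expresses")
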