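"""Ranked regulatory edge lists from a learned causal matrix.

The absolute value of ``A[i, j]`` scores the directed link i -> j
(row = regulator, column = target, matching the SEM convention used during
training).  Self-edges are dropped; with a TF list only edges whose
regulator is a listed TF are emitted.  Ties are broken by (regulator,
target) lexical order so rankings are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CausalMatrix

__all__ = ["RankedEdgeList", "extract_edges", "select_top_fraction"]


@dataclass
class RankedEdgeList:
    """(regulator, target, score) triples sorted by descending score."""

    edges: list[tuple[str, str, float]]
    provenance: str = ""

    def __post_init__(self):
        for reg, tgt, s in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge {reg}->{tgt} in ranked list")
            if not math.isfinite(s):
                raise ValueError(f"non-finite score for {reg}->{tgt}")
        scores = [s for _, _, s in self.edges]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("edges must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "score"])

    def write_tsv(self, path: str | Path, header: bool = False) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=header)

    @classmethod
    def read_tsv(cls, path: str | Path, header: bool = False) -> "RankedEdgeList":
        df = pd.read_csv(path, sep="\t",
                         header=0 if header else None,
                         names=["regulator", "target", "score"])
        edges = [(str(r), str(t), float(s)) for r, t, s in
                 df.itertuples(index=False)]
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
        return cls(edges, provenance=str(path))


def extract_edges(A: CausalMatrix, tf_list: set[str] | list[str] | None = None,
                  provenance: str = "") -> RankedEdgeList:
    """Rank all candidate edges by |A[i, j]|, highest first."""
    ids = A.gene_ids
    if tf_list is not None:
        tfs = [g for g in ids if g in set(tf_list)]
        if not tfs:
            raise ValueError("tf_list shares no genes with the causal matrix")
    else:
        tfs = ids
    idx = {g: k for k, g in enumerate(ids)}
    absA = np.abs(A.values)
    edges = [
        (reg, tgt, float(absA[idx[reg], idx[tgt]]))
        for reg in tfs for tgt in ids if tgt != reg
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedEdgeList(edges, provenance=provenance)


def select_top_fraction(edges: RankedEdgeList, fraction: float) -> RankedEdgeList:
    """Keep the ceil(fraction * |edges|) highest-scoring edges."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(edges) == 0:
        raise ValueError("cannot select from an empty edge list")
    k = math.ceil(fraction * len(edges))
    return RankedEdgeList(edges.edges[:k], provenance=edges.provenance)
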