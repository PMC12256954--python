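"""Variational encoders: hypergraph multi-head attention over gene nodes and
the structural-equation transform over cell hyperedges.

Gene encoder.  Genes are nodes; each cell is a hyperedge joining the genes it
expresses.  A layer scores every ordered pair of genes that co-occur in a
hyperedge with ``LeakyReLU(a^T [W h_i || W h_j])``, normalizes the scores per
hyperedge with a softmax over that hyperedge's members, and updates each gene
with the coefficient-weighted sum of smoothed, projected neighbor features.
The smoothing operator ``S = N Omega N^T`` (``N`` the genes x cells
incidence, ``Omega`` the hyperedge weights, identity by default) mixes the
profiles of genes sharing cells; a gene occurring in several hyperedges sums
its updates across them.  Heads are concatenated in hidden layers and
averaged in the final layer; the nonlinearity is ELU.

Cell encoder.  With ``A`` the gene x gene causal matrix (``A[i, j]`` = effect
of regulator ``i`` on target ``j``), the linear SEM reads ``H^E = A^T H^E + Z``
for gene-indexed columns, i.e. row-wise ``F -> F (I - A)`` maps observations
to their exogenous-noise coordinates.  The encoder applies an MLP
``f_E`` (cells x genes -> cells x genes) and then that SEM whitening before
the variational heads.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import CausalMatrix, GaussianLatent, Hypergraph

__all__ = [
    "AttentionParams",
    "SemEncoderParams",
    "GeneEncoder",
    "CellEncoder",
    "attention_score",
    "attention_coefficients",
    "propagate",
    "gene_variational_head",
    "cell_variational_head",
    "cell_encode_sem",
    "reparameterize",
    "smoothing_operator",
]


# --------------------------------------------------------------------- helpers
def smoothing_operator(
    incidence: np.ndarray,
    hyperedge_weights: np.ndarray | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Gene x gene smoothing operator ``N Omega N^T`` from a cells x genes
    incidence (``N = incidence.T``).  With ``normalized=True`` the operator is
    rescaled by node and hyperedge degrees,
    ``D_v^{-1/2} N Omega D_e^{-1} N^T D_v^{-1/2}``, the standard hypergraph
    convolution normalization; the unnormalized form grows with the cell
    count and is kept for the literal layer definition.
    """
    N = np.asarray(incidence, dtype=np.float64).T  # genes x cells
    m = N.shape[1]
    omega = np.eye(m) if hyperedge_weights is None else np.asarray(hyperedge_weights)
    if not normalized:
        return N @ omega @ N.T
    w = np.diag(omega)
    d_e = N.sum(axis=0)  # hyperedge sizes
    d_v = N @ w  # Omega-weighted node degrees
    inv_de = np.where(d_e > 0, 1.0 / d_e, 0.0)
    inv_sqrt_dv = np.where(d_v > 0, 1.0 / np.sqrt(d_v), 0.0)
    return (inv_sqrt_dv[:, None] * N) @ (omega * inv_de) @ (N.T * inv_sqrt_dv[None, :])


def _masked_softmax(scores: Tensor, col_mask: np.ndarray, row_mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to ``col_mask``; rows with
    ``row_mask == 0`` come out exactly zero, as do masked columns.
    """
    smax = np.max(np.where(col_mask > 0, scores.data, -np.inf), axis=-1, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)  # rows with no member
    z = (scores - Tensor(smax)).exp() * Tensor(col_mask)
    denom = z.sum(axis=-1, keepdims=True)
    safe = denom + Tensor(1.0 - row_mask)  # avoid 0/0 on empty rows
    return z / safe * Tensor(row_mask)


# ------------------------------------------------------------------ parameters
class AttentionParams:
    """Trainable state of one multi-head attention stack.

    Per layer ``l`` and head ``h``: a projection ``W[l][h]`` (out x in) and a
    score vector ``a[l][h]`` of length ``2 * out`` (its two halves weight the
    source and destination projections).
    """

    def __init__(self, W: list[Tensor], a: list[Tensor], leak: float = 0.2):
        if len(W) != len(a) or not W:
            raise ValueError("need one (W, a) pair per layer, at least one layer")
        for Wl, al in zip(W, a):
            if al.shape != (Wl.shape[0], 2 * Wl.shape[2]):
                raise ValueError("score vector length must be twice the head width")
        self.W = W  # [layer] -> Tensor (heads, in_w, out_w)
        self.a = a  # [layer] -> Tensor (heads, 2 * out_w)
        self.leak = leak

    @property
    def n_layers(self) -> int:
        return len(self.W)

    @property
    def n_heads(self) -> int:
        return self.W[0].shape[0]

    def tensors(self) -> list[Tensor]:
        return [*self.W, *self.a]


class SemEncoderParams:
    """Trainable state of the SEM cell encoder.

    ``f_E`` maps cells x genes to cells x genes.  Its MLP acts gene-wise
    with weights shared across genes (each gene's scalar expression passes
    through the same 1 -> hidden -> 1 stack), and the variational heads are
    per-gene elementwise scales/offsets.  Confining every cross-gene mixing
    of the cell branch to the causal matrix is what makes the SEM
    identifiable: if ``f_E`` or the heads could mix genes, they -- not
    ``A`` -- would absorb the gene-gene dependence, and the sparsity penalty
    would simply drive ``A`` to zero.  The gene feature matrix ``X^V`` is the
    identity (no prior per-gene features), so it is never materialized.
    """

    def __init__(self, mlp: list[tuple[Tensor, Tensor]],
                 head_mu: tuple[Tensor, Tensor], head_sigma: tuple[Tensor, Tensor]):
        self.mlp = mlp  # gene-wise [(W, b), ...]: W shapes (1, h), (h, 1)
        self.head_mu = head_mu  # per-gene (scale, offset) vectors
        self.head_sigma = head_sigma

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for W, b in [*self.mlp, self.head_mu, self.head_sigma]:
            out.extend([W, b])
        return out


def _mlp_forward(x: Tensor, layers: list[tuple[Tensor, Tensor]]) -> Tensor:
    """Linear stack with ELU between layers (none after the last)."""
    for k, (W, b) in enumerate(layers):
        x = x @ W + b
        if k < len(layers) - 1:
            x = ad.elu(x)
    return x


def _genewise_mlp_forward(x: Tensor, layers: list[tuple[Tensor, Tensor]]) -> Tensor:
    """Apply a shared scalar MLP to every entry of a cells x genes matrix."""
    m, n = x.shape
    h = x.reshape(m, n, 1)
    for k, (W, b) in enumerate(layers):
        h = h @ W + b
        if k < len(layers) - 1:
            h = ad.elu(h)
    return h.reshape(m, n)


def _linear_head(x: Tensor, head: tuple[Tensor, Tensor]) -> Tensor:
    W, b = head
    return x @ W + b


def _elementwise_head(x: Tensor, head: tuple[Tensor, Tensor]) -> Tensor:
    w, b = head
    return x * w + b


# ----------------------------------------------------------------- public ops
def attention_score(h_i: np.ndarray, h_j: np.ndarray, params: AttentionParams,
                    layer: int, head: int) -> float:
    """Pair score ``LeakyReLU(a^T [W h_i || W h_j])`` for two genes sharing a
    hyperedge; asymmetric in (i, j) in general.
    """
    W = params.W[layer].data[head]  # (in_w, out_w)
    a = params.a[layer].data[head]
    h_i, h_j = np.asarray(h_i, float), np.asarray(h_j, float)
    if h_i.shape[-1] != W.shape[0] or h_j.shape[-1] != W.shape[0]:
        raise ValueError("feature width does not match the layer's input width")
    pre = np.concatenate([h_i @ W, h_j @ W]) @ a
    return float(pre if pre > 0 else params.leak * pre)


def attention_coefficients(scores) -> np.ndarray | list[np.ndarray]:
    """Per-hyperedge softmax of attention scores.

    Accepts a single 1-D score vector (one node against the members of one
    hyperedge), a 2-D matrix (rows = nodes of the hyperedge), or a list of
    such arrays, one per hyperedge.  Coefficients over each row sum to 1.
    """
    if isinstance(scores, list):
        return [attention_coefficients(s) for s in scores]
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("empty hyperedge has no attention coefficients")
    z = np.exp(s - s.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


def propagate(node_features: np.ndarray, hg: Hypergraph, coeffs: np.ndarray,
              params: AttentionParams, layer: int, head: int = 0,
              activation: str = "elu", normalized_smoothing: bool = False) -> np.ndarray:
    """One attention layer update for a single head:
    ``h_i' = sigma(sum_c sum_{j in e_c} alpha[c,i,j] (N Omega N^T H)_j W)``.

    ``coeffs`` is a dense (cells, genes, genes) coefficient array consistent
    with the incidence (zero where a pair shares no hyperedge).
    """
    X = np.asarray(node_features, dtype=np.float64)
    inc = hg.incidence
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (hg.n_cells, hg.n_genes, hg.n_genes):
        raise ValueError("coefficient array must be cells x genes x genes")
    co_member = np.einsum("ci,cj->cij", inc, inc)
    if np.any(coeffs[co_member == 0] != 0):
        raise ValueError("coefficients present for pairs sharing no hyperedge")
    S = smoothing_operator(inc, hg.weights(), normalized=normalized_smoothing)
    T = (S @ X) @ params.W[layer].data[head]
    agg = np.einsum("cij,jw->iw", coeffs, T)
    if activation == "identity":
        return agg
    if activation == "elu":
        return np.where(agg > 0, agg, np.expm1(agg))
    raise ValueError(f"unknown activation {activation!r}")


def gene_variational_head(z_tilde: np.ndarray, head_mu: tuple, head_sigma: tuple) -> GaussianLatent:
    """Linear heads mapping encoder output to the posterior mean and (via
    softplus, to keep it positive) standard deviation.
    """
    x = Tensor(np.asarray(z_tilde, float))
    mu = _linear_head(x, head_mu).data
    std = ad.softplus(_linear_head(x, head_sigma)).data
    if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(std)):
        raise ValueError("variational head produced non-finite output")
    return GaussianLatent(mu, std)


def cell_variational_head(z_tilde: np.ndarray, head_mu: tuple, head_sigma: tuple
                          ) -> GaussianLatent:
    """Per-gene elementwise heads for the gene-indexed cell latent; std is
    kept positive through a softplus."""
    x = Tensor(np.asarray(z_tilde, float))
    mu = _elementwise_head(x, head_mu).data
    std = ad.softplus(_elementwise_head(x, head_sigma)).data
    if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(std)):
        raise ValueError("variational head produced non-finite output")
    return GaussianLatent(mu, std)


def cell_encode_sem(hyperedge_features: np.ndarray, A: CausalMatrix,
                    params: SemEncoderParams) -> np.ndarray:
    """SEM encoding of the cell view: the gene-wise ``f_E`` followed by the
    whitening ``F -> F (I - A)`` along the gene axis.
    """
    F = np.asarray(hyperedge_features, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("hyperedge features must be cells x genes")
    if A.n_genes != F.shape[1]:
        raise ValueError("causal matrix dimension does not match the gene axis")
    out = _genewise_mlp_forward(Tensor(F), params.mlp)
    I_minus_A = np.eye(A.n_genes) - A.values
    return out.data @ I_minus_A


def reparameterize(latent: GaussianLatent, rng: np.random.Generator) -> np.ndarray:
    """Draw ``Z = mu + std * eps`` with ``eps ~ N(0, I)``; deterministic for a
    given generator state.
    """
    eps = rng.standard_normal(latent.mean.shape)
    return latent.mean + latent.std * eps


# ----------------------------------------------------------- trainable modules
class GeneEncoder:
    """Multi-head hypergraph attention stack plus variational heads."""

    def __init__(self, params: AttentionParams, head_mu: tuple[Tensor, Tensor],
                 head_sigma: tuple[Tensor, Tensor], normalized_smoothing: bool = True,
                 degree_normalize: bool = True):
        self.params = params
        self.head_mu = head_mu
        self.head_sigma = head_sigma
        self.normalized_smoothing = normalized_smoothing
        self.degree_normalize = degree_normalize

    def tensors(self) -> list[Tensor]:
        return [*self.params.tensors(), *self.head_mu, *self.head_sigma]

    def _layer(self, X: Tensor, inc: np.ndarray, S: np.ndarray, layer: int,
               final: bool) -> Tensor:
        """One attention layer, all heads.

        The pair score e(i, j) does not depend on which hyperedge the pair
        shares -- only the per-hyperedge softmax normalization does -- so the
        summed update over hyperedges factorizes: with z = exp(e - rowmax)
        and denominators d[c, i] = sum_{j in e_c} z[i, j],

            sum_c alpha[c, i, j] = z[i, j] * sum_c inc[c, i] inc[c, j] / d[c, i],

        which needs only (heads, genes, genes) and (heads, genes, cells)
        intermediates instead of a dense per-hyperedge coefficient tensor.
        The per-row max shift is uniform within each row, so every
        hyperedge's softmax is shifted equally (exactly invariant).
        """
        W, a = self.params.W[layer], self.params.a[layer]
        heads, out_w = W.shape[0], W.shape[2]
        a_src, a_dst = a[:, :out_w], a[:, out_w:]
        X3 = X.reshape(1, *X.shape)
        proj = X3 @ W  # (heads, genes, out_w) score projection
        smooth = Tensor(S) @ X3 @ W  # (heads, genes, out_w) aggregation features
        s = (proj * a_src.reshape(heads, 1, out_w)).sum(axis=-1)  # (heads, genes)
        t = (proj * a_dst.reshape(heads, 1, out_w)).sum(axis=-1)
        n = inc.shape[1]
        pair = s.reshape(heads, n, 1) + t.reshape(heads, 1, n)
        pair = ad.leaky_relu(pair, self.params.leak)
        shift = pair.data.max(axis=-1, keepdims=True)
        z = (pair - Tensor(shift)).exp()  # (heads, n, n)
        denom = z @ Tensor(inc.T)  # (heads, n, cells): d[h, i, c]
        member = Tensor(inc.T[None, :, :])  # (1, n, cells)
        ratio = member / (denom + Tensor(1e-300))  # inc[c,i] / d[h,i,c]
        coeff = z * (ratio @ Tensor(inc))  # (heads, n, n) = sum_c alpha[c,i,j]
        agg = coeff @ smooth
        if self.degree_normalize:
            # mean over the hyperedges containing each gene keeps the update
            # scale independent of how many cells express it
            deg = np.maximum(inc.sum(axis=0), 1.0)
            agg = agg * Tensor(1.0 / deg[None, :, None])
        agg = ad.elu(agg)
        if final:
            return agg.mean(axis=0)
        return ad.concat([agg[h] for h in range(heads)], axis=-1)

    def encode(self, hg: Hypergraph, node_features: Tensor | None = None
               ) -> tuple[Tensor, Tensor]:
        """Return posterior (mean, std) tensors for the gene latents."""
        X = node_features if node_features is not None else Tensor(hg.node_features)
        S = smoothing_operator(hg.incidence, hg.weights(),
                               normalized=self.normalized_smoothing)
        L = self.params.n_layers
        for l in range(L):
            X = self._layer(X, hg.incidence, S, l, final=(l == L - 1))
        mu = _linear_head(X, self.head_mu)
        std = ad.softplus(_linear_head(X, self.head_sigma))
        return mu, std

    def attention_coefficients_dense(self, hg: Hypergraph, layer: int = 0) -> np.ndarray:
        """First-layer dense coefficients (heads, cells, genes, genes); a
        diagnostic view used to inspect learned gene-gene weights.
        """
        X = Tensor(hg.node_features)
        S = smoothing_operator(hg.incidence, hg.weights(),
                               normalized=self.normalized_smoothing)
        for l in range(layer):
            X = self._layer(X, hg.incidence, S, l, final=False)
        W, a = self.params.W[layer], self.params.a[layer]
        heads, out_w = W.shape[0], W.shape[2]
        proj = (X.reshape(1, *X.shape) @ W).data
        s = proj @ a.data[:, :out_w][..., None]
        t = proj @ a.data[:, out_w:][..., None]
        n = hg.n_genes
        pair = s.reshape(heads, 1, n, 1) + t.reshape(heads, 1, 1, n)
        pair = np.where(pair > 0, pair, self.params.leak * pair)
        inc = hg.incidence
        col_mask = np.einsum("ci,cj->cij", inc, inc)[None]
        row_mask = inc[None, :, :, None]
        alpha = _masked_softmax(Tensor(pair), col_mask, row_mask)
        return alpha.data


class CellEncoder:
    """SEM cell encoder: gene-wise MLP, whitening by (I - A), per-gene
    elementwise variational heads.  The cell latent is gene-indexed
    (cells x genes) so the KL prior acts on the SEM's exogenous-noise
    coordinates."""

    def __init__(self, params: SemEncoderParams):
        self.params = params

    def tensors(self) -> list[Tensor]:
        return self.params.tensors()

    def encode(self, hyperedge_features: Tensor, A: Tensor) -> tuple[Tensor, Tensor]:
        n = A.shape[0]
        h = _genewise_mlp_forward(hyperedge_features, self.params.mlp)
        z_tilde = h @ (Tensor(np.eye(n)) - A)
        mu = _elementwise_head(z_tilde, self.params.head_mu)
        std = ad.softplus(_elementwise_head(z_tilde, self.params.head_sigma))
        return mu, std
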