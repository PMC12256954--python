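"""Model assembly, parameter initialization, and the two-phase training loop.

Training alternates, for a configured number of cycles, between (phase 1)
RMSprop on all encoder/decoder parameters with the causal matrix ``A``
frozen, and (phase 2) RMSprop on ``A`` alone at its own learning rate with
the network frozen, re-zeroing the diagonal of ``A`` after every step.
Gradients are full-batch: attention coefficients are defined per hyperedge
over the whole incidence, so there is no natural mini-batch decomposition.

Initialization: the diagonal of ``A`` starts at zero and every off-diagonal
entry is drawn ``N(1/(n-1), eps^2)`` with ``n`` the gene count and ``eps``
small, which breaks the symmetry of the all-equal start without moving far
from it.  MLP weights are Kaiming-uniform, attention projections and score
vectors Xavier-uniform, biases zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .data import CausalMatrix, GaussianLatent, Hypergraph
from .encoders import AttentionParams, CellEncoder, GeneEncoder, SemEncoderParams
from .generative import Decoder, LossBreakdown, _kl_terms, _recon_nll
from .optim import RMSprop

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "HyperGVAE",
    "init_causal_matrix",
    "init_network_params",
    "train",
]


@dataclass
class TrainConfig:
    """Training and architecture configuration.

    Optimization: ``cycles`` two-phase alternations of ``epochs_net`` network
    epochs and ``epochs_A`` causal-matrix epochs; separate learning rates
    implement the differential learning-rate strategy.  Loss weights
    ``alpha``/``beta`` scale the two KL terms and ``gamma_sparsity`` the L1
    penalty on ``A``.  Architecture: ``layers`` attention layers with
    ``heads`` heads of ``attn_hidden`` units, gene/cell latent widths, and
    the hidden width of the SEM MLPs.
    """

    epochs_net: int = 50
    epochs_A: int = 50
    cycles: int = 10
    lr_net: float = 1e-3
    lr_A: float = 1e-2
    epsilon_init: float = 1e-4
    seed: int = 0
    alpha: float = 1.0
    beta: float = 1.0
    gamma_sparsity: float = 1.0
    layers: int = 2
    heads: int = 4
    attn_hidden: int = 16
    latent_dim_gene: int = 64
    mlp_hidden: int | None = None
    leaky_slope: float = 0.2
    normalized_smoothing: bool = True

    def __post_init__(self):
        if min(self.epochs_net, self.epochs_A, self.cycles) < 1:
            raise ValueError("epochs and cycles must be >= 1")
        if min(self.lr_net, self.lr_A) <= 0:
            raise ValueError("learning rates must be positive")
        if min(self.alpha, self.beta, self.gamma_sparsity) < 0:
            raise ValueError("loss weights must be non-negative")


def init_causal_matrix(n_genes: int, epsilon: float,
                       seed: int | np.random.Generator = 0) -> CausalMatrix:
    """Zero diagonal, off-diagonal i.i.d. N(1/(n_genes - 1), epsilon^2)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes for a causal matrix")
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = rng.normal(1.0 / (n_genes - 1), epsilon, size=(n_genes, n_genes))
    np.fill_diagonal(A, 0.0)
    return CausalMatrix(A, [f"g{i}" for i in range(n_genes)])


def _kaiming_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def _linear(rng: np.random.Generator, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
    W = Tensor(_kaiming_uniform(rng, n_in, (n_in, n_out)), requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return W, b


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _sigma_head(rng: np.random.Generator, n_in: int, n_out: int,
                init_std: float, weight_scale: float = 0.01
                ) -> tuple[Tensor, Tensor]:
    """A sigma head starting near a constant std: tiny weights, bias at
    softplus^{-1}(init_std).  Wide initial posteriors drown the decoder in
    sampling noise before it has learned anything, so stds start controlled
    and grow only if the objective asks for it."""
    W = Tensor(weight_scale * _kaiming_uniform(rng, n_in, (n_in, n_out)),
               requires_grad=True)
    b = Tensor(np.full(n_out, _softplus_inv(init_std)), requires_grad=True)
    return W, b


def init_network_params(config: TrainConfig, n_genes: int, n_cells: int,
                        rng: np.random.Generator
                        ) -> tuple[GeneEncoder, CellEncoder, Decoder]:
    """Build the three trainable modules with the documented init schemes.
    Deterministic for a fixed generator state.
    """
    # gene encoder: attention stack (Xavier) + variational heads (Kaiming)
    W_layers: list[Tensor] = []
    a_layers: list[Tensor] = []
    in_w = n_cells
    for l in range(config.layers):
        out_w = config.attn_hidden if l < config.layers - 1 else config.latent_dim_gene
        W = np.stack([
            _xavier_uniform(rng, in_w, out_w, (in_w, out_w))
            for _ in range(config.heads)
        ])
        a = np.stack([
            _xavier_uniform(rng, 2 * out_w, 1, (2 * out_w,))
            for _ in range(config.heads)
        ])
        W_layers.append(Tensor(W, requires_grad=True))
        a_layers.append(Tensor(a, requires_grad=True))
        in_w = out_w * config.heads if l < config.layers - 1 else out_w
    attn = AttentionParams(W_layers, a_layers, leak=config.leaky_slope)
    gene_enc = GeneEncoder(
        attn,
        head_mu=_linear(rng, in_w, config.latent_dim_gene),
        head_sigma=_sigma_head(rng, in_w, config.latent_dim_gene, init_std=1.0),
        normalized_smoothing=config.normalized_smoothing,
    )

    # cell encoder: gene-wise f_E and per-gene elementwise heads; cross-gene
    # mixing happens only through A.  The default f_E is a trainable affine
    # map initialized at the identity -- a monotone transform that preserves
    # the gene-gene correlation the SEM fit relies on; a hidden ELU layer is
    # available via mlp_hidden but lets the encoder deform profiles
    # non-monotonically, which degrades the identifiability of A.
    def _genewise_stack() -> list[tuple[Tensor, Tensor]]:
        if config.mlp_hidden is None:
            return [(Tensor(np.ones((1, 1)), requires_grad=True),
                     Tensor(np.zeros(1), requires_grad=True))]
        return [_linear(rng, 1, config.mlp_hidden),
                _linear(rng, config.mlp_hidden, 1)]

    # the mu head starts at the identity and the sigma head at a constant
    # std of 1 (zero slope), so the initial cell KL is exactly the
    # least-squares SEM objective 0.5 * sum(z~^2) in the whitened coordinates
    cell_enc = CellEncoder(SemEncoderParams(
        mlp=_genewise_stack(),
        head_mu=(Tensor(np.ones(n_genes), requires_grad=True),
                 Tensor(np.zeros(n_genes), requires_grad=True)),
        head_sigma=(Tensor(np.zeros(n_genes), requires_grad=True),
                    Tensor(np.full(n_genes, _softplus_inv(1.0)),
                           requires_grad=True)),
    ))

    # decoder: gene-wise stack, inverse SEM, dense heads to the gene-latent
    # width; its output std starts small so sampling noise does not drown
    # the reconstruction before the fit forms
    dec = Decoder(
        mlp=_genewise_stack(),
        head_mu=_linear(rng, n_genes, config.latent_dim_gene),
        head_sigma=_sigma_head(rng, n_genes, config.latent_dim_gene,
                               init_std=0.1),
    )
    return gene_enc, cell_enc, dec


class HyperGVAE:
    """The assembled model: both encoders, the decoder, and ``A``."""

    def __init__(self, gene_encoder: GeneEncoder, cell_encoder: CellEncoder,
                 decoder: Decoder, A: Tensor, gene_ids: list[str],
                 config: TrainConfig):
        self.gene_encoder = gene_encoder
        self.cell_encoder = cell_encoder
        self.decoder = decoder
        self.A = A
        self.gene_ids = list(gene_ids)
        self.config = config

    def network_tensors(self) -> list[Tensor]:
        return [*self.gene_encoder.tensors(), *self.cell_encoder.tensors(),
                *self.decoder.tensors()]

    def zero_grad(self) -> None:
        for t in [*self.network_tensors(), self.A]:
            t.grad = None

    def causal_matrix(self) -> CausalMatrix:
        return CausalMatrix(self.A.data.copy(), self.gene_ids)

    def loss(self, hg: Hypergraph, rng: np.random.Generator,
             phase: str = "network") -> tuple[Tensor, LossBreakdown]:
        """One full-batch forward pass; returns the differentiable objective
        for the given phase and the concrete full-loss breakdown.

        In the network phase the objective is the full weighted loss.  In
        the A phase it is ``beta * KL_cell + gamma * |A|`` -- the terms in
        which the causal matrix acts structurally (whitening the cell
        posterior).  The reconstruction reaches A only through the sampled
        cell latent, where its gradient is a common-mode term orders of
        magnitude above the per-edge signal; stepping A on it erases the
        edge ranking, so it is excluded from the A-phase objective.
        """
        cfg = self.config
        target = hg.hyperedge_features  # cells x genes, normalized
        mu_v, std_v = self.gene_encoder.encode(hg)
        mu_e, std_e = self.cell_encoder.encode(Tensor(target), self.A)
        eps_v = rng.standard_normal(mu_v.shape)
        eps_e = rng.standard_normal(mu_e.shape)
        z_v = mu_v + std_v * Tensor(eps_v)
        z_e = mu_e + std_e * Tensor(eps_e)
        # the decoder consumes A without passing gradient back: the inverse
        # colouring's gradient is dominated by a common-mode term along the
        # near-singular direction that swamps the per-edge signal, so A is
        # learned through the encoder whitening + KL path (and the L1)
        mu_d, std_d = self.decoder.decode(z_e, self.A.detach())
        eps_d = rng.standard_normal(mu_d.shape)
        z_e_dec = mu_d + std_d * Tensor(eps_d)
        recon = z_e_dec @ z_v.T
        rec_t = _recon_nll(target, recon)
        kl_v = _kl_terms(mu_v, std_v)
        kl_e = _kl_terms(mu_e, std_e)
        sparse = self.A.abs().sum()
        if phase == "A":
            total = cfg.beta * kl_e + cfg.gamma_sparsity * sparse
        else:
            total = (rec_t + cfg.alpha * kl_v + cfg.beta * kl_e
                     + cfg.gamma_sparsity * sparse)
        breakdown = LossBreakdown(
            reconstruction=float(rec_t.data), kl_gene=float(kl_v.data),
            kl_cell=float(kl_e.data), sparsity=float(sparse.data),
            alpha=cfg.alpha, beta=cfg.beta, gamma_sparsity=cfg.gamma_sparsity,
        )
        return total, breakdown

    def cell_embedding(self, hg: Hypergraph) -> np.ndarray:
        """Posterior mean of the cell latent (cells x d'), the embedding used
        for clustering and visualization."""
        mu, _ = self.cell_encoder.encode(Tensor(hg.hyperedge_features), self.A)
        return mu.data

    def gene_embedding(self, hg: Hypergraph) -> np.ndarray:
        """Posterior mean of the gene latent (genes x d)."""
        mu, _ = self.gene_encoder.encode(hg)
        return mu.data

    def gene_posteriors(self, hg: Hypergraph) -> tuple[GaussianLatent, GaussianLatent]:
        mu_v, std_v = self.gene_encoder.encode(hg)
        mu_e, std_e = self.cell_encoder.encode(Tensor(hg.hyperedge_features), self.A)
        return (GaussianLatent(mu_v.data, std_v.data),
                GaussianLatent(mu_e.data, std_e.data))


@dataclass
class TrainedModel:
    model: HyperGVAE
    causal: CausalMatrix
    loss_trajectory: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None
    seed: int = 0

    def save(self, out_dir: str | Path) -> None:
        """Serialize the causal matrix (TSV), parameters (npz) and loss log."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(self.causal.values, index=self.causal.gene_ids,
                     columns=self.causal.gene_ids).to_csv(
            out_dir / "causal_matrix.tsv", sep="\t")
        arrays = {f"p{i}": t.data for i, t in
                  enumerate([*self.model.network_tensors(), self.model.A])}
        np.savez(out_dir / "params.npz", **arrays)
        pd.DataFrame(self.loss_trajectory).to_csv(
            out_dir / "loss_log.tsv", sep="\t", index=False)


def train(hg: Hypergraph, config: TrainConfig | None = None) -> TrainedModel:
    """Two-phase alternating optimization of the full model on a hypergraph."""
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    n, m = hg.n_genes, hg.n_cells
    A0 = init_causal_matrix(n, config.epsilon_init, rng)
    A = Tensor(A0.values, requires_grad=True)
    gene_enc, cell_enc, dec = init_network_params(config, n, m, rng)
    model = HyperGVAE(gene_enc, cell_enc, dec, A, hg.gene_ids, config)

    opt_net = RMSprop(model.network_tensors(), lr=config.lr_net)
    opt_A = RMSprop([A], lr=config.lr_A)
    trajectory: list[dict] = []
    diag = np.diag_indices(n)

    def run_epoch(phase: str, opt: RMSprop, cycle: int, epoch: int) -> None:
        model.zero_grad()
        total, breakdown = model.loss(hg, rng, phase=phase)
        if not np.isfinite(total.data):
            terms = {k: getattr(breakdown, k) for k in
                     ("reconstruction", "kl_gene", "kl_cell", "sparsity")}
            bad = [k for k, v in terms.items() if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite loss in {phase} (cycle {cycle}, epoch {epoch}); "
                f"offending terms: {bad or 'total only'}; breakdown: {terms}"
            )
        total.backward()
        if phase == "A":
            A.grad[diag] = 0.0
        opt.step()
        if phase == "A":
            A.data[diag] = 0.0
        trajectory.append({
            "cycle": cycle, "phase": phase, "epoch": epoch,
            "reconstruction": breakdown.reconstruction,
            "kl_gene": breakdown.kl_gene, "kl_cell": breakdown.kl_cell,
            "sparsity": breakdown.sparsity, "total": breakdown.total,
        })

    for cycle in range(config.cycles):
        for epoch in range(config.epochs_net):
            run_epoch("network", opt_net, cycle, epoch)
        for epoch in range(config.epochs_A):
            run_epoch("A", opt_A, cycle, epoch)

    return TrainedModel(model=model, causal=model.causal_matrix(),
                        loss_trajectory=trajectory, config=config,
                        seed=config.seed)
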