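"""Decoder (SEM inversion + reconstruction) and the training objective.

The decoder mirrors the cell encoder: an MLP maps the cell latent back to a
gene-indexed feature space, the inverse SEM colouring ``F -> F (I - A)^{-1}``
re-introduces the causal structure, and a variational head plus
reparameterization yields the decoded cell representation ``Z^{E'}``.  The
expression matrix is reconstructed as the inner product of cell and gene
latents over the shared latent dimension, ``H~V[c, g] = <Z^{E'}[c], Z^V[g]>``
(a cells x genes matrix).

The objective is a weighted negative ELBO plus a sparsity penalty:

    total = recon + alpha * KL_gene + beta * KL_cell + gamma * sum|A|

with ``recon`` the unit-variance Gaussian negative log-likelihood
``0.5 * sum (HV - H~V)^2`` and each KL the closed form against a standard
normal prior, summed over entries.  Keeping every term a sum over entries
puts the four terms on a common scale, so the weights have the usual
beta-VAE interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import CausalMatrix, GaussianLatent

__all__ = [
    "Decoder",
    "LossBreakdown",
    "sem_decode",
    "reconstruct",
    "gaussian_kl",
    "elbo_loss",
]


@dataclass
class LossBreakdown:
    reconstruction: float
    kl_gene: float
    kl_cell: float
    sparsity: float
    alpha: float
    beta: float
    gamma_sparsity: float

    def __post_init__(self):
        for name in ("reconstruction", "kl_gene", "kl_cell", "sparsity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.alpha, self.beta, self.gamma_sparsity) < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def total(self) -> float:
        return (self.reconstruction + self.alpha * self.kl_gene
                + self.beta * self.kl_cell + self.gamma_sparsity * self.sparsity)


class Decoder:
    """MLP + inverse-SEM + variational head, the generative half."""

    def __init__(self, mlp: list[tuple[Tensor, Tensor]],
                 head_mu: tuple[Tensor, Tensor], head_sigma: tuple[Tensor, Tensor]):
        self.mlp = mlp
        self.head_mu = head_mu
        self.head_sigma = head_sigma

    def tensors(self) -> list[Tensor]:
        out: list[Tensor] = []
        for W, b in [*self.mlp, self.head_mu, self.head_sigma]:
            out.extend([W, b])
        return out

    def decode(self, z_cell: Tensor, A: Tensor) -> tuple[Tensor, Tensor]:
        """Posterior (mean, std) of the decoded cell representation.

        ``z_cell`` is the gene-indexed cell latent (cells x genes); the MLP
        mirrors the encoder's gene-wise stack, the inverse SEM re-colours the
        noise coordinates, and dense heads map genes to the reconstruction
        latent width shared with the gene encoder.
        """
        from .encoders import _genewise_mlp_forward, _linear_head

        n = A.shape[0]
        h = _genewise_mlp_forward(z_cell, self.mlp)
        cond = np.linalg.cond(np.eye(n) - A.data)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"I - A^T is numerically singular (condition number {cond:.3g})"
            )
        z_tilde = h @ ad.inv(Tensor(np.eye(n)) - A)
        mu = _linear_head(z_tilde, self.head_mu)
        std = ad.softplus(_linear_head(z_tilde, self.head_sigma))
        return mu, std


def sem_decode(z_cell: np.ndarray, A: CausalMatrix, decoder: Decoder,
               rng: np.random.Generator) -> np.ndarray:
    """Run the full decoding path on a cell latent sample: MLP, inverse SEM,
    variational head, reparameterization.  Requires spectral radius of A^T
    below 1 so the series inversion is defined.
    """
    if A.spectral_radius() >= 1:
        raise ValueError("spectral radius of A^T must be < 1 for SEM inversion")
    mu, std = decoder.decode(Tensor(np.asarray(z_cell, float)), Tensor(A.values))
    eps = rng.standard_normal(mu.shape)
    return mu.data + std.data * eps


def reconstruct(z_gene: np.ndarray, z_cell_dec: np.ndarray) -> np.ndarray:
    """Inner product over the shared latent width: a cells x genes matrix
    with ``out[c, g] = <z_cell_dec[c], z_gene[g]>``.
    """
    z_gene = np.asarray(z_gene, float)
    z_cell_dec = np.asarray(z_cell_dec, float)
    if z_gene.shape[1] != z_cell_dec.shape[1]:
        raise ValueError("gene and cell latents must share the latent width")
    return z_cell_dec @ z_gene.T


def gaussian_kl(q: GaussianLatent) -> float:
    """Closed-form KL(N(mu, sigma^2) || N(0, I)) summed over all entries."""
    return float(_kl_terms(Tensor(q.mean), Tensor(q.std)).data)


def _kl_terms(mu: Tensor, std: Tensor) -> Tensor:
    return (0.5 * (mu**2 + std**2 - 1.0) - std.log()).sum()


def _recon_nll(target: np.ndarray, recon: Tensor) -> Tensor:
    return 0.5 * ((recon - Tensor(target)) ** 2).sum()


def elbo_loss(HV: np.ndarray, HV_hat: np.ndarray, q_gene: GaussianLatent,
              q_cell: GaussianLatent, A: CausalMatrix,
              alpha: float = 1.0, beta: float = 1.0,
              gamma_sparsity: float = 1.0) -> LossBreakdown:
    """Evaluate the full objective on concrete arrays (no gradients)."""
    if min(alpha, beta, gamma_sparsity) < 0:
        raise ValueError("loss weights must be non-negative")
    HV = np.asarray(HV, float)
    HV_hat = np.asarray(HV_hat, float)
    if HV.shape != HV_hat.shape:
        raise ValueError("reconstruction shape does not match the input")
    return LossBreakdown(
        reconstruction=float(0.5 * np.sum((HV - HV_hat) ** 2)),
        kl_gene=gaussian_kl(q_gene),
        kl_cell=gaussian_kl(q_cell),
        sparsity=float(np.sum(np.abs(A.values))),
        alpha=alpha,
        beta=beta,
        gamma_sparsity=gamma_sparsity,
    )
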