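"""Negative-binomial and zero-inflated negative-binomial log-likelihoods.

The decoder parameterizes a ZINB distribution over raw counts: a point mass
at zero with probability π mixed with NB(μ, θ) in the mean–dispersion
convention (variance μ + μ²/θ). These functions are the reconstruction
term of the training objective and are exact — everything is computed in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from . import autodiff as ad

__all__ = ["ZINBParams", "nb_log_pmf", "zinb_log_pmf", "zinb_reconstruction_loss"]

# floors applied inside the training loss only (spec'd stability clamps)
_EPS = 1e-8


@dataclass
class ZINBParams:
    """(μ, θ, π) arrays broadcastable to cells × genes.

    μ > 0 is the NB mean, θ > 0 the inverse-dispersion (larger θ → closer
    to Poisson), π ∈ [0, 1] the zero-inflation probability.
    """

    mu: np.ndarray
    theta: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.pi = np.asarray(self.pi, dtype=np.float64)
        if (self.mu <= 0).any():
            raise ValueError("mu must be positive")
        if (self.theta <= 0).any():
            raise ValueError("theta must be positive")
        if ((self.pi < 0) | (self.pi > 1)).any():
            raise ValueError("pi must lie in [0, 1]")


def _check_counts(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("counts must be integral")
    return x


def nb_log_pmf(x, mu, theta) -> np.ndarray:
    """ln NB(x; μ, θ) in the mean–dispersion parameterization.

    ln Γ(x+θ) − ln Γ(θ) − ln Γ(x+1) + θ ln(θ/(θ+μ)) + x ln(μ/(θ+μ)).
    """
    x = _check_counts(x)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if (mu <= 0).any() or (theta <= 0).any():
        raise ValueError("mu and theta must be positive")
    return (
        sp.gammaln(x + theta)
        - sp.gammaln(theta)
        - sp.gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )


def zinb_log_pmf(x, params: ZINBParams) -> np.ndarray:
    """ln ZINB(x; μ, θ, π).

    For x = 0: ln(π + (1−π)·NB(0)), evaluated with log-sum-exp; for x > 0:
    ln(1−π) + ln NB(x).
    """
    x = _check_counts(x)
    nb = nb_log_pmf(x, params.mu, params.theta)
    x_b, pi, nb = np.broadcast_arrays(x, params.pi, nb)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log1mpi = np.log1p(-pi)
    zero_branch = np.logaddexp(log_pi, log1mpi + nb)
    pos_branch = log1mpi + nb
    return np.where(x_b == 0, zero_branch, pos_branch)


def zinb_reconstruction_loss(batch, params: ZINBParams) -> float:
    """Mean-per-cell negative ZINB log-likelihood of a count batch.

    −(1/M_b) Σ_cells Σ_genes ln ZINB(x_ij). Parameters are floored
    (μ, θ ≥ 1e-8; π kept inside (0, 1)) so the loss is always finite.
    """
    batch = _check_counts(batch)
    safe = ZINBParams(
        mu=np.maximum(params.mu, _EPS),
        theta=np.maximum(params.theta, _EPS),
        pi=np.clip(params.pi, _EPS, 1.0 - _EPS),
    )
    ll = zinb_log_pmf(batch, safe)
    ll = np.broadcast_to(ll, np.broadcast_shapes(batch.shape, ll.shape))
    n_cells = ll.shape[0] if ll.ndim == 2 else 1
    return float(-ll.sum() / n_cells)


# ----------------------------------------------------- differentiable form
def zinb_nll_tensors(x: np.ndarray, mu: ad.Tensor, theta: ad.Tensor, pi: ad.Tensor) -> ad.Tensor:
    """ZINB negative log-likelihood as an autodiff graph (training path).

    ``x`` is a constant count batch; μ, θ, π are decoder outputs. Same
    clamping as :func:`zinb_reconstruction_loss`; matches it numerically
    (cross-checked in the test suite).
    """
    x = np.asarray(x, dtype=np.float64)
    mu = ad.clip(mu, _EPS, 1e8)
    theta = ad.clip(theta, _EPS, 1e8)
    pi = ad.clip(pi, _EPS, 1.0 - _EPS)
    xt = ad.Tensor(x)
    log_theta_mu = (theta + mu).log()
    nb_ll = (
        ad.lgamma(xt + theta)
        - ad.lgamma(theta)
        - ad.Tensor(sp.gammaln(x + 1.0))
        + theta * (theta.log() - log_theta_mu)
        + xt * (mu.log() - log_theta_mu)
    )
    zero_mask = ad.Tensor((x == 0).astype(np.float64))
    one_m_pi = 1.0 - pi
    # x = 0: ln(π + (1−π)·e^{nb_ll}); exp underflows harmlessly for tiny mass
    zero_ll = (pi + one_m_pi * nb_ll.exp()).log()
    pos_ll = one_m_pi.log() + nb_ll
    ll = zero_mask * zero_ll + (1.0 - zero_mask) * pos_ll
    n_cells = x.shape[0] if x.ndim == 2 else 1
    return ll.sum() * (-1.0 / n_cells)
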