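"""Adversarial training objectives and Bhattacharyya distances.

Four interchangeable objectives drive the two discriminators:

* ``standard`` — the original cross-entropy minimax game (non-saturating
  generator form);
* ``wasserstein`` — critic maximizes the mean score gap;
* ``wasserstein_gp`` — same, plus a gradient penalty on interpolates to
  enforce the 1-Lipschitz constraint;
* ``bhattacharyya`` — the objective that defines DR-A: the discriminator
  maximizes, and the generator minimizes, the Bhattacharyya distance
  between the distributions of real-sample and fake-sample scores. Score
  distributions are summarized by Gaussian moment matching of the batch
  (sample mean and population variance), which keeps the distance
  computable and differentiable.

Public functions take a :class:`ScoreBatch` of numpy score vectors and
return plain floats; the ``*_t`` tensor forms are the training path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ScoreBatch",
    "AdversarialLossPair",
    "standard_gan_loss",
    "wasserstein_loss",
    "gradient_penalty",
    "bhattacharyya_discrete",
    "bhattacharyya_gaussian",
    "bd_adversarial_loss",
    "OBJECTIVES",
]

#: objective token → discriminator score domain
OBJECTIVES = {
    "standard": "probability",
    "wasserstein": "unbounded",
    "wasserstein_gp": "unbounded",
    "bhattacharyya": "probability",
}

_VAR_FLOOR = 1e-6


@dataclass
class ScoreBatch:
    """Discriminator outputs on a real batch and a generated batch."""

    real_scores: np.ndarray
    fake_scores: np.ndarray
    score_domain: str = "probability"

    def __post_init__(self):
        self.real_scores = np.asarray(self.real_scores, dtype=np.float64).ravel()
        self.fake_scores = np.asarray(self.fake_scores, dtype=np.float64).ravel()
        if self.score_domain not in ("probability", "unbounded"):
            raise ValueError("score_domain must be 'probability' or 'unbounded'")
        if self.score_domain == "probability":
            allv = np.concatenate([self.real_scores, self.fake_scores])
            if ((allv <= 0) | (allv >= 1)).any():
                raise ValueError("probability-domain scores must lie in (0, 1)")


@dataclass
class AdversarialLossPair:
    discriminator_loss: float
    generator_loss: float


# ------------------------------------------------------------ standard GAN
_P_EPS = 1e-7  # keeps ln D finite when the sigmoid saturates during training


def standard_disc_loss_t(real: Tensor, fake: Tensor) -> Tensor:
    real = ad.clip(real, _P_EPS, 1.0 - _P_EPS)
    fake = ad.clip(fake, _P_EPS, 1.0 - _P_EPS)
    return -(real.log().mean()) - (1.0 - fake).log().mean()


def standard_gen_loss_t(fake: Tensor) -> Tensor:
    # non-saturating form: maximize ln D(G(z))
    fake = ad.clip(fake, _P_EPS, 1.0 - _P_EPS)
    return -(fake.log().mean())


def standard_gan_loss(scores: ScoreBatch) -> AdversarialLossPair:
    """Cross-entropy minimax losses; requires probability-domain scores."""
    if scores.score_domain != "probability":
        raise ValueError("standard GAN loss needs probability-domain scores")
    r, f = Tensor(scores.real_scores), Tensor(scores.fake_scores)
    return AdversarialLossPair(
        discriminator_loss=standard_disc_loss_t(r, f).item(),
        generator_loss=standard_gen_loss_t(f).item(),
    )


# ------------------------------------------------------------- Wasserstein
def wasserstein_disc_loss_t(real: Tensor, fake: Tensor) -> Tensor:
    return -(real.mean() - fake.mean())


def wasserstein_gen_loss_t(fake: Tensor) -> Tensor:
    return -(fake.mean())


def wasserstein_loss(scores: ScoreBatch) -> AdversarialLossPair:
    """Critic loss −(E[D(x)] − E[D(G(z))]) and generator loss −E[D(G(z))]."""
    r, f = Tensor(scores.real_scores), Tensor(scores.fake_scores)
    return AdversarialLossPair(
        discriminator_loss=wasserstein_disc_loss_t(r, f).item(),
        generator_loss=wasserstein_gen_loss_t(f).item(),
    )


# -------------------------------------------------------- gradient penalty
def gradient_penalty_t(scorer, real_batch: np.ndarray, fake_batch: np.ndarray,
                       penalty_weight: float, rng: np.random.Generator) -> Tensor:
    """λ · E[(‖∇_x̂ D(x̂)‖₂ − 1)²] on uniform interpolates x̂.

    ``scorer`` must map a Tensor batch to a Tensor of per-sample scores and
    be built from differentiable operations (double backprop is used, so
    the returned penalty can itself be minimized w.r.t. critic weights).
    """
    real_batch = np.asarray(real_batch, dtype=np.float64)
    fake_batch = np.asarray(fake_batch, dtype=np.float64)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have identical shapes")
    eps = rng.random((real_batch.shape[0], 1))
    x_hat = Tensor(eps * real_batch + (1.0 - eps) * fake_batch, requires_grad=True)
    scores = scorer(x_hat)
    if not isinstance(scores, Tensor):
        raise TypeError("scorer must return a Tensor (differentiable scores)")
    g = ad.grad(scores.sum(), x_hat, create_graph=True)
    norms = ((g ** 2.0).sum(axis=1) + 1e-12) ** 0.5
    return float(penalty_weight) * ((norms - 1.0) ** 2.0).mean()


def gradient_penalty(scorer, real_batch, fake_batch, penalty_weight: float = 10.0,
                     rng: np.random.Generator | None = None) -> float:
    if rng is None:
        rng = np.random.default_rng(0)
    return gradient_penalty_t(scorer, real_batch, fake_batch, penalty_weight, rng).item()


# ------------------------------------------------------------ Bhattacharyya
def bhattacharyya_discrete(p, q) -> float:
    """BD(p, q) = −ln Σ_x √(p(x)·q(x)) for discrete distributions."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be nonnegative")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 (got {v.sum()!r})")
    coeff = np.sqrt(p * q).sum()
    if coeff <= 0.0:
        return float("inf")
    return float(-np.log(coeff))


def bhattacharyya_gaussian(mean1: float, var1: float, mean2: float, var2: float) -> float:
    """Closed-form BD between N(mean1, var1) and N(mean2, var2)."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    return float(
        0.25 * (mean1 - mean2) ** 2 / (var1 + var2)
        + 0.5 * np.log((var1 + var2) / (2.0 * np.sqrt(var1 * var2)))
    )


def _moments_t(scores: Tensor) -> tuple[Tensor, Tensor]:
    m = scores.mean()
    v = ad.clip(((scores - m) ** 2.0).mean(), _VAR_FLOOR, np.inf)
    return m, v


def _bd_gaussian_t(m1, v1, m2, v2) -> Tensor:
    m1, v1 = ad.as_tensor(m1), ad.as_tensor(v1)
    m2, v2 = ad.as_tensor(m2), ad.as_tensor(v2)
    return (m1 - m2) ** 2.0 / (v1 + v2) * 0.25 + ((v1 + v2) / ((v1 * v2) ** 0.5 * 2.0)).log() * 0.5


def bd_disc_loss_t(real: Tensor, fake: Tensor) -> Tensor:
    """−BD between Gaussian fits of the two score batches (D maximizes BD)."""
    mr, vr = _moments_t(real)
    mf, vf = _moments_t(fake)
    return -_bd_gaussian_t(mr, vr, mf, vf)


def bd_gen_loss_t(fake: Tensor, real_detached: Tensor) -> Tensor:
    """+BD of fake-score moments against frozen real-score moments."""
    mr, vr = _moments_t(real_detached.detach())
    mf, vf = _moments_t(fake)
    return _bd_gaussian_t(mr.detach(), vr.detach(), mf, vf)


def bd_adversarial_loss(scores: ScoreBatch) -> AdversarialLossPair:
    """The DR-A objective on a score batch.

    Both batches need ≥ 2 samples (the Gaussian fit uses a per-batch
    variance, floored at 1e-6).
    """
    if len(scores.real_scores) < 2 or len(scores.fake_scores) < 2:
        raise ValueError("Bhattacharyya objective needs at least 2 scores per side")
    r, f = Tensor(scores.real_scores), Tensor(scores.fake_scores)
    return AdversarialLossPair(
        discriminator_loss=bd_disc_loss_t(r, f).item(),
        generator_loss=bd_gen_loss_t(f, r).item(),
    )
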