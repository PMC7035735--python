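"""Fully connected networks: variational encoder, ZINB decoder, discriminators.

All networks follow the same architecture family: 1–4 hidden layers with
widths from {8, 16, ..., 1024}, LeakyReLU activations between hidden layers
and dropout regularization on hidden units. The encoder doubles as the
generator of the latent-space adversarial game; the decoder's output feeds
the data-space discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "NetworkSpec",
    "EncoderOutput",
    "MLP",
    "Encoder",
    "Decoder",
    "Discriminator",
    "reparameterize",
    "sample_prior",
]

_ALLOWED_SIZES = {8, 16, 32, 64, 128, 256, 512, 1024}


@dataclass
class NetworkSpec:
    """Hidden-layer widths plus activation/regularization settings."""

    layer_sizes: list[int]
    leaky_slope: float = 0.2
    dropout_rate: float = 0.1
    allow_any_sizes: bool = False

    def __post_init__(self):
        self.layer_sizes = [int(s) for s in self.layer_sizes]
        if not 1 <= len(self.layer_sizes) <= 4:
            raise ValueError("between 1 and 4 hidden layers are supported")
        if not self.allow_any_sizes:
            bad = [s for s in self.layer_sizes if s not in _ALLOWED_SIZES]
            if bad:
                raise ValueError(
                    f"layer sizes {bad} outside the supported set "
                    f"{sorted(_ALLOWED_SIZES)}; pass allow_any_sizes=True to override"
                )
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class EncoderOutput:
    """Per-cell Gaussian posterior parameters q(z|x) = N(mean, diag(exp(log_var)))."""

    mean: Tensor
    log_var: Tensor


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    # He initialization suits the LeakyReLU trunk
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


class MLP:
    """LeakyReLU/dropout trunk with an arbitrary number of linear heads."""

    def __init__(self, in_dim: int, spec: NetworkSpec, head_dims: list[int],
                 rng: np.random.Generator):
        self.spec = spec
        self.in_dim = int(in_dim)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        prev = in_dim
        for size in spec.layer_sizes:
            w, b = _init_linear(rng, prev, size)
            self.weights.append(w)
            self.biases.append(b)
            prev = size
        self.heads: list[tuple[Tensor, Tensor]] = []
        for hd in head_dims:
            # heads are linear read-outs; Glorot-ish scale
            w = Tensor(rng.normal(0.0, np.sqrt(1.0 / prev), size=(prev, hd)),
                       requires_grad=True)
            b = Tensor(np.zeros(hd), requires_grad=True)
            self.heads.append((w, b))

    def parameters(self) -> list[Tensor]:
        ps = []
        for w, b in zip(self.weights, self.biases):
            ps += [w, b]
        for w, b in self.heads:
            ps += [w, b]
        return ps

    def trunk(self, x: Tensor, train: bool = False,
              rng: np.random.Generator | None = None) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"input width {x.shape[-1]} != expected {self.in_dim}")
        h = x
        for w, b in zip(self.weights, self.biases):
            h = ad.leaky_relu(h @ w + b, self.spec.leaky_slope)
            if train and self.spec.dropout_rate > 0.0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                keep = 1.0 - self.spec.dropout_rate
                mask = (rng.random(h.shape) < keep).astype(np.float64) / keep
                h = h * Tensor(mask)
        return h

    def forward(self, x: Tensor, train: bool = False,
                rng: np.random.Generator | None = None) -> list[Tensor]:
        h = self.trunk(x, train=train, rng=rng)
        return [h @ w + b for w, b in self.heads]


class Encoder(MLP):
    """Maps log-expression vectors to the mean and log-variance of q(z|x)."""

    #: initial bias of the log-variance head. Starting with a tight
    #: posterior (std ≈ e^{-2} ≈ 0.14) keeps early z-samples close to the
    #: posterior mean, so the decoder sees separable codes from the first
    #: epochs; the variance is free to grow during training.
    LOG_VAR_BIAS_INIT = -4.0

    def __init__(self, n_genes: int, spec: NetworkSpec, latent_dim: int,
                 rng: np.random.Generator):
        super().__init__(n_genes, spec, [latent_dim, latent_dim], rng)
        self.latent_dim = int(latent_dim)
        self.heads[1][1].data += self.LOG_VAR_BIAS_INIT

    def encode(self, x, train: bool = False,
               rng: np.random.Generator | None = None) -> EncoderOutput:
        mean, log_var = self.forward(ad.as_tensor(x), train=train, rng=rng)
        return EncoderOutput(mean=mean, log_var=log_var)


class Decoder(MLP):
    """Maps latent codes to ZINB parameters (μ, θ, π) per gene.

    μ and θ use exponential links with pre-activation clamping so the
    outputs stay inside [1e-8, 1e8]; π uses a sigmoid link.
    """

    _LOG_LIM = 18.420680743952367  # ln(1e8)

    def __init__(self, latent_dim: int, spec: NetworkSpec, n_genes: int,
                 rng: np.random.Generator):
        super().__init__(latent_dim, spec, [n_genes, n_genes, n_genes], rng)
        self.latent_dim = int(latent_dim)
        self.n_genes = int(n_genes)

    def decode(self, z, train: bool = False,
               rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor, Tensor]:
        z = ad.as_tensor(z)
        if not np.all(np.isfinite(z.data)):
            raise ValueError("latent codes must be finite")
        h_mu, h_theta, h_pi = self.forward(z, train=train, rng=rng)
        # pre-clip keeps exp finite; post-clip pins the exact [1e-8, 1e8] range
        mu = ad.clip(ad.clip(h_mu, -self._LOG_LIM, self._LOG_LIM).exp(), 1e-8, 1e8)
        theta = ad.clip(ad.clip(h_theta, -self._LOG_LIM, self._LOG_LIM).exp(), 1e-8, 1e8)
        # sigmoid saturates to exactly 0/1 in float64 for |logit| ≳ 37;
        # keep π strictly inside the open unit interval
        pi = ad.clip(ad.sigmoid(h_pi), 1e-10, 1.0 - 1e-10)
        return mu, theta, pi


class Discriminator(MLP):
    """Scores samples as real vs generated.

    ``domain='probability'`` puts a sigmoid on the scalar head (standard
    GAN and Bhattacharyya objectives); ``domain='unbounded'`` leaves it
    linear (Wasserstein critics).
    """

    def __init__(self, in_dim: int, spec: NetworkSpec, rng: np.random.Generator,
                 domain: str = "probability"):
        if domain not in ("probability", "unbounded"):
            raise ValueError("domain must be 'probability' or 'unbounded'")
        super().__init__(in_dim, spec, [1], rng)
        self.domain = domain

    def score(self, x, train: bool = False,
              rng: np.random.Generator | None = None) -> Tensor:
        (raw,) = self.forward(ad.as_tensor(x), train=train, rng=rng)
        raw = raw.reshape(-1)
        return ad.sigmoid(raw) if self.domain == "probability" else raw


def reparameterize(out: EncoderOutput, noise) -> Tensor:
    """z = mean + exp(log_var / 2) ⊙ ε with ε ~ N(0, I)."""
    noise = ad.as_tensor(noise)
    if noise.shape != out.mean.shape:
        raise ValueError("noise shape must match the posterior mean")
    return out.mean + (out.log_var * 0.5).exp() * noise


def sample_prior(n: int, latent_dim: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from the N(0, I) latent prior."""
    if n < 1:
        raise ValueError("need at least one sample")
    return rng.standard_normal((n, latent_dim))
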