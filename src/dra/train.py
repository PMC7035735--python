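"""AVAE / AVAE-DM training loops, presets and checkpointing.

The model couples a variational autoencoder (encoder → latent z → ZINB
decoder) with one or two adversarial games:

* D1 pushes the aggregate posterior q(z) toward the N(0, I) prior — this
  replaces the KL term of a classical VAE;
* with dual matching, D2 additionally pushes the distribution of
  reconstructed expression profiles toward the real data distribution.

Per minibatch the loop runs: (a) a reconstruction step on the ZINB
negative log-likelihood updating encoder+decoder, (b) a D1 update,
(c) ``gen_updates_per_disc`` encoder updates against D1, and — when dual
matching is on — (d) a D2 update followed by encoder+decoder updates
against D2 at the same ratio. All optimizers are Adam; all randomness
derives from ``config.seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import objectives as obj
from .autodiff import Tensor
from .io import CountMatrix, ProcessedMatrix
from .networks import Decoder, Discriminator, Encoder, NetworkSpec, reparameterize, sample_prior
from .zinb import zinb_nll_tensors

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "DRAModel",
    "Adam",
    "train_model",
    "project",
    "preset_config",
    "demo_config",
]

logger = logging.getLogger("dra.train")

_LN2 = float(np.log(2.0))


@dataclass
class TrainConfig:
    """All knobs of one training run."""

    latent_dim: int = 2
    objective: str = "bhattacharyya"
    encoder_spec: NetworkSpec = field(default_factory=lambda: NetworkSpec([128, 64]))
    decoder_spec: NetworkSpec = field(default_factory=lambda: NetworkSpec([64, 128]))
    d1_spec: NetworkSpec = field(default_factory=lambda: NetworkSpec([32, 32]))
    d2_spec: NetworkSpec = field(default_factory=lambda: NetworkSpec([32, 32]))
    batch_size: int = 128
    learning_rate: float = 1e-3
    epochs: int = 300
    gen_updates_per_disc: int = 2
    dual_matching: bool = True
    seed: int = 0
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gp_weight: float = 10.0
    early_stopping_patience: int = 30
    early_stopping_min_delta: float = 1e-3
    #: feed D2 the expected reconstruction μ(1−π) (default) or a ZINB draw
    d2_sample: bool = False

    def __post_init__(self):
        if self.objective not in obj.OBJECTIVES:
            raise ValueError(
                f"unknown objective {self.objective!r}; choose from {sorted(obj.OBJECTIVES)}"
            )
        if self.batch_size < 2:
            raise ValueError("batch_size must be ≥ 2 (per-batch score variance is used)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.gen_updates_per_disc < 1:
            raise ValueError("gen_updates_per_disc must be positive")
        if any(w <= 0 for w in self.loss_weights):
            raise ValueError("loss weights must be positive")

    @property
    def score_domain(self) -> str:
        return obj.OBJECTIVES[self.objective]


@dataclass
class TrainHistory:
    """Per-epoch mean losses. Dual-matching histories carry D2 entries."""

    records: dict[str, list[float]] = field(default_factory=dict)

    def append(self, **losses: float) -> None:
        for k, v in losses.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite loss for {k}: {v}")
            self.records.setdefault(k, []).append(float(v))

    @property
    def n_epochs(self) -> int:
        return len(self.records.get("reconstruction", []))


class Adam:
    """Adaptive-moment stochastic gradient descent (β₁=0.9, β₂=0.999)."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            mhat = m / (1.0 - self.b1 ** self.t)
            vhat = v / (1.0 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DRAModel:
    """A trained (or freshly initialized) AVAE / AVAE-DM."""

    def __init__(self, config: TrainConfig, n_genes: int, gene_ids: list[str] | None = None):
        self.config = config
        self.n_genes = int(n_genes)
        self.gene_ids = list(gene_ids) if gene_ids is not None else None
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        self.encoder = Encoder(n_genes, config.encoder_spec, config.latent_dim, rng)
        self.decoder = Decoder(config.latent_dim, config.decoder_spec, n_genes, rng)
        self.d1 = Discriminator(config.latent_dim, config.d1_spec, rng, config.score_domain)
        self.d2 = (
            Discriminator(n_genes, config.d2_spec, rng, config.score_domain)
            if config.dual_matching
            else None
        )

    # ------------------------------------------------------------- inference
    def project(self, x) -> np.ndarray:
        """Posterior mean embedding (deterministic: no sampling, no dropout)."""
        arr = _as_gene_matrix(x, self)
        return self.encoder.encode(Tensor(arr)).mean.data.copy()

    def reconstruct_expected(self, x) -> np.ndarray:
        """Expected reconstructed counts μ(1−π) at the posterior mean."""
        z = self.project(x)
        mu, _, pi = self.decoder.decode(Tensor(z))
        return mu.data * (1.0 - pi.data)

    # ----------------------------------------------------------- persistence
    def _named_params(self) -> dict[str, Tensor]:
        out = {}
        nets = {"enc": self.encoder, "dec": self.decoder, "d1": self.d1}
        if self.d2 is not None:
            nets["d2"] = self.d2
        for tag, net in nets.items():
            for i, p in enumerate(net.parameters()):
                out[f"{tag}_{i}"] = p
        return out

    def save(self, path: str) -> None:
        cfg = asdict(self.config)
        meta = {"config": cfg, "n_genes": self.n_genes, "gene_ids": self.gene_ids}
        arrays = {k: p.data for k, p in self._named_params().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "DRAModel":
        with np.load(path) as zf:
            meta = json.loads(bytes(zf["__meta__"]).decode())
            cfg = meta["config"]
            for key in ("encoder_spec", "decoder_spec", "d1_spec", "d2_spec"):
                cfg[key] = NetworkSpec(**cfg[key])
            cfg["loss_weights"] = tuple(cfg["loss_weights"])
            model = cls(TrainConfig(**cfg), meta["n_genes"], meta["gene_ids"])
            for name, p in model._named_params().items():
                p.data = zf[name].copy()
        return model


def _as_gene_matrix(x, model: DRAModel) -> np.ndarray:
    if isinstance(x, ProcessedMatrix):
        if model.gene_ids is not None:
            missing = [g for g in model.gene_ids if g not in set(x.source_gene_ids)]
            if missing:
                raise ValueError(f"input lacks genes the model was trained on: {missing[:10]}")
        arr = x.values
    else:
        arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != model.n_genes:
        raise ValueError(
            f"expected a cells × {model.n_genes} matrix, got shape {arr.shape}"
        )
    return arr


def project(model: DRAModel, x) -> np.ndarray:
    """Module-level alias for :meth:`DRAModel.project`."""
    return model.project(x)


# ------------------------------------------------------------------- losses
def _disc_loss(objective: str, real: Tensor, fake: Tensor) -> Tensor:
    if objective == "standard":
        return obj.standard_disc_loss_t(real, fake)
    if objective in ("wasserstein", "wasserstein_gp"):
        return obj.wasserstein_disc_loss_t(real, fake)
    return obj.bd_disc_loss_t(real, fake)


def _gen_loss(objective: str, fake: Tensor, real_ref: Tensor) -> Tensor:
    if objective == "standard":
        return obj.standard_gen_loss_t(fake)
    if objective in ("wasserstein", "wasserstein_gp"):
        return obj.wasserstein_gen_loss_t(fake)
    return obj.bd_gen_loss_t(fake, real_ref)


def _check_finite(loss: Tensor, step: str, epoch: int) -> None:
    if not np.all(np.isfinite(loss.data)):
        raise RuntimeError(f"non-finite loss in {step} step at epoch {epoch}")


# ----------------------------------------------------------------- training
def train_model(processed: ProcessedMatrix, counts: CountMatrix,
                config: TrainConfig) -> tuple[DRAModel, TrainHistory]:
    """Train an AVAE (dual_matching=False) or AVAE-DM on paired matrices.

    ``processed`` holds the log2(1+C) values the encoder consumes;
    ``counts`` holds the raw counts the ZINB reconstruction likelihood is
    evaluated on. Both must cover the same cells and gene panel.
    """
    X = np.asarray(processed.values, dtype=np.float64)
    C = np.asarray(counts.values)
    if X.shape != C.shape:
        raise ValueError(f"processed {X.shape} and count {C.shape} shapes differ")
    n_cells, n_genes = X.shape
    if n_cells == 0:
        raise ValueError("no cells to train on")
    if config.batch_size > n_cells:
        raise ValueError(f"batch_size {config.batch_size} exceeds n_cells {n_cells}")

    rng = np.random.default_rng(config.seed)
    model = DRAModel(config, n_genes, gene_ids=list(counts.gene_ids))
    enc_p = model.encoder.parameters()
    dec_p = model.decoder.parameters()
    d1_p = model.d1.parameters()
    ae_params = enc_p + dec_p
    # Each sub-objective is minimized in its own Adam step; because Adam
    # normalizes gradients by their running scale, static loss weights alone
    # would be ineffective — so the weights also scale the per-step
    # learning rates (recon weight on the reconstruction step, latent/data
    # weights on the generator-vs-discriminator steps).
    w_recon, w_latent, w_data = config.loss_weights
    lr = config.learning_rate
    opt_recon = Adam(ae_params, lr * w_recon)
    opt_d1 = Adam(d1_p, lr)
    opt_enc_latent = Adam(enc_p, lr * w_latent)
    if config.dual_matching:
        d2_p = model.d2.parameters()
        opt_d2 = Adam(d2_p, lr)
        opt_ae_data = Adam(ae_params, lr * w_data)
    K = config.latent_dim
    history = TrainHistory()
    best, best_epoch = np.inf, -1

    def encode_z(xb: Tensor) -> Tensor:
        out = model.encoder.encode(xb, train=True, rng=rng)
        noise = rng.standard_normal(out.mean.shape)
        return reparameterize(out, noise)

    for epoch in range(config.epochs):
        perm = rng.permutation(n_cells)
        sums: dict[str, float] = {}
        counts_b = 0
        for start in range(0, n_cells, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # per-batch variance undefined for singletons
            xb = Tensor(X[idx])
            cb = C[idx]

            # (a) reconstruction
            z = encode_z(xb)
            mu, theta, pi = model.decoder.decode(z, train=True, rng=rng)
            recon = zinb_nll_tensors(cb, mu, theta, pi) * w_recon
            _check_finite(recon, "reconstruction", epoch)
            opt_recon.step(ad.grad(recon, ae_params))

            # (b) D1: prior samples are 'real', posterior samples are 'fake'
            prior = sample_prior(len(idx), K, rng)
            z_fake = encode_z(xb).detach()
            real_s = model.d1.score(Tensor(prior), train=True, rng=rng)
            fake_s = model.d1.score(z_fake, train=True, rng=rng)
            d1_loss = _disc_loss(config.objective, real_s, fake_s)
            if config.objective == "wasserstein_gp":
                d1_loss = d1_loss + obj.gradient_penalty_t(
                    lambda xh: model.d1.score(xh), prior, z_fake.data,
                    config.gp_weight, rng)
            _check_finite(d1_loss, "D1", epoch)
            opt_d1.step(ad.grad(d1_loss, d1_p))

            # (c) encoder as generator vs D1
            g1_last = 0.0
            for _ in range(config.gen_updates_per_disc):
                z = encode_z(xb)
                fake_s = model.d1.score(z, train=True, rng=rng)
                real_ref = model.d1.score(
                    Tensor(sample_prior(len(idx), K, rng)), train=True, rng=rng
                ).detach()
                g1 = _gen_loss(config.objective, fake_s, real_ref) * w_latent
                _check_finite(g1, "encoder-vs-D1", epoch)
                opt_enc_latent.step(ad.grad(g1, enc_p))
                g1_last = g1.item()

            batch_losses = {
                "reconstruction": recon.item() / w_recon,
                "d1_loss": d1_loss.item(),
                "d1_gen_loss": g1_last / w_latent,
            }

            # (d) dual matching: D2 on real vs reconstructed expression
            if config.dual_matching:
                def recon_log_expr(sample: bool = False) -> Tensor:
                    z = encode_z(xb)
                    mu, theta, pi = model.decoder.decode(z, train=True, rng=rng)
                    if sample:
                        # stochastic reconstruction: a ZINB draw (constant —
                        # only the discriminator step may use it)
                        p_nb = theta.data / (theta.data + mu.data)
                        draws = rng.negative_binomial(theta.data, p_nb)
                        draws = np.where(rng.random(mu.shape) < pi.data, 0, draws)
                        return Tensor(np.log2(1.0 + draws))
                    expected = mu * (1.0 - pi)
                    return (expected + 1.0).log() * (1.0 / _LN2)

                x_fake = recon_log_expr(sample=config.d2_sample).detach()
                real_s = model.d2.score(xb, train=True, rng=rng)
                fake_s = model.d2.score(x_fake, train=True, rng=rng)
                d2_loss = _disc_loss(config.objective, real_s, fake_s)
                if config.objective == "wasserstein_gp":
                    d2_loss = d2_loss + obj.gradient_penalty_t(
                        lambda xh: model.d2.score(xh), X[idx], x_fake.data,
                        config.gp_weight, rng)
                _check_finite(d2_loss, "D2", epoch)
                opt_d2.step(ad.grad(d2_loss, d2_p))

                g2_last = 0.0
                for _ in range(config.gen_updates_per_disc):
                    x_hat = recon_log_expr()
                    fake_s = model.d2.score(x_hat, train=True, rng=rng)
                    real_ref = model.d2.score(xb, train=True, rng=rng).detach()
                    g2 = _gen_loss(config.objective, fake_s, real_ref) * w_data
                    _check_finite(g2, "autoencoder-vs-D2", epoch)
                    opt_ae_data.step(ad.grad(g2, ae_params))
                    g2_last = g2.item()
                batch_losses["d2_loss"] = d2_loss.item()
                batch_losses["d2_gen_loss"] = g2_last / w_data

            for k, v in batch_losses.items():
                sums[k] = sums.get(k, 0.0) + v
            counts_b += 1

        epoch_means = {k: v / counts_b for k, v in sums.items()}
        history.append(**epoch_means)
        logger.info("epoch %d: %s", epoch,
                     " ".join(f"{k}={v:.4f}" for k, v in epoch_means.items()))

        # early stopping on the reconstruction plateau
        rec = epoch_means["reconstruction"]
        if rec < best - config.early_stopping_min_delta:
            best, best_epoch = rec, epoch
        elif epoch - best_epoch >= config.early_stopping_patience:
            logger.info("early stop at epoch %d (best %.4f at %d)", epoch, best, best_epoch)
            break

    return model, history


# ------------------------------------------------------------------ presets
# Published per-dataset hyperparameters: (generator layers, discriminator
# layers, learning rate); batch size 128 throughout. Generator sizes are
# used for the encoder as listed and mirrored for the decoder; both
# discriminators share the discriminator sizes.
_PRESETS: dict[tuple[str, int], tuple[list[int], list[int], float]] = {
    ("rosenberg156k", 2): ([1024, 512, 512, 256], [32, 16, 16, 8], 7e-5),
    ("zheng73k", 2): ([512, 512, 512], [32, 32, 32], 6e-5),
    ("zheng68k", 2): ([256, 256, 256, 256], [32, 32, 16, 16], 1e-4),
    ("macosko44k", 2): ([256, 128, 64], [64, 64, 64], 1e-4),
    ("zeisel3k", 2): ([512, 512, 512, 512], [32, 32, 32, 32], 8e-4),
    ("rosenberg156k", 10): ([512, 256, 128, 64], [256, 128, 64, 32], 6e-5),
    ("zheng73k", 10): ([1024, 512, 512, 256], [32, 32, 32, 32], 2e-5),
    ("zheng68k", 10): ([256, 256, 256, 256], [32, 32, 16, 16], 7e-5),
    ("macosko44k", 10): ([512, 256, 256, 128], [256, 128, 128, 64], 7e-5),
    ("zeisel3k", 10): ([512], [512], 7e-4),
    ("rosenberg156k", 20): ([1024, 1024, 1024, 1024], [64, 64, 64, 64], 6e-5),
    ("zheng73k", 20): ([1024, 512, 512, 256], [64, 32, 32, 16], 1e-5),
    ("zheng68k", 20): ([256], [256], 2e-5),
    ("macosko44k", 20): ([256], [256], 7e-5),
    ("zeisel3k", 20): ([512], [512], 7e-4),
}


def _canon_tag(tag: str) -> str:
    return "".join(ch for ch in tag.lower() if ch.isalnum())


def preset_config(dataset_tag: str, K: int, **overrides) -> TrainConfig:
    """The published hyperparameter preset for (dataset, latent dim).

    Tags: zeisel3k, macosko44k, zheng68k, zheng73k, rosenberg156k (case and
    punctuation insensitive). Raises on unknown combinations.
    """
    key = (_canon_tag(dataset_tag), int(K))
    if key not in _PRESETS:
        raise ValueError(
            f"no preset for dataset {dataset_tag!r} at K={K}; available: "
            f"{sorted(set(k for k, _ in _PRESETS))} × {sorted(set(k for _, k in _PRESETS))}"
        )
    g_layers, d_layers, lr = _PRESETS[key]
    cfg = dict(
        latent_dim=int(K),
        objective="bhattacharyya",
        encoder_spec=NetworkSpec(list(g_layers)),
        decoder_spec=NetworkSpec(list(reversed(g_layers))),
        d1_spec=NetworkSpec(list(d_layers)),
        d2_spec=NetworkSpec(list(d_layers)),
        batch_size=128,
        learning_rate=lr,
        dual_matching=True,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


def demo_config(seed: int = 0, **overrides) -> TrainConfig:
    """Training configuration for the package's reference simulation.

    Sized for the 300-cell × 120-gene three-cluster fixture: a compact
    encoder/decoder, small discriminators and the Bhattacharyya objective.
    """
    cfg = dict(
        latent_dim=2,
        objective="bhattacharyya",
        encoder_spec=NetworkSpec([128, 64]),
        decoder_spec=NetworkSpec([64, 128]),
        d1_spec=NetworkSpec([32, 32]),
        d2_spec=NetworkSpec([32, 32]),
        batch_size=128,
        learning_rate=1e-3,
        epochs=300,
        early_stopping_patience=300,
        loss_weights=(1.0, 0.2, 0.2),
        seed=seed,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)
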