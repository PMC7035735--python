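# Methods

## Model

Let C be an M × N matrix of raw transcript counts (cells × rows, genes ×
columns). Preprocessing keeps the G genes of largest across-cell count
variance (default G = 720, or all genes if fewer) and feeds the encoder
x = log2(1 + C). The generative model is

    z ~ N(0, I_K),      x_count | z ~ ZINB(μ(z), θ(z), π(z)),

with the ZINB pmf in the mean–dispersion convention:
NB(x; μ, θ) has log-mass ln Γ(x+θ) − ln Γ(θ) − ln Γ(x+1) + θ ln(θ/(θ+μ)) +
x ln(μ/(θ+μ)) and variance μ + μ²/θ; the zero-inflated form places
probability π on an exact zero, so P(0) = π + (1−π)(θ/(θ+μ))^θ. The
decoder emits all three parameters per cell per gene (rather than a single
gene-wise θ) through stabilized links: exponential clamped to [1e-8, 1e8]
for μ and θ, sigmoid clamped to the open unit interval for π. The encoder
is a variational Gaussian with diagonal covariance; embeddings used
downstream are the posterior means (no sampling, dropout off), so
projection is deterministic.

Inference replaces the VAE's KL regularizer with adversarial matching:

* **D1** scores K-vectors and is trained to separate prior draws
  z ~ N(0, I) ("real") from reparameterized posterior samples
  z = μ(x) + σ(x)⊙ε ("fake"); the encoder doubles as the generator that
  tries to defeat it. This drives the aggregate posterior q(z) toward the
  prior.
* **D2** (dual matching) scores G-vectors in log-expression space and is
  trained to separate real profiles log2(1+x) from reconstructions
  log2(1 + μ(1−π)) — the expected count under the fitted ZINB, which keeps
  the path differentiable; a stochastic ZINB draw can be fed to D2 instead
  (`d2_sample=True`), in which case only the discriminator sees the draw.
  Encoder and decoder jointly play the generator against D2.

## Adversarial objectives

All four objectives consume a batch of real scores and a batch of fake
scores:

| token | discriminator loss | generator loss | score head |
|---|---|---|---|
| `standard` | −E ln D(real) − E ln(1−D(fake)) | −E ln D(fake) (non-saturating) | sigmoid |
| `wasserstein` | −(E D(real) − E D(fake)) | −E D(fake) | linear |
| `wasserstein_gp` | above + λ E(‖∇x̂ D(x̂)‖−1)², λ=10 | −E D(fake) | linear |
| `bhattacharyya` | −BD(real scores, fake scores) | +BD(fake vs frozen real moments) | sigmoid |

The Bhattacharyya objective needs distributions, not scalars, so each score
batch is summarized as a Gaussian by moment matching (sample mean,
population variance floored at 1e-6) and the closed form
BD = ¼(m₁−m₂)²/(v₁+v₂) + ½ ln[(v₁+v₂)/(2√(v₁v₂))] is used; it is exact for
Gaussians and differentiable in both batches. The generator's copy freezes
the real-score moments so only the fake-score distribution moves. The
gradient penalty differentiates the critic's input gradients (double
backprop) on uniform interpolates between real and fake batches; plain
`wasserstein` enforces no Lipschitz constraint (no weight clipping) — a
known limitation, use `wasserstein_gp` when that matters. Sigmoid scores
are clamped to [1e-7, 1−1e-7] inside the cross-entropy losses because a
confident discriminator otherwise saturates to exact 0/1 in float64.

## Training schedule

Per minibatch (cells shuffled each epoch, trailing batches of fewer than
two cells dropped because the score-batch variance is undefined):

1. reconstruction step — ZINB NLL, updates encoder + decoder;
2. D1 step;
3. encoder-vs-D1 step, run `gen_updates_per_disc` (default 2) times —
   the two-to-one generator/discriminator update ratio;
4. with dual matching: D2 step, then encoder+decoder-vs-D2 at the same
   ratio.

Every step uses its own Adam optimizer (β₁=0.9, β₂=0.999). Because Adam
normalizes gradients by their running magnitude, multiplying a loss by a
constant does not change the step size; the `loss_weights`
(reconstruction, latent, data) are therefore implemented as per-step
learning-rate multipliers, which is the scale that actually matters under
this schedule. Defaults are (1, 1, 1); the synthetic-fixture preset uses
(1, 0.2, 0.2) — chosen, like the rest of its hyperparameters, by a small
grid search scored on held-out clustering, the same selection protocol the
published per-dataset presets came from.

All randomness (shuffling, reparameterization noise, dropout masks, prior
draws, interpolation ε) flows from one generator seeded by `config.seed`,
so a (data, config, seed) triple reproduces the training history and
embeddings bit-for-bit on the same platform. Any non-finite loss aborts
with the offending step named. Early stopping watches the epoch-mean
reconstruction NLL (patience 30 epochs, min improvement 1e-3 by default).

Networks are 1–4 fully connected LeakyReLU layers (negative slope 0.2)
with widths from {8, …, 1024} and dropout (rate 0.1) on hidden units of
all networks, discriminators included. The encoder's log-variance head
bias starts at −4: with a unit-variance posterior at initialization the
z-samples of distinct cell populations overlap heavily and the decoder can
settle on a merged representation; starting tight (σ ≈ 0.14) keeps early
codes separable and markedly stabilizes cluster recovery, while the
variance remains free to grow. Published per-dataset presets (batch 128,
generator/discriminator widths and learning rate per dataset and K) are
available via `preset_config(tag, K)`; the generator widths are used as
listed for the encoder and mirrored for the decoder, and both
discriminators share the discriminator widths.

## Synthetic data

`synthetic.generate_zinb_counts` inverts the model's own data assumption:
cells draw a cluster from given proportions, counts draw from
ZINB(μ_{cluster,gene}, θ, π). The reference fixture
(`three_cluster_spec()`) has 300 cells, 120 genes, three equally likely
clusters with 40 marker genes each (mean 10 vs baseline 0.5), shared
θ = 2 and dropout π = 0.3 — strong, block-structured signal of the kind
cell types produce. What it deliberately lacks: library-size variation,
batch effects, per-gene dispersion trends, continuous/trajectory
structure, and realistic numbers of genes. Passing the recovery tests
therefore shows the pipeline is implemented correctly and can extract
planted structure through ZINB noise and 30 % dropout; it does not certify
performance on real tissue atlases, where preprocessing choices and scale
dominate.

## Evaluation and visualization

K-means (k-means++ initialization, 10 restarts, seeded) clusters the
embedding with k equal to the number of ground-truth classes; agreement is
NMI computed from the joint contingency table in natural log (the ratio is
base-invariant; the implementation is cross-checked against scikit-learn's
geometric-mean NMI in the tests). A labeling with a single class gets NMI
0 with a warning. Baselines PCA, t-SNE (perplexity 30, capped below the
sample count) and UMAP run through scikit-learn/umap-learn; t-SNE is
reported not-applicable above three output dimensions, which its
Barnes–Hut implementation cannot produce. Evaluation defaults to the
held-out 20 % of cells (splits are seeded, |train| = round-half-up of
0.8·M). Visualization offers the direct K=2 scatter and the two-step
route — project with a K=10 model, then t-SNE to 2-D — plus a filter to
the n most abundant cell types (frequency ties broken lexicographically).

## Numerical and design notes

* Gene selection ranks genes by population variance (ddof 0) of **raw**
  counts, ties broken toward the lower original index; ranking on
  log-transformed counts is a reasonable alternative and the choice is
  deliberately isolated in `select_top_variance_genes`.
* Inside the reconstruction loss μ and θ are floored at 1e-8 and π kept in
  [1e-8, 1−1e-8]; the pure pmf functions are exact and unfloored.
* The training-path NLL (autodiff graph) and the exact numpy NLL are two
  independent code paths kept consistent by a dedicated test.
* Checkpoints are single `.npz` files containing all weights plus the
  JSON-encoded configuration and gene panel, so a saved model validates
  its inputs on reload.
* Training cost is dominated by the per-batch step count (≈ 8 network
  passes with dual matching); the reference fixture trains in roughly
  15–20 s per 300-epoch run on one CPU.

## Known limitations

Plain Wasserstein mode has no Lipschitz control; `d2_sample` draws reach
only the discriminator; the BD objective's Gaussian moment matching is a
two-moment summary of the score distributions (multimodal score batches
are summarized coarsely); and bit-identical reproducibility is guaranteed
only within one numpy/BLAS build.
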