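# dra — adversarial variational autoencoder with dual matching for scRNA-seq

`dra` reduces single-cell RNA-seq count matrices (cells × genes) to a
low-dimensional latent space with **DR-A**, an *Adversarial Variational
AutoEncoder with Dual Matching* (AVAE-DM). It is aimed at anyone who needs a
compact, cluster-preserving embedding of scRNA-seq data for cell-type
discovery and visualization, and at methodologists who want a small,
dependency-light reference implementation of the model with exact
likelihoods and a fully reproducible training loop (the networks and
optimizer run on a built-in numpy reverse-mode autodiff engine — no deep
learning framework required).

## The model

A variational encoder maps the log-transformed expression profile
x ∈ ℝ^G of each cell to a Gaussian posterior q(z|x) = N(μ(x), diag σ²(x))
over a K-dimensional latent code. A decoder maps z back to the parameters
(μ, θ, π) of a **zero-inflated negative binomial** (ZINB) distribution over
the raw counts — a point mass at zero with probability π (technical
dropout) mixed with NB(μ, θ), variance μ + μ²/θ — and the reconstruction
loss is the exact ZINB negative log-likelihood.

Instead of a KL term, two adversarial games regularize the model:

* **D1 (latent space)** discriminates N(0, I) prior draws from posterior
  samples, pushing the aggregate posterior q(z) onto the prior;
* **D2 (data space, the "dual matching")** discriminates real expression
  profiles from reconstructions, pushing the decoder's output distribution
  onto the data distribution.

Four interchangeable adversarial objectives are provided: the standard
cross-entropy GAN, Wasserstein, Wasserstein with gradient penalty, and the
**Bhattacharyya-distance objective** that defines DR-A: with
BD(p, q) = −ln Σ√(p·q), the discriminator maximizes — and the generator
minimizes — the BD between the distributions of real-sample and
fake-sample discriminator scores (estimated by Gaussian moment matching of
each score batch):

    min_G max_D  BD( D(real scores), D(fake scores) )

Embeddings are the posterior means; quality is scored by K-means clustering
(k = number of cell types) and normalized mutual information
NMI = MI(X;Y)/√(H(X)H(Y)) against ground-truth labels.

## Worked example

Everything below runs offline on simulated data — a 300-cell × 120-gene
ZINB count matrix with three planted cell types (40 marker genes each,
dropout probability 0.3):

```bash
dra simulate   --cells 300 --genes 120 --clusters 3 --seed 0 --out-dir demo
dra preprocess --counts demo/counts.csv --n-genes 120 --seed 0 --out-dir demo
dra train      --counts demo/counts_selected.csv --split demo/split.json \
               --K 2 --objective bhattacharyya --epochs 300 --seed 0 --out-dir demo
dra embed      --model demo/model.npz --counts demo/counts_selected.csv \
               --split demo/split.json --subset test --labels demo/labels.csv --out-dir demo
dra evaluate   --embedding demo/embedding.csv --out-dir demo
dra benchmark  --counts demo/counts_selected.csv --labels demo/labels.csv \
               --split demo/split.json --methods pca,tsne,umap --K 2 --out-dir demo
```

which prints:

```
wrote 300×120 counts to demo
selected 120 genes; split 240/60
trained 300 epochs; final reconstruction NLL 193.094
wrote 60 × 2 embedding to demo/embedding.csv
NMI = 0.7786 (k = 3)
method  K  seed  nmi note
   pca  2     0  1.0
  tsne  2     0  1.0
  umap  2     0  1.0
```

The model is trained on the 240 training cells and the 60 held-out cells
are projected into the 2-D latent space; K-means with k = 3 on that
embedding recovers the planted cell types with NMI 0.78 (1.0 is perfect
agreement; a random embedding scores ≈ 0.03). `dra visualize
--embedding demo/embedding.csv --out-dir demo` draws the labeled 2-D
scatter plot. On real data, use `dra preprocess` with the default
`--n-genes 720` and, for large panels, the published per-dataset presets
(`dra train --preset zeisel3k --K 2`).

The same workflow is available as a library (`dra.synthetic`, `dra.io`,
`dra.train`, `dra.evaluate`, `dra.viz`); see `docs/methods.md` for the
model details and design choices.

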