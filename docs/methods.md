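# Methods

## The model

A cell is encoded as a sequence of gene tokens. Each position carries a
gene-identity embedding `emb_g(t_g)` plus an expression embedding: for
binned inputs, a learned embedding of the discrete value token; for rank
inputs, an embedding of the (capped) rank position; for continuous inputs,
a learned linear lift `v ↦ v·w + b` of the log1p-normalized value (the
mechanism for embedding un-binned values is unspecified in the protocols
this package follows, so the simplest learnable lift is used). The
perturbation task adds a binary condition embedding `emb_c(t_c)` at every
position. No positional encodings are used — a cell is a set of
(gene, value) pairs, and the encoder is permutation-equivariant over gene
positions (a property the test suite checks directly).

Each of the `n` Transformer blocks applies multi-head self-attention, a
residual connection, LayerNorm, a ReLU MLP, a second residual and a second
LayerNorm, **in that post-norm order** — fidelity to the written recurrence
was preferred over the more common pre-norm variant. Attention logits are
scaled by `1/sqrt(d)` with `d` the embedding dimension, again following the
written form rather than the per-head convention; the two differ only by a
constant factor absorbable into `W_Q`. The cls token, when used, sits at
the last sequence position; its final-block output is the cell embedding
`h_c`. With mean pooling, gene positions (excluding padding, prefix and
cls) are averaged instead.

Self-supervised objectives mask a fraction of the *non-zero* gene positions
per cell (`floor(mask_ratio · n_nonzero)` drawn uniformly without
replacement). GEP reconstructs the masked value from the position's
final-block embedding through a 2-layer MLP projector — cross-entropy over
value tokens for binned inputs, MSE on log1p values for continuous inputs.
GEPC forms a query `q_j = MLP(emb_g(t_g_j))` per masked gene and predicts
its value as the bilinear form `q_j · (W h_c)`, scored by MSE. Both
objectives double as the pretraining routine (`fit_unsupervised` with
`train_backbone=True`) that produces the "native" backbone used in the
zero-shot and forgetting studies.

Weight matrices are Xavier-initialized and embedding tables unit-scaled.
This matters at miniature scale: with the small-constant initialization
common in large pretrained models, the attention output is negligible
against the residual stream and cls embeddings are nearly constant across
cells, so an untrained backbone carries no usable signal.

## Adapters

All four adapters attach to a frozen backbone; only adapter + task-head
parameters are trainable, and a SHA-256 checksum over the frozen parameter
bytes verifies the freeze contract before and after every run.

* **Token adapter** (bottleneck `s`, default 8): the value-embedding path
  becomes `e + up(ReLU(down(e)))`. The literal compress-restore form
  without a residual cannot reproduce the native model at initialization,
  so the residual form with a zero-initialized up-projection is used — the
  same start-at-native rationale LoRA states for `ΔW = 0`. The non-residual
  behavior remains reachable by disabling `zero_init`.
* **Prefix adapter** (`k` tokens, default 8, Gaussian σ=0.02 init): one set
  of learnable d-dimensional tokens is prepended before block 1 and carried
  through all blocks (not re-inserted per layer). Prefix positions are
  excluded from reconstruction targets, pooling means and attention
  profiles. With cls at the end, the layout is `[p, genes…, cls]`; since
  the encoder is permutation-equivariant this differs from any other
  ordering only in bookkeeping.
* **LoRA** (rank `r`, default 8): `Q̃ = W_Q h + BAh`, `Ṽ = W_V h + BAh`,
  Key untouched; separate `(A, B)` per block and per target; `A` Gaussian,
  `B` zero, no `α/r` scaling factor.
* **Encoder adapter**: the post-attention LayerNorm output becomes
  `a + up(ReLU(down(a)))` in each target block (same residual/zero-init
  reasoning as the token adapter).

`freeze_and_count` performs exact parameter accounting. On stand-ins of
the three published backbone shapes (6 blocks/10 heads, 12/12, 12/8) at
`d=512` with a 60k-gene vocabulary, every default adapter plus a linear
head trains under 0.4% of the model. Stand-ins with 10 or 12 heads at
`d=512` violate head-divisibility; since the projection tables are `d×d`
regardless of head count, construction and counting are permitted for any
head count and divisibility is enforced only when a forward pass runs.

## Tasks

All tasks share one protocol: Adam, multiplicative lr decay per epoch
(default 0.9), early stopping after `patience` (default 5) epochs without
validation improvement, max 100 epochs, validation on the cells of one
randomly chosen held-out donor. The protocol's default `initial_lr = 1e-5`
mirrors published practice for full-scale pretrained backbones; the
miniature from-scratch models in the tests and examples use `1e-3`–`1e-2`
with decay 0.97–0.98, chosen once as scale-appropriate (at `1e-5` a
miniature model barely moves within the epoch budget). The best-validation
parameter state is restored at the end of training. For deliberately
biased single-donor subsets (the forgetting study) a 10% random cell
holdout replaces the impossible donor holdout.

Batch correction concatenates a learned per-batch embedding (width 8) onto
the final-block embeddings before widened GEP/GEPC heads; the elastic
cell-similarity loss `−(cos(h_c_i, h_c_j) − β)` (β default 0.6) averages
over same-batch pairs within a minibatch, and a 2-layer batch classifier
trains through a gradient-reversal layer (λ default 1.0, constant — no
schedule). As written, the ECS term rewards same-batch similarity, which is
in tension with batch mixing; it is implemented as written with a toggle.
At miniature scale the adversarial term cannot reliably strip batch signal
from the embedding as judged by an external linear probe — the reversal
gradient reaches the encoder only through a small adapter while the
reconstruction terms dominate — so the tests verify the mechanism
(reversal sign and scale, loss composition, freeze contract, training
convergence) rather than probe-level batch erasure.

Perturbation prediction follows the paired-cell scheme: the input is a
control cell's log1p profile plus condition tokens, the target the profile
of a randomly paired perturbed cell of the same type, the loss MSE over
*all* genes (zeros included), with a per-gene scalar head on the final
gene embeddings.

## Interpretation

Attention profiles average the post-softmax attention maps over heads,
take the cls row, drop cls/prefix columns and renormalize the row to sum
to 1 — the renormalization makes profiles comparable across models with
different prefix lengths ("normalized" being otherwise unspecified). Any
subset of layers can be requested; the default is the last block.
Differential attention between two cell groups uses per-cell attention
values as the test samples (the sampling unit being otherwise unstated):
per-gene delta of group means, two-sided Wilcoxon rank-sum, BY correction
across genes, ranking by |delta| with gene-index tie-breaks.

Zero-shot annotation embeds reference and query cells with the native
model and transfers labels by majority vote over the k=10 Euclidean
nearest references; vote ties break by smaller mean neighbor distance,
then lexicographic label order. Leiden clustering runs on a UMAP-weighted
cosine kNN graph (15 neighbors) — unweighted kNN graphs over-split even
perfectly separated blobs at standard resolutions. For the NMI/ARI
components of the integration score the clustering follows the scIB
convention: a deterministic resolution sweep keeping the clustering that
maximizes NMI against the cell-type labels (a fixed resolution of 1.0
over-clusters desk-scale embeddings and misstates ARI even for perfect
embeddings). ASW_batch is the scIB form `1 − |silhouette|` on batch labels
averaged within cell-type strata; graph connectivity is the per-type
largest-connected-component fraction of the 15-NN graph. ARI is clipped at
0 so all components live in [0, 1].

## Synthetic data

The generator draws negative-binomial counts (Gamma–Poisson, variance
`μ + μ²/θ`, θ default 2 — moderate overdispersion typical of UMI data)
around log-normal baseline gene means. Each cell type elevates a disjoint
block of `program_size` genes by `exp(program_log_fold)` (default e¹);
batches multiply every gene mean by a log-normal factor (scale 0.3);
library sizes are log-normal around 2,500 counts. Donors and batches are
assigned round-robin *within* cell type so donor holdouts stay stratified.
Condition shifts resample chosen genes in chosen cell types from the
negative binomial with latent means scaled by `exp(log_fold)`, leaving all
other entries bit-identical. Perturbed cells add a per-gene effect vector
plus Gaussian noise (σ default 0.1) to log1p profiles, randomly paired
within cell type.

What this emulates — and what it does not: counts are overdispersed,
library sizes vary, types/donors/batches/conditions have realistic label
structure, and ground truth (programs, shifted genes, planted effects) is
known exactly. It does **not** model ambient RNA, doublets, dropout beyond
NB sampling, gene–gene correlation within programs, or realistic pathway
structure. Passing tests therefore demonstrate that the machinery works and
recovers planted structure under the stated noise model, not that any
particular accuracy will transfer to real tissue data.

## Study designs used by the test suite

Problem sizes were chosen so the full suite runs in minutes on one CPU:
backbones of 2–3 blocks at `d = 16–64`, datasets of 300–600 cells × 60–100
genes. The heavier studies:

* **Forgetting** (3 seeds): train a source model by full fine-tuning on
  five donors, adapt to a biased subset (one donor, two of four types)
  either by continued full fine-tuning or by LoRA with the backbone
  frozen, and compare held-out-donor balanced-accuracy drops. The claim is
  directional and is asserted on the mean over the three seeds.
* **Adaptation vs zero-shot** (3 seeds): pretrain the backbone
  self-supervised on unshifted data; shift 50 genes by log-fold 1.5 in two
  of four cell types; compare supervised LoRA tuning on the shifted
  reference against kNN transfer in the native embedding on shifted query
  donors.
* **Perturbation recovery** (seeded): 20 planted log1p effects of
  magnitude 1–2 with noise σ=0.1; the tuned predictor must place ≥15
  planted genes in its top-20 predicted changes with DE_PCC ≥ 0.9.

## Numerical choices and degenerate inputs

Float64 throughout the autodiff engine (exact identity-at-init and stable
LayerNorm gradients at tiny `d`). Bin edges are per-cell quantiles of the
cell's non-zero values; ties share a bin; zeros map to token 0. Rank
encoding breaks ties by ascending gene index. All-zero cells tokenize to
all-zero tokens and are simply never masked; empty mask sets raise.
Duplicate gene names on load are suffix-deduplicated with a warning.
Attention over padded positions is excluded by additive −1e9 logits.

## Known limitations

The backbone is randomly initialized or briefly pretrained on synthetic
data, not a published pretrained checkpoint, so absolute task accuracies
are far below published full-scale numbers and only the *relative* claims
(efficiency, freeze contract, adapter-vs-full-tuning, adaptation-vs-zero-
shot) are meaningful here. Single-gene perturbations only; one adapter at
a time; no GPU path; the ortholog table must be one-to-one.
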