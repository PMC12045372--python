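# scadapt

Parameter-efficient adapter tuning for single-cell Transformer models, as a
self-contained, desk-scale library.

Single-cell "large language models" (scLLMs) treat a cell as a sequence of
(gene, expression) tokens and learn gene and cell embeddings with a
Transformer encoder. They work well in familiar cellular contexts but
degrade out of context — unseen diseases, other species, under-characterized
populations — and full fine-tuning both costs compute and overwrites
pretrained knowledge (catastrophic forgetting). `scadapt` implements the
alternative: keep the backbone **frozen** and train only a small, pluggable
**adapter** plus a task head.

The package bundles everything needed to study this end to end without any
external download:

* a miniature, configurable scLLM backbone — gene-identity / value-bin /
  rank / continuous-value tokenization, `n` stacked post-norm Transformer
  blocks `h_{l+1} = LayerNorm(MLP(a_l) + a_l)` with
  `a_l = LayerNorm(Att(h_l) + h_l)`, cls or mean pooling, and the two
  masked-expression objectives (GEP: reconstruct masked values from gene
  context; GEPC: predict them from the cell token via a bilinear query
  `q_j · W h_c`);
* four adapters: **token** (bottleneck autoencoder on the value embedding),
  **prefix** (`k` learnable tokens prepended to the sequence), **LoRA**
  (low-rank `ΔW = BA` on Query and Value, `B = 0` at init), and **encoder**
  (bottleneck inside each block after attention) — all with exact parameter
  accounting, identity-at-initialization and bit-exact detachability;
* four task protocols: supervised cell-type annotation
  (`cross-entropy(MLP(h_c), z)`), self-supervised reconstruction, batch
  correction (GEP + GEPC on batch-aware embeddings + an elastic
  cell-similarity margin loss + a domain-adversarial batch classifier
  trained through gradient reversal), and single-gene perturbation
  prediction (`MSE(MLP(h_g), z')` over all genes with a binary condition
  token);
* attention-based gene–cell-state association: head-averaged cls-row
  attention profiles, per-gene differential attention with Wilcoxon
  rank-sum tests and Benjamini–Yekutieli correction, `.rnk` export;
* zero-shot kNN label transfer, ortholog mapping for cross-species work,
  Leiden clustering, and the evaluation metric suite (balanced accuracy,
  confusion matrices, CHI, AvgBIO = (ARI+NMI+ASW_cell)/3,
  AvgBATCH = (ASW_batch+GraphConn)/2, perturbation PCC/MSE with top-20
  differentially-expressed-gene variants);
* a synthetic-data generator (negative-binomial counts with cell-type gene
  programs, donor/batch structure, condition shifts, paired perturbations)
  so every claim is testable on data with known ground truth.

Because no deep-learning framework is assumed, the package ships its own
compact reverse-mode autodiff engine on numpy (`scadapt.autodiff`),
validated against finite differences; the models are deliberately
miniature and run on a single CPU.

## Worked example

Adapter-tune a cell-type classifier on synthetic data and evaluate on a
held-out donor:

```python
import numpy as np
import scadapt as sa

spec = sa.SyntheticSpec(n_cells=600, n_genes=100, n_cell_types=4, n_donors=6, seed=0)
data = sa.simulate_profiles(spec)
vocab = sa.GeneVocabulary.from_genes(list(data.gene_names))
reference = data.subset_cells(np.where(data.donor != "donor5")[0])
query = data.subset_cells(np.where(data.donor == "donor5")[0])

model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=3, d_model=64,
                                             n_heads=4, m_bins=10, seed=0))
model = sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=8))

proto = sa.TrainProtocol(initial_lr=5e-3, lr_decay=0.98, max_epochs=40,
                         patience=10, batch_size=64, seed=0)
fitted = sa.fit_annotation(model, reference, proto, vocab)
pred, prob = sa.predict_annotation(fitted, query)

rep = sa.freeze_and_count(model, [fitted.head])
print("epochs trained:", len(fitted.history))
print("balanced accuracy on the held-out donor:",
      round(sa.balanced_accuracy(query.cell_type.astype(str), pred), 3))
print("trainable parameters: {:,} of {:,} ({:.2f}%)".format(
    rep["trainable_params"], rep["total_params"], 100 * rep["fraction"]))
```

prints

```
epochs trained: 34
balanced accuracy on the held-out donor: 0.79
trainable parameters: 10,564 of 115,408 (9.15%)
```

Training stopped early (34 of 40 epochs) once the held-out-donor validation
loss stalled for 10 epochs. The classifier reaches 0.79 balanced accuracy
(mean per-class recall over the four cell types) on a donor it never saw,
while updating 9% of this miniature model's parameters — the frozen-backbone
checksum is unchanged by training. On full-scale backbone shapes the
trainable share drops below 0.4% (see below). A command-line interface
(`scadapt simulate|annotate|adapt-unsup|batchcorrect|perturb|attention|zero-shot|crossval|count-params`)
wraps the same functions and writes config snapshots, logs, histories and
metric reports per run.

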