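"""Adaptation protocols: supervised annotation, self-supervised
reconstruction, batch correction, and perturbation prediction.

All four tasks share one optimization protocol: Adam with a multiplicative
per-epoch learning-rate decay, a validation split holding out the cells of
one randomly chosen donor, and early stopping after ``patience`` epochs
without validation improvement.  When an adapter is attached the backbone
stays frozen and only adapter + task-head parameters receive updates; the
``train_backbone`` flag switches to full fine-tuning for comparison
studies.

Batch correction combines four objectives: the two masked-reconstruction
losses computed on batch-aware representations (the final-block embeddings
concatenated with a learned batch embedding), an elastic cell-similarity
margin loss over same-batch pairs, and a domain-adversarial batch
classifier trained through a gradient-reversal layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .backbone import (
    CellTransformer,
    EncodeOutput,
    MLPHead,
    cross_entropy,
    gep_loss,
    gepc_loss,
    sample_mask,
)
from .syndata import LabeledMatrix, PerturbationPairs, _log1p_normalize
from .tokenizer import GeneVocabulary, TokenizedBatch, assemble_tokens, tokenize_perturbation

__all__ = [
    "TrainProtocol",
    "BatchLossWeights",
    "Adam",
    "FittedAnnotator",
    "FittedPerturbationModel",
    "fit_annotation",
    "predict_annotation",
    "fit_unsupervised",
    "fit_batch_correction",
    "fit_perturbation",
    "predict_perturbation",
]


@dataclass(frozen=True)
class TrainProtocol:
    """Shared optimization settings.

    ``initial_lr=1e-5`` mirrors the published protocol for full-scale
    pretrained backbones; miniature from-scratch backbones train with a
    larger rate (pass e.g. ``initial_lr=1e-3``).
    """

    initial_lr: float = 1e-5
    lr_decay: float = 0.9
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass(frozen=True)
class BatchLossWeights:
    """Component toggles and constants of the batch-correction objective."""

    margin_beta: float = 0.6
    dar_lambda: float = 1.0
    use_gep: bool = True
    use_gepc: bool = True
    use_ecs: bool = True
    use_dar: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 <= self.margin_beta <= 1.0):
            raise ValueError("margin_beta must lie in [-1, 1]")
        if self.dar_lambda <= 0:
            raise ValueError("dar_lambda must be positive")


class Adam:
    """Adam over a named set of tensors (only these are ever updated)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _donor_holdout(donors: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Train/validation row split holding out every cell of one random donor."""
    uniq = np.unique(donors.astype(str))
    if uniq.size < 2:
        raise ValueError("cannot form validation holdout: data contains a single donor")
    rng = np.random.default_rng(seed)
    held = rng.choice(uniq)
    val = np.where(donors.astype(str) == held)[0]
    train = np.where(donors.astype(str) != held)[0]
    return train, val


def _set_requires_grad(model: CellTransformer, heads: Sequence[MLPHead | dict]) -> dict[str, Tensor]:
    """Mark the trainable tensor set (and flip requires_grad flags to match)."""
    for name, t in model.params.items():
        t.requires_grad = model.trainable[name]
    trainables = dict(model.trainable_tensors())
    for i, head in enumerate(heads):
        items = head.params.items() if isinstance(head, MLPHead) else head.items()
        for name, t in items:
            t.requires_grad = True
            trainables[f"head{i}.{name}"] = t
    return trainables


def _run_training(
    loss_fn: Callable[[np.ndarray, int], Tensor],
    val_fn: Callable[[], float],
    trainables: dict[str, Tensor],
    n_train: int,
    protocol: TrainProtocol,
) -> list[dict]:
    """Generic minibatch loop with lr decay and patience-based early stopping."""
    rng = np.random.default_rng(protocol.seed)
    opt = Adam(trainables, lr=protocol.initial_lr)
    history: list[dict] = []
    best_val = np.inf
    best_state = {k: t.data.copy() for k, t in trainables.items()}
    stale = 0
    for epoch in range(protocol.max_epochs):
        opt.lr = protocol.initial_lr * protocol.lr_decay**epoch
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, protocol.batch_size):
            idx = order[start : start + protocol.batch_size]
            if idx.size < 2:
                continue
            opt.zero_grad()
            loss = loss_fn(idx, epoch)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val = val_fn()
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val, "lr": opt.lr})
        if val < best_val - 1e-12:
            best_val = val
            best_state = {k: t.data.copy() for k, t in trainables.items()}
            stale = 0
        else:
            stale += 1
            if stale >= protocol.patience:
                break
    for k, t in trainables.items():
        t.data[...] = best_state[k]
    return history


# ---------------------------------------------------------------- annotation
@dataclass
class FittedAnnotator:
    """A trained annotation model: backbone (+adapter), head, and feature space."""

    model: CellTransformer
    head: MLPHead
    classes: np.ndarray
    feature_genes: np.ndarray
    vocab: GeneVocabulary
    mode: str
    history: list = field(default_factory=list)

    def tokenize(self, data: LabeledMatrix) -> TokenizedBatch:
        return _tokenize_fixed(data, self.feature_genes, self.vocab, self.mode, self.model.config.m_bins)


def _tokenize_fixed(
    data: LabeledMatrix, feature_genes: np.ndarray, vocab: GeneVocabulary, mode: str, m: int
) -> TokenizedBatch:
    """Tokenize against a frozen feature gene list (training-time gene space)."""
    pos = {g: j for j, g in enumerate(data.gene_names)}
    missing = [g for g in feature_genes if g not in pos]
    if missing:
        raise ValueError(f"gene-space mismatch: query is missing {len(missing)} training genes, e.g. {missing[:5]}")
    sub = data.subset_genes(np.array([pos[g] for g in feature_genes]))
    return assemble_tokens(sub, vocab, mode=mode, task="annotation", m=m, with_cls=True, n_hvg=None)


def fit_annotation(
    model: CellTransformer,
    reference: LabeledMatrix,
    protocol: TrainProtocol,
    vocab: GeneVocabulary,
    mode: str = "binned",
    n_hvg: int | None = None,
    train_backbone: bool = False,
    head_seed: int = 0,
    val_split: str = "donor",
    head: MLPHead | None = None,
    classes: np.ndarray | None = None,
) -> FittedAnnotator:
    """Train a cell-type classifier head (cross-entropy on the pooled cell
    embedding) with the shared protocol; the backbone trains only when
    ``train_backbone`` (full fine-tuning comparison mode).

    ``val_split='donor'`` holds out one random donor (the default;
    single-donor data is an error); ``'random'`` holds out 10% of cells
    instead, for deliberately biased single-donor subsets.  Passing an
    existing ``head`` (with matching class count) continues training it.
    """
    if classes is None:
        classes = np.unique(reference.cell_type.astype(str))
    classes = np.asarray(classes)
    if classes.size < 2:
        raise ValueError("fit_annotation requires at least two cell types")
    if not set(reference.cell_type.astype(str)) <= set(classes):
        raise ValueError("reference contains cell types outside the given class list")
    if val_split == "donor":
        train_rows, val_rows = _donor_holdout(reference.donor, protocol.seed)
    elif val_split == "random":
        rng = np.random.default_rng(protocol.seed)
        order = rng.permutation(reference.n_cells)
        n_val = max(1, reference.n_cells // 10)
        val_rows, train_rows = order[:n_val], order[n_val:]
    else:
        raise ValueError("val_split must be 'donor' or 'random'")

    batch = assemble_tokens(reference, vocab, mode=mode, task="annotation", m=model.config.m_bins, with_cls=True, n_hvg=n_hvg)
    y = np.searchsorted(classes, reference.cell_type.astype(str))
    if head is None:
        head = MLPHead(model.config.d_model, classes.size, seed=head_seed)

    model.set_backbone_trainable(train_backbone)
    trainables = _set_requires_grad(model, [head])

    def loss_on(rows: np.ndarray) -> Tensor:
        out = model.forward(batch.subset_cells(rows))
        return cross_entropy(head(out.cell), y[rows])

    def loss_fn(idx: np.ndarray, epoch: int) -> Tensor:
        return loss_on(train_rows[idx])

    def val_fn() -> float:
        return _chunked_scalar(lambda rows: loss_on(rows), val_rows)

    history = _run_training(loss_fn, val_fn, trainables, train_rows.size, protocol)
    return FittedAnnotator(
        model=model,
        head=head,
        classes=classes,
        feature_genes=batch.gene_names,
        vocab=vocab,
        mode=mode,
        history=history,
    )


def _chunked_scalar(fn: Callable[[np.ndarray], Tensor], rows: np.ndarray, chunk: int = 256) -> float:
    vals, weights = [], []
    for start in range(0, rows.size, chunk):
        sub = rows[start : start + chunk]
        vals.append(fn(sub).item())
        weights.append(sub.size)
    return float(np.average(vals, weights=weights))


def predict_annotation(fitted: FittedAnnotator, query: LabeledMatrix, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell labels and class probabilities for a query dataset."""
    batch = fitted.tokenize(query)
    probs = []
    for start in range(0, batch.n_cells, chunk):
        sub = batch.subset_cells(np.arange(start, min(start + chunk, batch.n_cells)))
        logits = fitted.head(fitted.model.forward(sub).cell)
        probs.append(ag.softmax(logits, axis=-1).data)
    probs = np.vstack(probs)
    return fitted.classes[np.argmax(probs, axis=1)], probs


# -------------------------------------------------------------- unsupervised
def fit_unsupervised(
    model: CellTransformer,
    data: LabeledMatrix,
    protocol: TrainProtocol,
    vocab: GeneVocabulary,
    mask_ratio: float | None = None,
    mode: str = "binned",
    n_hvg: int | None = None,
    train_backbone: bool = False,
) -> tuple[TokenizedBatch, list]:
    """Self-supervised adaptation by masked-expression reconstruction.

    Minimizes the GEP loss (plus GEPC under cls pooling) over masked
    non-zero genes; cell-type labels are never read.  With
    ``train_backbone=True`` this doubles as the pretraining routine that
    produces the "native" backbone for downstream studies.  Returns the
    tokenized data (the model's feature space) and the training history.
    """
    ratio = model.config.mask_ratio if mask_ratio is None else mask_ratio
    if ratio <= 0:
        raise ValueError("mask_ratio must be positive for self-supervised adaptation")
    train_rows, val_rows = _donor_holdout(data.donor, protocol.seed)
    batch = assemble_tokens(data, vocab, mode=mode, task="unsup", m=model.config.m_bins, with_cls=True, n_hvg=n_hvg)

    model.set_backbone_trainable(train_backbone)
    trainables = _set_requires_grad(model, [])
    use_gepc = model.config.pooling == "cls"

    def loss_on(rows: np.ndarray, seed: int) -> Tensor:
        sub = batch.subset_cells(rows)
        mask = sample_mask(sub, ratio, seed=seed)
        if not mask.any():
            mask[0, np.argmax(sub.values[0] > 0)] = True
        out = model.forward(sub, mask=mask)
        loss = gep_loss(model, out, sub, mask)
        if use_gepc:
            loss = loss + gepc_loss(model, out, sub, mask)
        return loss

    def loss_fn(idx: np.ndarray, epoch: int) -> Tensor:
        return loss_on(train_rows[idx], seed=protocol.seed + 7919 * epoch + idx[0])

    def val_fn() -> float:
        return _chunked_scalar(lambda rows: loss_on(rows, seed=protocol.seed), val_rows)

    history = _run_training(loss_fn, val_fn, trainables, train_rows.size, protocol)
    return batch, history


# ---------------------------------------------------------- batch correction
def fit_batch_correction(
    model: CellTransformer,
    data: LabeledMatrix,
    protocol: TrainProtocol,
    vocab: GeneVocabulary,
    weights: BatchLossWeights = BatchLossWeights(),
    mode: str = "binned",
    n_hvg: int | None = None,
    d_batch: int = 8,
    mask_ratio: float | None = None,
    train_backbone: bool = False,
) -> tuple[TokenizedBatch, list]:
    """Batch-integration adaptation with the four-part objective.

    Final-block embeddings are concatenated with a learned per-batch
    embedding (width ``d_batch``) before the widened reconstruction heads;
    the ECS margin loss acts on same-batch cell-embedding pairs within each
    minibatch, and the DAR batch classifier trains through gradient
    reversal so the encoder is pushed toward batch invariance.
    """
    n_batches = len(set(data.batch.astype(str)))
    if n_batches < 2:
        raise ValueError("fit_batch_correction requires at least two batches")
    ratio = model.config.mask_ratio if mask_ratio is None else mask_ratio
    train_rows, val_rows = _donor_holdout(data.donor, protocol.seed)
    batch = assemble_tokens(data, vocab, mode=mode, task="batch", m=model.config.m_bins, with_cls=True, n_hvg=n_hvg)

    d = model.config.d_model
    dc = d + d_batch
    rng = np.random.default_rng(protocol.seed)
    wide = {
        "emb_b": Tensor(rng.normal(0, 0.02, (n_batches, d_batch)), requires_grad=True),
        # widened GEP projector (input d + d_batch)
        "proj_W1": Tensor(rng.normal(0, 0.02, (dc, d)), requires_grad=True),
        "proj_b1": Tensor(np.zeros(d), requires_grad=True),
        "proj_W2": Tensor(rng.normal(0, 0.02, (d, 1)), requires_grad=True),
        "proj_b2": Tensor(np.zeros(1), requires_grad=True),
        # widened GEPC: query MLP maps gene embedding d -> dc; bilinear W is dc x dc
        "gepc_W1": Tensor(rng.normal(0, 0.02, (d, d)), requires_grad=True),
        "gepc_b1": Tensor(np.zeros(d), requires_grad=True),
        "gepc_W2": Tensor(rng.normal(0, 0.02, (d, dc)), requires_grad=True),
        "gepc_b2": Tensor(np.zeros(dc), requires_grad=True),
        "gepc_W": Tensor(rng.normal(0, 0.02, (dc, dc)), requires_grad=True),
    }
    dar_head = MLPHead(d, n_batches, seed=protocol.seed + 1)

    model.set_backbone_trainable(train_backbone)
    trainables = _set_requires_grad(model, [dar_head, wide])
    use_gepc = model.config.pooling == "cls"

    def loss_on(rows: np.ndarray, seed: int) -> Tensor:
        sub = batch.subset_cells(rows)
        mask = sample_mask(sub, ratio, seed=seed)
        if not mask.any():
            mask[0, np.argmax(sub.values[0] > 0)] = True
        out = model.forward(sub, mask=mask)
        b_ids = sub.batch_ids
        b_emb = ag.embedding(wide["emb_b"], b_ids)  # (n, d_batch)
        cell_wide = ag.concat([out.cell, b_emb], axis=-1)  # (n, dc)

        loss = Tensor(0.0)
        if weights.use_gep:
            rws, cls_ = np.where(mask)
            hm = out.hidden[(rws, cls_ + out.n_prefix)]  # (K, d)
            hm_wide = ag.concat([hm, b_emb[rws]], axis=-1)  # (K, dc)
            pred = ag.relu(hm_wide @ wide["proj_W1"] + wide["proj_b1"]) @ wide["proj_W2"] + wide["proj_b2"]
            diff = pred.reshape(-1) - Tensor(sub.values[mask])
            loss = loss + (diff * diff).mean()
        if weights.use_gepc and use_gepc:
            loss = loss + gepc_loss(model, out, sub, mask, cell=cell_wide, params=wide)
        if weights.use_ecs:
            loss = loss + _ecs_loss(out.cell, b_ids, weights.margin_beta)
        if weights.use_dar:
            logits = dar_head(ag.grad_reverse(out.cell, weights.dar_lambda))
            loss = loss + cross_entropy(logits, b_ids)
        return loss

    def loss_fn(idx: np.ndarray, epoch: int) -> Tensor:
        return loss_on(train_rows[idx], seed=protocol.seed + 7919 * epoch + idx[0])

    def val_fn() -> float:
        return _chunked_scalar(lambda rows: loss_on(rows, seed=protocol.seed), val_rows, chunk=128)

    history = _run_training(loss_fn, val_fn, trainables, train_rows.size, protocol)
    return batch, history


def _ecs_loss(cell: Tensor, batch_ids: np.ndarray, beta: float) -> Tensor:
    """Elastic cell similarity: -(mean over same-batch pairs of cos - beta)."""
    norm = ((cell * cell).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
    unit = cell * norm
    cos = unit @ unit.transpose()  # (n, n)
    same = (batch_ids[:, None] == batch_ids[None, :]) & ~np.eye(len(batch_ids), dtype=bool)
    iu = np.triu(same)
    if not iu.any():
        return Tensor(0.0)
    pair_mean = (cos * Tensor(iu.astype(float))).sum() * (1.0 / iu.sum())
    return -(pair_mean - beta)


# ---------------------------------------------------------------- perturbation
@dataclass
class FittedPerturbationModel:
    model: CellTransformer
    head: MLPHead
    feature_genes: np.ndarray
    vocab: GeneVocabulary
    history: list = field(default_factory=list)


def fit_perturbation(
    model: CellTransformer,
    pairs: PerturbationPairs,
    protocol: TrainProtocol,
    vocab: GeneVocabulary,
    train_backbone: bool = False,
    head_seed: int = 0,
) -> FittedPerturbationModel:
    """Learn to map a control cell plus a perturbation condition token to the
    paired perturbed expression profile (MSE over all genes, zeros included)."""
    if pairs.control_log1p.shape != pairs.perturbed_log1p.shape:
        raise ValueError("unpaired input: control and perturbed matrices differ in shape")
    batch, target = tokenize_perturbation(pairs, vocab, with_cls=True)
    head = MLPHead(model.config.d_model, 1, seed=head_seed)

    # random pair-level holdout (pairs have no donor identity)
    rng = np.random.default_rng(protocol.seed)
    order = rng.permutation(batch.n_cells)
    n_val = max(1, batch.n_cells // 10)
    val_rows, train_rows = order[:n_val], order[n_val:]

    model.set_backbone_trainable(train_backbone)
    trainables = _set_requires_grad(model, [head])
    gene_cols = batch.gene_columns()

    def loss_on(rows: np.ndarray) -> Tensor:
        sub = batch.subset_cells(rows)
        out = model.forward(sub)
        pred = head(out.hidden[:, gene_cols + out.n_prefix, :]).reshape(rows.size, -1)
        diff = pred - Tensor(target[rows])
        return (diff * diff).mean()

    history = _run_training(
        lambda idx, epoch: loss_on(train_rows[idx]),
        lambda: _chunked_scalar(loss_on, val_rows, chunk=128),
        trainables,
        train_rows.size,
        protocol,
    )
    return FittedPerturbationModel(
        model=model, head=head, feature_genes=batch.gene_names, vocab=vocab, history=history
    )


def predict_perturbation(
    fitted: FittedPerturbationModel,
    controls: LabeledMatrix | np.ndarray,
    target_gene: str,
    gene_names: np.ndarray | None = None,
    chunk: int = 128,
) -> np.ndarray:
    """Predicted post-perturbation log1p expression for each control cell.

    ``controls`` is a LabeledMatrix of counts or an already log1p-normalized
    matrix (with ``gene_names``); predictions are deterministic.
    """
    if isinstance(controls, LabeledMatrix):
        names = controls.gene_names
        log1p = _log1p_normalize(controls.counts)
    else:
        if gene_names is None:
            raise ValueError("gene_names required when controls is a plain matrix")
        names = np.asarray(gene_names, dtype=object)
        log1p = np.asarray(controls, dtype=float)
    pos = {g: j for j, g in enumerate(names)}
    missing = [g for g in fitted.feature_genes if g not in pos]
    if missing:
        raise ValueError(f"gene-space mismatch: controls are missing {len(missing)} model genes")
    cols = np.array([pos[g] for g in fitted.feature_genes])
    log1p = log1p[:, cols]
    if target_gene not in set(fitted.feature_genes):
        raise ValueError(f"unknown perturbation target {target_gene!r} (not in the model gene space)")

    cond = np.zeros(len(fitted.feature_genes), dtype=np.int64)
    cond[np.where(fitted.feature_genes == target_gene)[0][0]] = 1
    pairs = PerturbationPairs(
        control_log1p=log1p,
        perturbed_log1p=log1p,
        condition_tokens=cond,
        gene_names=fitted.feature_genes,
        cell_type=np.array(["?"] * log1p.shape[0], dtype=object),
        target_gene=target_gene,
        source_index=np.arange(log1p.shape[0]),
    )
    batch, _ = tokenize_perturbation(pairs, fitted.vocab, with_cls=True)
    preds = []
    gene_cols = batch.gene_columns()
    for start in range(0, batch.n_cells, chunk):
        sub = batch.subset_cells(np.arange(start, min(start + chunk, batch.n_cells)))
        out = fitted.model.forward(sub)
        pred = fitted.head(out.hidden[:, gene_cols + out.n_prefix, :])
        preds.append(pred.data.reshape(sub.n_cells, -1))
    return np.vstack(preds)
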