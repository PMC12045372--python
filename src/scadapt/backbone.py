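"""Miniature single-cell Transformer backbone.

Embedding layers for gene identity, expression value (binned token, rank
position, or a learned linear lift of the continuous log1p value), and the
binary perturbation condition; ``n`` stacked post-norm Transformer blocks
(attention -> LayerNorm residual -> MLP -> LayerNorm residual, in that
written order); cls or mean pooling into a cell embedding; masked
gene-expression prediction objectives (GEP from gene context, GEPC from the
cell token via a bilinear query); and per-layer, per-head attention-map
export for interpretation.

No positional encodings are used: a cell is a set of (gene, value) tokens,
so the encoder is permutation-equivariant over gene positions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .tokenizer import GeneVocabulary, TokenizedBatch

if TYPE_CHECKING:  # pragma: no cover
    from .adapters import AdapterState

__all__ = [
    "BackboneConfig",
    "EncodeOutput",
    "CellTransformer",
    "MLPHead",
    "layer_norm",
    "sample_mask",
    "gep_loss",
    "gepc_loss",
]

_NEG = -1e9  # additive attention bias for padded keys


@dataclass(frozen=True)
class BackboneConfig:
    """Shape and behavior of the backbone.

    ``d_model`` must be divisible by ``n_heads`` to *run* the model; the
    weight tables themselves are head-count independent (d x d), so
    configurations used only for parameter accounting may violate
    divisibility.
    """

    vocab: GeneVocabulary
    n_blocks: int = 4
    d_model: int = 64
    n_heads: int = 4
    m_bins: int = 51
    d_ff: int | None = None  # MLP hidden width; defaults to d_model
    pooling: str = "cls"  # cls | mean
    mask_ratio: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pooling not in ("cls", "mean"):
            raise ValueError(f"pooling must be 'cls' or 'mean', got {self.pooling!r}")
        if not (0.0 <= self.mask_ratio < 1.0):
            raise ValueError("mask_ratio must lie in [0, 1)")
        if min(self.n_blocks, self.d_model, self.n_heads, self.m_bins) < 1:
            raise ValueError("n_blocks, d_model, n_heads and m_bins must be >= 1")

    @property
    def hidden_ff(self) -> int:
        return self.d_ff if self.d_ff is not None else self.d_model


@dataclass
class EncodeOutput:
    """Forward-pass products: final gene embeddings, pooled cell embedding,
    and (optionally) every layer's head-resolved attention maps."""

    hidden: Tensor  # (n_cells, L, d) final-block embeddings
    cell: Tensor  # (n_cells, d) pooled cell embedding
    attention: list[np.ndarray] | None  # per layer: (n_cells, heads, L, L)
    gene_positions: np.ndarray  # columns of `hidden` holding genes
    cls_position: int | None
    n_prefix: int


class MLPHead:
    """A two-layer perceptron head (in -> hidden -> out) with ReLU."""

    def __init__(self, d_in: int, d_out: int, d_hidden: int | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        h = d_hidden if d_hidden is not None else d_in
        s1 = np.sqrt(2.0 / (d_in + h))
        s2 = np.sqrt(2.0 / (h + d_out))
        self.params: dict[str, Tensor] = {
            "W1": Tensor(rng.normal(0, s1, (d_in, h)), requires_grad=True),
            "b1": Tensor(np.zeros(h), requires_grad=True),
            "W2": Tensor(rng.normal(0, s2, (h, d_out)), requires_grad=True),
            "b2": Tensor(np.zeros(d_out), requires_grad=True),
        }

    def __call__(self, x: Tensor) -> Tensor:
        p = self.params
        return ag.relu(x @ p["W1"] + p["b1"]) @ p["W2"] + p["b2"]

    def n_params(self) -> int:
        return sum(t.size for t in self.params.values())


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gain + bias


class CellTransformer:
    """The backbone model: parameter store plus the forward pass.

    Parameters live in ``self.params`` (name -> Tensor); ``self.trainable``
    flags which groups an optimizer may touch.  A single pluggable adapter
    can be attached via :mod:`scadapt.adapters`; the forward pass consults
    it at the token-embedding, pre-block, attention, and post-attention
    hooks depending on its kind.
    """

    def __init__(self, config: BackboneConfig):
        self.config = config
        self.adapter: Optional["AdapterState"] = None
        rng = np.random.default_rng(config.seed)
        d, ff = config.d_model, config.hidden_ff

        def W(*shape):
            # Xavier for matrices (keeps attention and residual on one scale),
            # unit scale for embedding tables and vectors
            s = np.sqrt(2.0 / (shape[0] + shape[1])) if len(shape) == 2 else 1.0
            return Tensor(rng.normal(0, s, shape), requires_grad=False)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=False)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=False)

        def E(*shape):  # embedding tables: unit per-dimension scale
            return Tensor(rng.normal(0, 1.0, shape), requires_grad=False)

        p: dict[str, Tensor] = {
            "emb_g": E(config.vocab.n_tokens, d),
            "emb_e": E(config.m_bins + 2, d),  # value tokens 0..m plus the mask slot m+1
            "emb_v_w": W(d),  # continuous value lift: v -> v * w + b
            "emb_v_b": zeros(d),
            "emb_c": E(2, d),  # binary perturbation condition
            "mask_emb": W(d),  # continuous-mode mask marker
        }
        for l in range(config.n_blocks):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[f"blk{l}.{nm}"] = W(d, d)
                p[f"blk{l}.{nm[1]}b"] = zeros(d)
            p[f"blk{l}.ln1_g"], p[f"blk{l}.ln1_b"] = ones(d), zeros(d)
            p[f"blk{l}.ln2_g"], p[f"blk{l}.ln2_b"] = ones(d), zeros(d)
            p[f"blk{l}.mlp_W1"], p[f"blk{l}.mlp_b1"] = W(d, ff), zeros(ff)
            p[f"blk{l}.mlp_W2"], p[f"blk{l}.mlp_b2"] = W(ff, d), zeros(d)
        # GEP projector (continuous and binned flavors) and GEPC bilinear query
        p["proj_mse_W1"], p["proj_mse_b1"] = W(d, d), zeros(d)
        p["proj_mse_W2"], p["proj_mse_b2"] = W(d, 1), zeros(1)
        p["proj_ce_W1"], p["proj_ce_b1"] = W(d, d), zeros(d)
        p["proj_ce_W2"], p["proj_ce_b2"] = W(d, config.m_bins + 1), zeros(config.m_bins + 1)
        p["gepc_W1"], p["gepc_b1"] = W(d, d), zeros(d)
        p["gepc_W2"], p["gepc_b2"] = W(d, d), zeros(d)
        p["gepc_W"] = W(d, d)
        self.params = p
        self.trainable = {name: True for name in p}  # fresh model: everything tunable

    # ------------------------------------------------------------ bookkeeping
    def set_backbone_trainable(self, flag: bool) -> None:
        for name in self.params:
            self.trainable[name] = flag

    def trainable_tensors(self) -> dict[str, Tensor]:
        out = {n: t for n, t in self.params.items() if self.trainable[n]}
        if self.adapter is not None:
            out.update({f"adapter.{n}": t for n, t in self.adapter.params.items()})
        return out

    def frozen_checksum(self) -> str:
        """SHA-256 digest over all frozen parameter bytes, in name order."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            if not self.trainable[name]:
                h.update(name.encode())
                h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def n_backbone_params(self) -> int:
        return sum(t.size for t in self.params.values())

    # ---------------------------------------------------------------- forward
    def forward(
        self,
        batch: TokenizedBatch,
        mask: np.ndarray | None = None,
        capture_attention: bool = False,
    ) -> EncodeOutput:
        cfg = self.config
        d = cfg.d_model
        if d % cfg.n_heads != 0:
            raise ValueError(f"d_model={d} is not divisible by n_heads={cfg.n_heads}")
        H, dh = cfg.n_heads, d // cfg.n_heads
        p = self.params
        adapter = self.adapter
        n, L = batch.gene_ids.shape

        g_emb = ag.embedding(p["emb_g"], batch.gene_ids)  # (n, L, d)

        if batch.mode in ("binned", "rank"):
            tokens = batch.value_tokens.copy()
            if mask is not None:
                tokens[mask] = cfg.m_bins + 1  # the mask slot of emb_e
            e_emb = ag.embedding(p["emb_e"], tokens)
        else:
            vals = batch.values.copy()
            if mask is not None:
                vals[mask] = 0.0
            e_emb = Tensor(vals[:, :, None]) * p["emb_v_w"] + p["emb_v_b"]
            if mask is not None and mask.any():
                e_emb = e_emb + Tensor(mask[:, :, None].astype(float)) * p["mask_emb"]

        if adapter is not None and adapter.config.kind == "token":
            e_emb = adapter.apply_token(e_emb)

        h = g_emb + e_emb
        if batch.condition_tokens is not None:
            h = h + ag.embedding(p["emb_c"], batch.condition_tokens)

        attn_valid = batch.attention_mask
        n_prefix = 0
        if adapter is not None and adapter.config.kind == "prefix":
            h, attn_valid = adapter.prepend_prefix(h, attn_valid)
            n_prefix = adapter.config.prefix_len
        Lp = L + n_prefix

        bias = np.where(attn_valid[:, None, None, :], 0.0, _NEG)  # (n,1,1,Lp)
        scale = 1.0 / np.sqrt(d)  # embedding-dimension scaling, as written
        maps: list[np.ndarray] | None = [] if capture_attention else None

        for l in range(cfg.n_blocks):
            q = h @ p[f"blk{l}.Wq"] + p[f"blk{l}.qb"]
            k = h @ p[f"blk{l}.Wk"] + p[f"blk{l}.kb"]
            v = h @ p[f"blk{l}.Wv"] + p[f"blk{l}.vb"]
            if adapter is not None and adapter.config.kind == "lora" and l in adapter.lora_blocks:
                q = q + adapter.apply_lora(h, l, "q")
                v = v + adapter.apply_lora(h, l, "v")

            def split(t: Tensor) -> Tensor:  # (n, Lp, d) -> (n, H, Lp, dh)
                return t.reshape(n, Lp, H, dh).transpose(0, 2, 1, 3)

            qh, kh, vh = split(q), split(k), split(v)
            scores = qh @ kh.swapaxes(-1, -2) * scale + Tensor(bias)
            att = ag.softmax(scores, axis=-1)  # (n, H, Lp, Lp)
            if maps is not None:
                maps.append(att.data.copy())
            ctx = (att @ vh).transpose(0, 2, 1, 3).reshape(n, Lp, d)
            attn_out = ctx @ p[f"blk{l}.Wo"] + p[f"blk{l}.ob"]

            a = layer_norm(attn_out + h, p[f"blk{l}.ln1_g"], p[f"blk{l}.ln1_b"])
            if adapter is not None and adapter.config.kind == "encoder" and l in adapter.encoder_blocks:
                a = adapter.apply_encoder(a, l)
            mlp = ag.relu(a @ p[f"blk{l}.mlp_W1"] + p[f"blk{l}.mlp_b1"]) @ p[f"blk{l}.mlp_W2"] + p[f"blk{l}.mlp_b2"]
            h = layer_norm(mlp + a, p[f"blk{l}.ln2_g"], p[f"blk{l}.ln2_b"])

        gene_positions = batch.gene_columns() + n_prefix
        cls_position = None if batch.cls_index is None else batch.cls_index + n_prefix
        if cfg.pooling == "cls":
            if cls_position is None:
                raise ValueError("cls pooling requires a batch assembled with_cls=True")
            cell = h[:, cls_position, :]
        else:
            # mean over valid gene positions (prefix and cls excluded)
            w = np.zeros((n, Lp))
            w[:, gene_positions] = attn_valid[:, gene_positions]
            w = w / w.sum(axis=1, keepdims=True)
            cell = (h * Tensor(w[:, :, None])).sum(axis=1)

        return EncodeOutput(
            hidden=h,
            cell=cell,
            attention=maps,
            gene_positions=gene_positions,
            cls_position=cls_position,
            n_prefix=n_prefix,
        )

    def encode_cells(self, batch: TokenizedBatch, chunk: int = 256) -> np.ndarray:
        """Pooled cell embeddings as a plain array (no gradient tape)."""
        outs = []
        for start in range(0, batch.n_cells, chunk):
            sub = batch.subset_cells(np.arange(start, min(start + chunk, batch.n_cells)))
            outs.append(self.forward(sub).cell.data)
        return np.vstack(outs)


# ------------------------------------------------------------------- masking
def sample_mask(batch: TokenizedBatch, mask_ratio: float, seed: int = 0) -> np.ndarray:
    """Boolean (n_cells, L) mask over non-zero gene positions.

    Per cell, ``floor(mask_ratio * n_nonzero)`` positions are drawn
    uniformly without replacement from positions with non-zero expression
    (cls and padding are never masked).
    """
    if not (0.0 <= mask_ratio < 1.0):
        raise ValueError("mask_ratio must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = np.zeros(batch.gene_ids.shape, dtype=bool)
    if mask_ratio == 0.0:
        return mask
    gene_cols = batch.gene_columns()
    for i in range(batch.n_cells):
        valid = gene_cols[batch.attention_mask[i, gene_cols] & (batch.values[i, gene_cols] > 0)]
        k = int(mask_ratio * valid.size)
        if k:
            mask[i, rng.choice(valid, size=k, replace=False)] = True
    return mask


def _gather_masked(x: Tensor, mask: np.ndarray, n_prefix: int) -> Tensor:
    rows, cols = np.where(mask)
    return x[(rows, cols + n_prefix)]


def gep_loss(model: CellTransformer, output: EncodeOutput, batch: TokenizedBatch, mask: np.ndarray) -> Tensor:
    """Masked gene-expression prediction loss.

    Cross-entropy over value tokens for binned/rank inputs, mean squared
    error on log1p values for continuous inputs; averaged over the masked
    positions.
    """
    if not mask.any():
        raise ValueError("nothing to reconstruct: the mask set is empty")
    p = model.params
    hm = _gather_masked(output.hidden, mask, output.n_prefix)  # (K, d)
    if batch.mode == "continuous":
        pred = ag.relu(hm @ p["proj_mse_W1"] + p["proj_mse_b1"]) @ p["proj_mse_W2"] + p["proj_mse_b2"]
        target = batch.values[mask]
        diff = pred.reshape(-1) - Tensor(target)
        return (diff * diff).mean()
    logits = ag.relu(hm @ p["proj_ce_W1"] + p["proj_ce_b1"]) @ p["proj_ce_W2"] + p["proj_ce_b2"]
    targets = batch.value_tokens[mask]
    return cross_entropy(logits, targets)


def gepc_loss(
    model: CellTransformer,
    output: EncodeOutput,
    batch: TokenizedBatch,
    mask: np.ndarray,
    cell: Tensor | None = None,
    params: dict[str, Tensor] | None = None,
) -> Tensor:
    """Cell-token-conditioned masked expression loss.

    Each masked gene's identity embedding is mapped by an MLP to a query
    ``q_j``; the prediction is the bilinear form ``q_j . (W h_c)`` against
    the pooled cell embedding, scored by MSE on the log1p value.  ``cell``
    and ``params`` allow the batch-integration task to substitute a widened
    cell representation and its own widened weights.
    """
    if model.config.pooling != "cls" and cell is None:
        raise ValueError("gepc_loss requires cls pooling (no cell token row otherwise)")
    if not mask.any():
        raise ValueError("nothing to reconstruct: the mask set is empty")
    p = params if params is not None else model.params
    hc = cell if cell is not None else output.cell  # (n, d_c)
    rows, cols = np.where(mask)
    g_emb = ag.embedding(model.params["emb_g"], batch.gene_ids[mask])  # (K, d)
    q = ag.relu(g_emb @ p["gepc_W1"] + p["gepc_b1"]) @ p["gepc_W2"] + p["gepc_b2"]  # (K, d)
    wh = hc @ p["gepc_W"].transpose()  # (n, d); row i is W h_c(i)
    pred = (q * wh[rows]).sum(axis=-1)  # (K,)
    diff = pred - Tensor(batch.values[mask])
    return (diff * diff).mean()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between logits (K, C) and integer targets (K,)."""
    z = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - lse
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(targets)), targets] = 1.0
    return -(logp * Tensor(onehot)).sum(axis=-1).mean()
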