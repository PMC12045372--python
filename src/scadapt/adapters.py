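"""Pluggable parameter-efficient adapters for the frozen backbone.

Four adapter families, each a small trainable module attached to a frozen
Transformer so that task adaptation updates only the adapter (plus a task
head):

* **Token adapter** — a bottleneck autoencoder (d -> s -> d, ReLU) on the
  expression-value embedding, in residual form with a zero-initialized
  up-projection so the adapted model starts exactly at the native model.
* **Prefix adapter** — ``k`` learnable d-dimensional tokens prepended to
  the sequence entering block 1 and carried through all blocks; prefix
  positions are excluded from reconstruction targets, pooling means and
  attention profiles.
* **LoRA** — low-rank updates ``ΔW = B A`` (A: r x d Gaussian, B: d x r
  zeros) added to the Query and Value projections of selected blocks; Key
  is untouched, so ΔW = 0 at initialization.
* **Encoder adapter** — the same residual bottleneck applied to the
  post-attention LayerNorm output inside selected blocks.

``freeze_and_count`` does the exact parameter accounting behind the
framework's efficiency claims (trainable fraction, frozen checksum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from . import autodiff as ag
from .autodiff import Tensor
from .backbone import CellTransformer, MLPHead

__all__ = [
    "AdapterConfig",
    "AdapterState",
    "attach_token_adapter",
    "attach_prefix_adapter",
    "attach_lora",
    "attach_encoder_adapter",
    "attach_adapter",
    "detach_adapter",
    "freeze_and_count",
]

Kind = Literal["token", "prefix", "lora", "encoder"]


@dataclass(frozen=True)
class AdapterConfig:
    """Hyperparameters of one adapter.

    Defaults: bottleneck ``s=8``, prefix length ``k=8``, rank ``r=8``,
    adapter carried by every block.
    """

    kind: Kind
    bottleneck_dim: int = 8
    prefix_len: int = 8
    lora_rank: int = 8
    target_blocks: tuple[int, ...] | None = None  # None = all blocks
    zero_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("token", "prefix", "lora", "encoder"):
            raise ValueError(f"unknown adapter kind {self.kind!r}")
        if self.bottleneck_dim < 1 or self.lora_rank < 1 or self.prefix_len < 0:
            raise ValueError("bottleneck_dim, lora_rank must be >= 1 and prefix_len >= 0")


class AdapterState:
    """Trainable adapter parameters plus the forward hooks the backbone calls."""

    def __init__(self, config: AdapterConfig, model: CellTransformer):
        self.config = config
        d = model.config.d_model
        n = model.config.n_blocks
        blocks = tuple(range(n)) if config.target_blocks is None else tuple(sorted(config.target_blocks))
        if blocks and (min(blocks) < 0 or max(blocks) >= n):
            raise ValueError(f"target_blocks {blocks} out of range for {n} blocks")
        self.lora_blocks = blocks if config.kind == "lora" else ()
        self.encoder_blocks = blocks if config.kind == "encoder" else ()
        rng = np.random.default_rng(config.seed)
        s = config.bottleneck_dim
        r = config.lora_rank
        p: dict[str, Tensor] = {}

        if config.kind == "token":
            if s >= d:
                raise ValueError(f"bottleneck must compress: s={s} >= d={d}")
            p["down_W"] = Tensor(rng.normal(0, 0.02, (d, s)), requires_grad=True)
            p["down_b"] = Tensor(np.zeros(s), requires_grad=True)
            up = np.zeros((s, d)) if config.zero_init else rng.normal(0, 0.02, (s, d))
            p["up_W"] = Tensor(up, requires_grad=True)
            p["up_b"] = Tensor(np.zeros(d), requires_grad=True)
        elif config.kind == "prefix":
            if config.prefix_len < 1:
                raise ValueError("prefix adapter requires prefix_len >= 1")
            p["prefix"] = Tensor(rng.normal(0, 0.02, (config.prefix_len, d)), requires_grad=True)
        elif config.kind == "lora":
            if r >= d:
                raise ValueError(f"LoRA rank must satisfy r < d: r={r}, d={d}")
            for l in blocks:
                for tgt in ("q", "v"):
                    p[f"A{l}_{tgt}"] = Tensor(rng.normal(0, 0.02, (r, d)), requires_grad=True)
                    B = np.zeros((d, r)) if config.zero_init else rng.normal(0, 0.02, (d, r))
                    p[f"B{l}_{tgt}"] = Tensor(B, requires_grad=True)
        elif config.kind == "encoder":
            if not blocks:
                raise ValueError("encoder adapter requires at least one target block")
            if s >= d:
                raise ValueError(f"bottleneck must compress: s={s} >= d={d}")
            for l in blocks:
                p[f"down_W{l}"] = Tensor(rng.normal(0, 0.02, (d, s)), requires_grad=True)
                p[f"down_b{l}"] = Tensor(np.zeros(s), requires_grad=True)
                up = np.zeros((s, d)) if config.zero_init else rng.normal(0, 0.02, (s, d))
                p[f"up_W{l}"] = Tensor(up, requires_grad=True)
                p[f"up_b{l}"] = Tensor(np.zeros(d), requires_grad=True)
        self.params = p

    # --------------------------------------------------------------- hooks
    def apply_token(self, e_emb: Tensor) -> Tensor:
        p = self.params
        return e_emb + ag.relu(e_emb @ p["down_W"] + p["down_b"]) @ p["up_W"] + p["up_b"]

    def prepend_prefix(self, h: Tensor, attn_valid: np.ndarray) -> tuple[Tensor, np.ndarray]:
        n = h.shape[0]
        k = self.config.prefix_len
        pref = self.params["prefix"].reshape(1, k, h.shape[2]) * Tensor(np.ones((n, 1, 1)))
        h = ag.concat([pref, h], axis=1)
        valid = np.hstack([np.ones((n, k), dtype=bool), attn_valid])
        return h, valid

    def apply_lora(self, h: Tensor, block: int, target: str) -> Tensor:
        A = self.params[f"A{block}_{target}"]
        B = self.params[f"B{block}_{target}"]
        return h @ A.transpose() @ B.transpose()

    def apply_encoder(self, a: Tensor, block: int) -> Tensor:
        p = self.params
        return a + ag.relu(a @ p[f"down_W{block}"] + p[f"down_b{block}"]) @ p[f"up_W{block}"] + p[f"up_b{block}"]

    def n_params(self) -> int:
        return sum(t.size for t in self.params.values())


def attach_adapter(model: CellTransformer, config: AdapterConfig) -> CellTransformer:
    """Attach an adapter and freeze the backbone; returns the same model."""
    model.adapter = AdapterState(config, model)
    model.set_backbone_trainable(False)
    return model


def attach_token_adapter(model: CellTransformer, config: AdapterConfig) -> CellTransformer:
    if config.kind != "token":
        raise ValueError("attach_token_adapter requires kind='token'")
    return attach_adapter(model, config)


def attach_prefix_adapter(model: CellTransformer, config: AdapterConfig) -> CellTransformer:
    if config.kind != "prefix":
        raise ValueError("attach_prefix_adapter requires kind='prefix'")
    return attach_adapter(model, config)


def attach_lora(model: CellTransformer, config: AdapterConfig) -> CellTransformer:
    if config.kind != "lora":
        raise ValueError("attach_lora requires kind='lora'")
    return attach_adapter(model, config)


def attach_encoder_adapter(model: CellTransformer, config: AdapterConfig) -> CellTransformer:
    if config.kind != "encoder":
        raise ValueError("attach_encoder_adapter requires kind='encoder'")
    return attach_adapter(model, config)


def detach_adapter(model: CellTransformer) -> CellTransformer:
    """Remove the adapter; the native forward pass is restored bit-exactly."""
    model.adapter = None
    return model


def freeze_and_count(model: CellTransformer, heads: Iterable[MLPHead | dict] = ()) -> dict:
    """Exact parameter accounting for a (backbone + adapter + heads) assembly.

    Returns trainable and total parameter counts, the trainable fraction,
    and a SHA-256 checksum over the frozen backbone parameters (stable
    across any number of adapter-only optimization steps).
    """
    backbone_total = model.n_backbone_params()
    backbone_trainable = sum(
        model.params[n].size for n in model.params if model.trainable[n]
    )
    adapter_n = model.adapter.n_params() if model.adapter is not None else 0
    head_n = 0
    for head in heads:
        if isinstance(head, MLPHead):
            head_n += head.n_params()
        else:  # plain dict of Tensors
            head_n += sum(t.size for t in head.values())
    total = backbone_total + adapter_n + head_n
    trainable = backbone_trainable + adapter_n + head_n
    return {
        "trainable_params": int(trainable),
        "total_params": int(total),
        "fraction": trainable / total,
        "frozen_checksum": model.frozen_checksum(),
    }
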