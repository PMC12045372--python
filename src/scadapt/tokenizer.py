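"""Gene vocabulary and expression tokenization.

Turns a count matrix into the token streams the Transformer consumes: each
gene becomes an integer identity token from a fixed vocabulary, and its
expression becomes either a discrete value token (per-cell quantile binning
of the non-zero normalized values into ``m`` bins, zeros mapping to token
0), a rank position (expression scaled by 10000, divided by the gene's
corpus-wide non-zero median, genes ordered by descending scaled value), or
the raw log1p-normalized value for continuous-input tasks.

Highly variable gene selection and the per-task token assembly (appending
the ``<cls>`` cell token, batch ids for integration, binary perturbation
condition tokens) also live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .syndata import LabeledMatrix, PerturbationPairs, _log1p_normalize

__all__ = [
    "GeneVocabulary",
    "CorpusMedians",
    "TokenizedBatch",
    "match_genes",
    "select_hvg",
    "bin_expression",
    "rank_value_encode",
    "compute_corpus_medians",
    "assemble_tokens",
    "tokenize_perturbation",
]

Mode = Literal["binned", "rank", "continuous"]
Task = Literal["annotation", "unsup", "batch", "perturb"]


@dataclass(frozen=True)
class GeneVocabulary:
    """Bidirectional gene-symbol <-> integer-id map plus special tokens.

    Gene ids are contiguous from 0; the pad/cls/mask special ids follow the
    gene block and never collide with it.
    """

    gene_to_id: Mapping[str, int]
    pad_id: int
    cls_id: int
    mask_id: int

    def __post_init__(self) -> None:
        ids = list(self.gene_to_id.values())
        if not ids:
            raise ValueError("GeneVocabulary must contain at least one gene")
        if sorted(ids) != list(range(len(ids))):
            raise ValueError("gene ids must be unique and contiguous from 0")
        specials = {self.pad_id, self.cls_id, self.mask_id}
        if len(specials) != 3 or specials & set(ids):
            raise ValueError("special ids must be distinct and disjoint from gene ids")

    @classmethod
    def from_genes(cls, genes: Sequence[str]) -> "GeneVocabulary":
        n = len(genes)
        return cls(gene_to_id={g: i for i, g in enumerate(genes)}, pad_id=n, cls_id=n + 1, mask_id=n + 2)

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_id)

    @property
    def n_tokens(self) -> int:
        """Size of the identity-embedding table (genes + 3 specials)."""
        return self.n_genes + 3

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_to_id

    def __getitem__(self, gene: str) -> int:
        return self.gene_to_id[gene]

    # ------------------------------------------------------------------- json
    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": dict(self.gene_to_id),
            "specials": {"pad": self.pad_id, "cls": self.cls_id, "mask": self.mask_id},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneVocabulary":
        payload = json.loads(Path(path).read_text())
        sp = payload["specials"]
        return cls(
            gene_to_id={str(k): int(v) for k, v in payload["genes"].items()},
            pad_id=int(sp["pad"]),
            cls_id=int(sp["cls"]),
            mask_id=int(sp["mask"]),
        )


@dataclass
class CorpusMedians:
    """Per-gene non-zero median expression, the rank-encoding normalizer.

    Genes never observed non-zero get NaN and are flagged unusable.
    """

    gene_names: np.ndarray
    medians: np.ndarray

    @classmethod
    def from_counts(cls, counts: np.ndarray, gene_names: Sequence[str]) -> "CorpusMedians":
        counts = np.asarray(counts, dtype=float)
        med = np.full(counts.shape[1], np.nan)
        for j in range(counts.shape[1]):
            nz = counts[:, j][counts[:, j] > 0]
            if nz.size:
                med[j] = np.median(nz)
        return cls(gene_names=np.asarray(gene_names, dtype=object), medians=med)

    def usable(self) -> np.ndarray:
        return np.isfinite(self.medians) & (self.medians > 0)


@dataclass
class TokenizedBatch:
    """Per-cell token arrays feeding the encoder.

    ``gene_ids`` and ``values`` are (n_cells, L); ``value_tokens`` is
    present for binned/rank modes; ``values`` always carries the
    log1p-normalized expression used as the regression target.  The ``cls``
    position, when present, is the last column.  ``n_prefix`` is filled in
    by the prefix adapter at forward time and stays 0 here.
    """

    gene_ids: np.ndarray
    values: np.ndarray
    value_tokens: np.ndarray | None
    attention_mask: np.ndarray
    gene_names: np.ndarray
    mode: Mode
    cls_index: int | None = None
    condition_tokens: np.ndarray | None = None
    batch_ids: np.ndarray | None = None
    mask_positions: np.ndarray | None = None
    n_prefix: int = 0

    @property
    def n_cells(self) -> int:
        return self.gene_ids.shape[0]

    @property
    def seq_len(self) -> int:
        return self.gene_ids.shape[1]

    def gene_columns(self) -> np.ndarray:
        """Column indices holding genes (excludes the cls position)."""
        cols = np.arange(self.seq_len)
        if self.cls_index is not None:
            cols = cols[cols != self.cls_index]
        return cols

    def subset_cells(self, idx: np.ndarray) -> "TokenizedBatch":
        return TokenizedBatch(
            gene_ids=self.gene_ids[idx],
            values=self.values[idx],
            value_tokens=None if self.value_tokens is None else self.value_tokens[idx],
            attention_mask=self.attention_mask[idx],
            gene_names=self.gene_names,
            mode=self.mode,
            cls_index=self.cls_index,
            condition_tokens=None if self.condition_tokens is None else self.condition_tokens[idx],
            batch_ids=None if self.batch_ids is None else self.batch_ids[idx],
            mask_positions=None,
            n_prefix=self.n_prefix,
        )


def match_genes(gene_names: Sequence[str], vocab: GeneVocabulary) -> tuple[np.ndarray, np.ndarray]:
    """Drop genes absent from the vocabulary, preserving order.

    Returns (kept column indices, their vocabulary ids).
    """
    kept, ids = [], []
    for j, g in enumerate(gene_names):
        if g in vocab:
            kept.append(j)
            ids.append(vocab[g])
    if not kept:
        raise ValueError("no vocabulary overlap: none of the input genes are in the vocabulary")
    return np.asarray(kept, dtype=np.int64), np.asarray(ids, dtype=np.int64)


def select_hvg(data: LabeledMatrix, n_top: int = 2000) -> np.ndarray:
    """Indices of the ``n_top`` most highly variable genes.

    Dispersion (variance/mean) of log1p library-normalized expression,
    highest first; ties break by ascending gene index.  A plain dispersion
    ranking is used rather than mean-binned z-scoring so that genes with
    genuinely high dispersion are always ranked above constant genes,
    whatever their mean expression.  Deterministic given the input.
    """
    if n_top <= 0:
        raise ValueError(f"n_top must be positive, got {n_top}")
    if n_top > data.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={data.n_genes}")
    if n_top == data.n_genes:
        return np.arange(data.n_genes)
    log1p = _log1p_normalize(data.counts)
    mean = log1p.mean(axis=0)
    var = log1p.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.lexsort((np.arange(data.n_genes), -disp))
    return np.sort(order[:n_top])


def bin_expression(values: np.ndarray, m: int) -> np.ndarray:
    """Per-cell quantile binning of non-negative expression into tokens 0..m.

    Zeros map to token 0; positive values map to 1..m using the m-quantile
    edges of the cell's own non-zero values, so the mapping is monotone
    within a cell and robust to library-size differences.
    """
    values = np.asarray(values, dtype=float)
    if m < 1:
        raise ValueError(f"bin count m must be >= 1, got {m}")
    if (values < 0).any():
        raise ValueError("bin_expression requires non-negative values")
    single = values.ndim == 1
    V = values[None, :] if single else values
    tokens = np.zeros(V.shape, dtype=np.int64)
    for i in range(V.shape[0]):
        nz = V[i] > 0
        if not nz.any():
            continue
        edges = np.quantile(V[i][nz], np.linspace(0, 1, m + 1)[1:-1])
        tokens[i][nz] = 1 + np.searchsorted(edges, V[i][nz], side="right")
    return tokens[0] if single else tokens


def rank_value_encode(values: np.ndarray, medians: CorpusMedians) -> np.ndarray:
    """Order a cell's expressed genes by 10000*value/median, descending.

    Returns the gene *column indices* in rank order (highest scaled value
    first); ties break by ascending column index.  Zero-expressed genes are
    excluded.  Raises if a non-zero gene lacks a usable corpus median.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("rank_value_encode operates on a single cell")
    nz = np.where(values > 0)[0]
    usable = medians.usable()
    missing = nz[~usable[nz]]
    if missing.size:
        raise ValueError(
            f"missing corpus median for non-zero genes: {list(medians.gene_names[missing])}"
        )
    scaled = 10000.0 * values[nz] / medians.medians[nz]
    order = np.lexsort((nz, -scaled))
    return nz[order]


def compute_corpus_medians(data: LabeledMatrix) -> CorpusMedians:
    """Corpus medians from library-normalized (counts per 10k) expression."""
    lib = data.counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return CorpusMedians.from_counts(data.counts / lib * 1e4, data.gene_names)


def assemble_tokens(
    data: LabeledMatrix,
    vocab: GeneVocabulary,
    mode: Mode = "binned",
    task: Task = "annotation",
    m: int = 51,
    with_cls: bool = True,
    n_hvg: int | None = None,
    medians: CorpusMedians | None = None,
) -> TokenizedBatch:
    """Full tokenization pipeline for one dataset and task.

    Vocabulary matching always applies.  For annotation/unsup/batch tasks an
    optional HVG subset (``n_hvg``) restricts the gene set; the perturbation
    task keeps every matched gene, zeros included, and requires continuous
    values.  The ``<cls>`` column, when requested, is appended after the
    genes.
    """
    if task == "perturb" and mode != "continuous":
        raise ValueError("the perturbation task requires mode='continuous' (log1p values in and out)")
    if mode == "rank" and task == "perturb":
        raise ValueError("rank mode is not defined for the perturbation task")

    work = data
    if task != "perturb" and n_hvg is not None and n_hvg < work.n_genes:
        work = work.subset_genes(select_hvg(work, n_hvg))
    kept, ids = match_genes(work.gene_names, vocab)
    work = work.subset_genes(kept)
    log1p = _log1p_normalize(work.counts)

    n, M = log1p.shape
    if mode == "rank":
        if medians is None:
            medians = compute_corpus_medians(work)
        seqs = [rank_value_encode(log1p[i], medians) for i in range(n)]
        L = max((len(s) for s in seqs), default=0)
        gene_ids = np.full((n, L), vocab.pad_id, dtype=np.int64)
        values = np.zeros((n, L))
        value_tokens = np.zeros((n, L), dtype=np.int64)
        mask = np.zeros((n, L), dtype=bool)
        for i, s in enumerate(seqs):
            gene_ids[i, : len(s)] = ids[s]
            values[i, : len(s)] = log1p[i, s]
            # rank position stands in for the value token, capped at m
            value_tokens[i, : len(s)] = np.minimum(np.arange(1, len(s) + 1), m)
            mask[i, : len(s)] = True
        gene_names = work.gene_names  # column identity varies per cell in rank mode
    else:
        gene_ids = np.tile(ids, (n, 1))
        values = log1p
        mask = np.ones((n, M), dtype=bool)
        value_tokens = bin_expression(log1p, m) if mode == "binned" else None
        gene_names = work.gene_names

    cls_index = None
    if with_cls:
        gene_ids = np.hstack([gene_ids, np.full((n, 1), vocab.cls_id, dtype=np.int64)])
        values = np.hstack([values, np.zeros((n, 1))])
        if value_tokens is not None:
            value_tokens = np.hstack([value_tokens, np.zeros((n, 1), dtype=np.int64)])
        mask = np.hstack([mask, np.ones((n, 1), dtype=bool)])
        cls_index = gene_ids.shape[1] - 1

    condition_tokens = None
    batch_ids = None
    if task == "batch":
        batches = {b: i for i, b in enumerate(sorted(set(data.batch.astype(str))))}
        batch_ids = np.array([batches[str(b)] for b in data.batch], dtype=np.int64)

    return TokenizedBatch(
        gene_ids=gene_ids,
        values=values,
        value_tokens=value_tokens,
        attention_mask=mask,
        gene_names=gene_names,
        mode=mode,
        cls_index=cls_index,
        condition_tokens=condition_tokens,
        batch_ids=batch_ids,
    )


def tokenize_perturbation(
    pairs: PerturbationPairs, vocab: GeneVocabulary, with_cls: bool = True
) -> tuple[TokenizedBatch, np.ndarray]:
    """Tokenize paired perturbation data (continuous mode, all genes kept).

    Returns the tokenized control cells (with per-gene binary condition
    tokens) and the aligned target matrix of perturbed log1p values.
    """
    kept, ids = match_genes(pairs.gene_names, vocab)
    control = pairs.control_log1p[:, kept]
    target = pairs.perturbed_log1p[:, kept]
    cond = pairs.condition_tokens[kept]
    n, M = control.shape

    gene_ids = np.tile(ids, (n, 1))
    values = control.copy()
    condition = np.tile(cond, (n, 1))
    mask = np.ones((n, M), dtype=bool)
    cls_index = None
    if with_cls:
        gene_ids = np.hstack([gene_ids, np.full((n, 1), vocab.cls_id, dtype=np.int64)])
        values = np.hstack([values, np.zeros((n, 1))])
        condition = np.hstack([condition, np.zeros((n, 1), dtype=np.int64)])
        mask = np.hstack([mask, np.ones((n, 1), dtype=bool)])
        cls_index = gene_ids.shape[1] - 1

    batch = TokenizedBatch(
        gene_ids=gene_ids,
        values=values,
        value_tokens=None,
        attention_mask=mask,
        gene_names=pairs.gene_names[kept],
        mode="continuous",
        cls_index=cls_index,
        condition_tokens=condition,
    )
    return batch, target
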