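"""Attention-based gene–cell-state association and zero-shot utilities.

The cls row of the head-averaged attention map quantifies how much each
gene informs the cell representation.  For two cell groups, the per-gene
difference of mean attention (the differential attention score) ranks
condition-associated genes; significance comes from a two-sided Wilcoxon
rank-sum test per gene with Benjamini–Yekutieli correction across genes.

Also here: k-nearest-neighbor label transfer for the zero-shot protocol,
ortholog mapping into the model vocabulary for cross-species work, and
Leiden clustering of cell embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import ranksums
from sklearn.neighbors import NearestNeighbors, kneighbors_graph
from statsmodels.stats.multitest import multipletests

from .backbone import CellTransformer
from .syndata import LabeledMatrix
from .tokenizer import GeneVocabulary, TokenizedBatch, match_genes

__all__ = [
    "AttentionProfile",
    "DifferentialAttentionResult",
    "extract_attention",
    "differential_attention",
    "export_ranked_genes",
    "knn_label_transfer",
    "map_orthologs",
    "cluster_embeddings",
]


@dataclass
class AttentionProfile:
    """Per-cell, per-layer cls-row attention over gene positions.

    ``profiles[layer]`` is (n_cells, n_genes); rows are renormalized to sum
    to 1 after dropping cls/prefix columns, making cells with different
    prefix lengths comparable.
    """

    profiles: dict[int, np.ndarray]
    gene_names: np.ndarray

    def layer(self, l: int) -> np.ndarray:
        return self.profiles[l]


def extract_attention(
    model: CellTransformer,
    batch: TokenizedBatch,
    layers=None,
    chunk: int = 128,
) -> AttentionProfile:
    """Head-averaged, renormalized cls-row attention for the requested layers.

    ``layers`` defaults to the last block; any subset of blocks (e.g. top,
    middle, last) may be requested.
    """
    if model.config.pooling != "cls":
        raise ValueError("no cls row: attention profiles require a cls-pooling model")
    if batch.cls_index is None:
        raise ValueError("batch was assembled without a cls token")
    if layers is None:
        layers = [model.config.n_blocks - 1]
    layers = list(layers)
    for l in layers:
        if not (0 <= l < model.config.n_blocks):
            raise ValueError(f"layer {l} out of range for {model.config.n_blocks} blocks")

    collected: dict[int, list[np.ndarray]] = {l: [] for l in layers}
    for start in range(0, batch.n_cells, chunk):
        sub = batch.subset_cells(np.arange(start, min(start + chunk, batch.n_cells)))
        out = model.forward(sub, capture_attention=True)
        gene_cols = out.gene_positions
        for l in layers:
            att = out.attention[l].mean(axis=1)  # head average: (n, L, L)
            row = att[:, out.cls_position, :][:, gene_cols]  # drop cls/prefix columns
            row = row / row.sum(axis=1, keepdims=True)
            collected[l].append(row)
    return AttentionProfile(
        profiles={l: np.vstack(collected[l]) for l in layers},
        gene_names=batch.gene_names,
    )


@dataclass
class DifferentialAttentionResult:
    gene_names: np.ndarray
    delta: np.ndarray  # mean attention in group_a minus group_b, per gene
    p_values: np.ndarray
    q_values: np.ndarray  # Benjamini–Yekutieli adjusted
    ranking: np.ndarray  # gene indices sorted by |delta| descending


def differential_attention(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    gene_names=None,
) -> DifferentialAttentionResult:
    """Per-gene differential attention between two disjoint cell groups.

    ``profiles_a``/``profiles_b`` are (cells, genes) attention profiles for
    the two groups; per-cell attention values are the test samples.
    """
    A = np.asarray(profiles_a, dtype=float)
    B = np.asarray(profiles_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("profile matrices must be 2-D with matching gene columns")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least two cells")
    G = A.shape[1]
    if gene_names is None:
        gene_names = np.array([f"G{j}" for j in range(G)], dtype=object)
    gene_names = np.asarray(gene_names, dtype=object)

    delta = A.mean(axis=0) - B.mean(axis=0)
    pvals = np.ones(G)
    for j in range(G):
        if np.all(A[:, j] == A[0, j]) and np.all(B[:, j] == A[0, j]):
            continue  # identical constant samples: no evidence
        pvals[j] = ranksums(A[:, j], B[:, j]).pvalue
    qvals = multipletests(pvals, method="fdr_by")[1]
    ranking = np.lexsort((np.arange(G), -np.abs(delta)))
    return DifferentialAttentionResult(
        gene_names=gene_names, delta=delta, p_values=pvals, q_values=qvals, ranking=ranking
    )


def export_ranked_genes(result: DifferentialAttentionResult, path) -> Path:
    """Write a two-column .rnk ranked gene list (symbol, delta), descending."""
    path = Path(path)
    order = np.lexsort((np.arange(len(result.delta)), -result.delta))
    lines = [f"{result.gene_names[j]}\t{result.delta[j]:.10g}" for j in order]
    path.write_text("\n".join(lines) + "\n")
    return path


def knn_label_transfer(
    reference_embeddings: np.ndarray,
    reference_labels,
    query_embeddings: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """Majority-vote label transfer from k Euclidean nearest reference cells.

    Vote ties break by the smaller mean neighbor distance, then by label
    lexicographic order.
    """
    R = np.asarray(reference_embeddings, dtype=float)
    Q = np.asarray(query_embeddings, dtype=float)
    labels = np.asarray(reference_labels)
    if R.shape[0] == 0:
        raise ValueError("empty reference set")
    if k > R.shape[0]:
        raise ValueError(f"k={k} exceeds the number of reference cells {R.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(R)
    dist, idx = nn.kneighbors(Q)
    out = np.empty(Q.shape[0], dtype=labels.dtype)
    for i in range(Q.shape[0]):
        neigh = labels[idx[i]]
        cands = {}
        for lab, d in zip(neigh, dist[i]):
            cnt, dsum = cands.get(lab, (0, 0.0))
            cands[lab] = (cnt + 1, dsum + d)
        # sort: most votes, then smallest mean distance, then lexicographic
        best = sorted(cands.items(), key=lambda kv: (-kv[1][0], kv[1][1] / kv[1][0], str(kv[0])))[0][0]
        out[i] = best
    return out


def map_orthologs(data: LabeledMatrix, table: dict, vocab: GeneVocabulary) -> LabeledMatrix:
    """Rename genes via the ortholog table, then keep only vocabulary genes.

    The table maps source-species symbols to human symbols and must be
    injective; column order is preserved.
    """
    if not table:
        raise ValueError("empty ortholog table")
    targets = list(table.values())
    if len(set(targets)) != len(targets):
        raise ValueError("ortholog table must be one-to-one (duplicate human symbols)")
    from .syndata import relabel_species

    renamed = relabel_species(data, table)
    try:
        kept, _ = match_genes(renamed.gene_names, vocab)
    except ValueError as err:
        raise ValueError("no orthologous overlap with the model vocabulary") from err
    return renamed.subset_genes(kept)


def cluster_embeddings(
    embeddings: np.ndarray,
    resolution: float = 1.5,
    seed: int = 0,
    n_neighbors: int = 15,
    metric: str = "cosine",
) -> np.ndarray:
    """Leiden communities on a weighted kNN graph of the embedding.

    The graph uses UMAP-style connectivity weights over ``n_neighbors``
    neighbors (cosine by default, reduced automatically for tiny inputs);
    deterministic for a fixed seed.
    """
    import anndata as ad
    import igraph as ig
    import leidenalg
    import scanpy as sc

    X = np.asarray(embeddings, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("cluster_embeddings requires at least two cells")
    k = min(n_neighbors, n - 1)
    adata = ad.AnnData(X=X.astype(np.float32))
    sc.pp.neighbors(adata, n_neighbors=k, metric=metric, use_rep="X", random_state=seed)
    conn = adata.obsp["connectivities"].tocoo()
    edges, weights = [], []
    for i, j, w in zip(conn.row, conn.col, conn.data):
        if i < j:
            edges.append((int(i), int(j)))
            weights.append(float(w))
    g = ig.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=np.int64)
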