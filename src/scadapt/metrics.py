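"""Evaluation metrics: balanced accuracy, confusion matrices, clustering
dispersion (CHI), batch-integration composites, and perturbation scores.

The two integration composites summarize an embedding after batch
correction::

    AvgBIO   = (ARI + NMI + ASW_cell) / 3
    AvgBATCH = (ASW_batch + GraphConn) / 2

with every component rescaled to [0, 1].  ASW_batch follows the scIB
convention: 1 - |silhouette on batch labels|, averaged within cell-type
strata.  Graph connectivity is the per-type fraction of cells in the
largest connected component of the embedding kNN graph, averaged over
types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
    silhouette_score,
)
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "ConfusionMatrix",
    "IntegrationScores",
    "balanced_accuracy",
    "confusion",
    "chi_score",
    "integration_scores",
    "perturbation_scores",
]


def balanced_accuracy(true, predicted) -> float:
    """Mean per-class recall: (1/c) * sum_i TP_i / (TP_i + FN_i)."""
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if true.size == 0:
        raise ValueError("balanced_accuracy requires at least one label")
    if true.shape != predicted.shape:
        raise ValueError("true and predicted labels must have the same length")
    recalls = []
    for cls in np.unique(true):
        sel = true == cls
        recalls.append(np.mean(predicted[sel] == cls))
    return float(np.mean(recalls))


@dataclass
class ConfusionMatrix:
    """Counts and the row-normalized percentage view.

    Rows are annotated classes, columns predicted classes; each percentage
    row sums to 100 (rows with no support are flagged and left at 0).
    """

    classes: np.ndarray
    counts: np.ndarray
    percentages: np.ndarray
    zero_support: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.percentages, index=self.classes, columns=self.classes).to_csv(path)


def confusion(true, predicted, classes=None) -> ConfusionMatrix:
    true = np.asarray(true)
    predicted = np.asarray(predicted)
    if classes is None:
        classes = np.unique(np.concatenate([true, predicted]))
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes)}
    stray = set(true) | set(predicted)
    stray -= set(classes)
    if stray:
        raise ValueError(f"labels outside the class order: {sorted(map(str, stray))}")
    c = len(classes)
    counts = np.zeros((c, c), dtype=np.int64)
    for t, p in zip(true, predicted):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1)
    zero = support == 0
    pct = np.zeros((c, c))
    pct[~zero] = 100.0 * counts[~zero] / support[~zero, None]
    return ConfusionMatrix(classes=classes, counts=counts, percentages=pct, zero_support=zero)


def chi_score(embeddings: np.ndarray, labels) -> float:
    """Calinski–Harabasz index: between/within dispersion times (N-k)/(k-1)."""
    X = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("chi_score requires at least two labels")
    N, k = X.shape[0], len(groups)
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in groups:
        Xg = X[labels == g]
        if Xg.shape[0] < 2:
            raise ValueError(f"chi_score requires >= 2 cells per label; {g!r} has {Xg.shape[0]}")
        mu = Xg.mean(axis=0)
        between += Xg.shape[0] * np.sum((mu - grand) ** 2)
        within += np.sum((Xg - mu) ** 2)
    return float(between / within * (N - k) / (k - 1))


@dataclass
class IntegrationScores:
    nmi: float
    ari: float
    asw_cell: float
    asw_batch: float
    graph_connectivity: float
    avg_bio: float
    avg_batch: float

    def as_dict(self) -> dict:
        return {
            "NMI": self.nmi,
            "ARI": self.ari,
            "ASW_cell": self.asw_cell,
            "ASW_batch": self.asw_batch,
            "GraphConn": self.graph_connectivity,
            "AvgBIO": self.avg_bio,
            "AvgBATCH": self.avg_batch,
        }


def _graph_connectivity(X: np.ndarray, labels: np.ndarray, k: int = 15) -> float:
    fracs = []
    for g in np.unique(labels):
        Xg = X[labels == g]
        kk = min(k, Xg.shape[0] - 1)
        if kk < 1:
            fracs.append(1.0)
            continue
        graph = kneighbors_graph(Xg, n_neighbors=kk, include_self=False)
        n_comp, comp = connected_components(graph, directed=False)
        largest = np.bincount(comp).max()
        fracs.append(largest / Xg.shape[0])
    return float(np.mean(fracs))


def integration_scores(
    embeddings: np.ndarray,
    cell_types,
    batches,
    cluster_labels=None,
    seed: int = 0,
) -> IntegrationScores:
    """Biological-conservation and batch-mixing composites for an embedding.

    NMI/ARI compare ``cluster_labels`` (Leiden at resolution 1.0 on the
    embedding kNN graph, computed here when not supplied) against the cell
    type labels; silhouettes are rescaled to [0, 1].
    """
    X = np.asarray(embeddings, dtype=float)
    ct = np.asarray(cell_types)
    bt = np.asarray(batches)
    if len(np.unique(ct)) < 2 or len(np.unique(bt)) < 2:
        raise ValueError("integration_scores requires >= 2 cell types and >= 2 batches")

    if cluster_labels is None:
        from .interpret import cluster_embeddings

        # scIB convention: sweep the Leiden resolution and keep the
        # clustering that maximizes NMI against the cell-type labels
        best, best_nmi = None, -1.0
        for res in (0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0):
            lab = cluster_embeddings(X, resolution=res, seed=seed, metric="euclidean")
            score = normalized_mutual_info_score(ct, lab)
            if score > best_nmi:
                best, best_nmi = lab, score
        cluster_labels = best
    cluster_labels = np.asarray(cluster_labels)

    nmi = float(normalized_mutual_info_score(ct, cluster_labels))
    ari = float(adjusted_rand_score(ct, cluster_labels))
    ari = max(0.0, ari)  # clip the (rare) negative ARI into [0, 1]
    asw_cell = float((silhouette_score(X, ct) + 1.0) / 2.0)

    # scIB-style batch ASW: 1 - |silhouette on batch| within each type stratum
    per_type = []
    for g in np.unique(ct):
        sel = ct == g
        if len(np.unique(bt[sel])) < 2 or sel.sum() < 3:
            continue
        s = silhouette_samples(X[sel], bt[sel])
        per_type.append(np.mean(1.0 - np.abs(s)))
    if not per_type:
        raise ValueError("no cell-type stratum contains more than one batch")
    asw_batch = float(np.mean(per_type))

    gc = _graph_connectivity(X, ct)
    return IntegrationScores(
        nmi=nmi,
        ari=ari,
        asw_cell=asw_cell,
        asw_batch=asw_batch,
        graph_connectivity=gc,
        avg_bio=(ari + nmi + asw_cell) / 3.0,
        avg_batch=(asw_batch + gc) / 2.0,
    )


def perturbation_scores(
    predicted: np.ndarray,
    true: np.ndarray,
    control: np.ndarray,
    top_k: int = 20,
) -> dict:
    """PCC/MSE of mean post-perturbation profiles, plus top-k DE variants.

    The DE gene set is the ``top_k`` genes by |mean(true) - mean(control)|,
    ties broken by gene index.
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    control = np.asarray(control, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true matrices must share a shape")
    n_genes = true.shape[-1]
    if top_k > n_genes:
        raise ValueError(f"top_k={top_k} exceeds n_genes={n_genes}")

    mp = predicted.mean(axis=0)
    mt = true.mean(axis=0)
    mc = control.mean(axis=0)
    delta = np.abs(mt - mc)
    order = np.lexsort((np.arange(n_genes), -delta))
    de = np.sort(order[:top_k])

    def pcc(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "PCC": pcc(mp, mt),
        "MSE": float(np.mean((mp - mt) ** 2)),
        "DE_PCC": pcc(mp[de], mt[de]),
        "DE_MSE": float(np.mean((mp[de] - mt[de]) ** 2)),
        "de_genes": de,
    }
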