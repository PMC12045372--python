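"""Readers/writers, run configuration, and the cross-validation harness.

Expression data moves through h5ad (counts in ``X``, labels in ``obs``) or
an MTX directory (``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``); ortholog
tables are two-column TSV (source_symbol, human_symbol, header required).
``crossval_harness`` runs donor-wise k-fold evaluation — donors, never
cells, are partitioned, so query donors are always unseen — and compares
two strategies with a paired two-sided t-test across folds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .metrics import balanced_accuracy
from .syndata import LabeledMatrix

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_ortholog_table",
    "crossval_harness",
]


@dataclass
class RunConfig:
    """A fully serializable description of one run; round-trips via YAML."""

    task: str = "annotate"
    data_path: str = ""
    vocab_path: str = ""
    ortholog_path: str | None = None
    out_dir: str = "run"
    adapter: str = "lora"
    mode: str = "binned"
    n_hvg: int | None = None
    n_blocks: int = 4
    d_model: int = 64
    n_heads: int = 4
    m_bins: int = 51
    pooling: str = "cls"
    mask_ratio: float = 0.25
    initial_lr: float = 1e-3
    lr_decay: float = 0.9
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def write_expression(data: LabeledMatrix, path: str | Path) -> Path:
    """Write to h5ad, or to an MTX directory when ``path`` has no .h5ad suffix."""
    path = Path(path)
    if path.suffix == ".h5ad":
        data.to_anndata().write_h5ad(path)
        return path
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.csr_matrix(data.counts))
    pd.DataFrame({"gene": data.gene_names.astype(str)}).to_csv(path / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell": [f"cell{i}" for i in range(data.n_cells)],
            "cell_type": data.cell_type.astype(str),
            "donor": data.donor.astype(str),
            "batch": data.batch.astype(str),
            "condition": data.condition.astype(str),
        }
    ).to_csv(path / "cells.tsv", sep="\t", index=False)
    return path


def read_expression(path: str | Path) -> LabeledMatrix:
    """Load counts + labels from h5ad or an MTX directory.

    Duplicate gene names are suffix-deduplicated with a warning; an empty
    matrix is an error.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        genes = path / "genes.tsv"
        cells = path / "cells.tsv"
        missing = [p.name for p in (mtx, genes, cells) if not p.exists()]
        if missing:
            raise FileNotFoundError(f"MTX directory {path} is missing companion files: {missing}")
        counts = np.asarray(scipy.io.mmread(mtx).todense())
        if not np.issubdtype(counts.dtype, np.number):
            raise ValueError("non-numeric matrix")
        gdf = pd.read_csv(genes, sep="\t")
        cdf = pd.read_csv(cells, sep="\t")
        gene_names = gdf.iloc[:, 0].astype(str).to_numpy(dtype=object)

        def col(name: str) -> np.ndarray:
            if name in cdf.columns:
                return cdf[name].astype(str).to_numpy(dtype=object)
            return np.array(["unknown"] * counts.shape[0], dtype=object)

        data = LabeledMatrix(
            counts=np.rint(counts).astype(np.int64),
            gene_names=gene_names,
            cell_type=col("cell_type"),
            donor=col("donor"),
            batch=col("batch"),
            condition=col("condition"),
        )
    elif path.suffix == ".h5ad":
        data = LabeledMatrix.from_anndata(ad.read_h5ad(path))
    else:
        raise ValueError(f"unsupported expression path {path} (expected .h5ad or an MTX directory)")
    if data.n_cells == 0 or data.n_genes == 0:
        raise ValueError(f"empty expression matrix in {path}")
    names = data.gene_names.astype(str)
    uniq, counts_ = np.unique(names, return_counts=True)
    if (counts_ > 1).any():
        import warnings

        warnings.warn("duplicate gene names found; deduplicating with numeric suffixes")
        seen: dict[str, int] = {}
        fixed = []
        for g in names:
            k = seen.get(g, 0)
            fixed.append(g if k == 0 else f"{g}-{k}")
            seen[g] = k + 1
        data.gene_names = np.array(fixed, dtype=object)
    return data


def read_ortholog_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source_symbol, human_symbol); header required."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("ortholog table must have two columns: source_symbol, human_symbol")
    table = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if len(set(table.values())) != len(table):
        raise ValueError("ortholog table must be one-to-one")
    return table


def donor_folds(donors: np.ndarray, n_folds: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition donors (never cells) into folds; returns (ref_rows, query_rows) pairs."""
    donors = np.asarray(donors).astype(str)
    uniq = np.unique(donors)
    if uniq.size < n_folds:
        raise ValueError(f"need at least {n_folds} donors for {n_folds}-fold cross-validation, got {uniq.size}")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    groups = np.array_split(shuffled, n_folds)
    folds = []
    for g in groups:
        query = np.where(np.isin(donors, g))[0]
        ref = np.where(~np.isin(donors, g))[0]
        folds.append((ref, query))
    return folds


def crossval_harness(
    data: LabeledMatrix,
    fit_predict: Callable[[LabeledMatrix, LabeledMatrix, int], np.ndarray],
    n_folds: int = 5,
    seed: int = 0,
    baseline: Callable[[LabeledMatrix, LabeledMatrix, int], np.ndarray] | None = None,
) -> dict:
    """Donor-wise k-fold evaluation of an annotation strategy.

    ``fit_predict(reference, query, fold_seed)`` returns predicted labels
    for the query cells.  With ``baseline`` supplied, the two strategies
    are compared fold-by-fold with a paired two-sided t-test.
    """
    from scipy.stats import ttest_rel

    folds = donor_folds(data.donor, n_folds, seed=seed)
    scores, base_scores, records = [], [], []
    for f, (ref_rows, query_rows) in enumerate(folds):
        ref = data.subset_cells(ref_rows)
        query = data.subset_cells(query_rows)
        pred = fit_predict(ref, query, seed + f)
        score = balanced_accuracy(query.cell_type.astype(str), np.asarray(pred).astype(str))
        scores.append(score)
        rec = {"fold": f, "n_ref_donors": len(set(ref.donor.astype(str))), "n_query_donors": len(set(query.donor.astype(str))), "balanced_accuracy": score}
        if baseline is not None:
            bpred = baseline(ref, query, seed + f)
            bscore = balanced_accuracy(query.cell_type.astype(str), np.asarray(bpred).astype(str))
            base_scores.append(bscore)
            rec["baseline_balanced_accuracy"] = bscore
        records.append(rec)
    result = {
        "folds": records,
        "mean": float(np.mean(scores)),
        "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
    }
    if baseline is not None:
        result["baseline_mean"] = float(np.mean(base_scores))
        diff = np.asarray(scores) - np.asarray(base_scores)
        if np.allclose(diff, 0):
            result["paired_t_p"] = 1.0
        else:
            result["paired_t_p"] = float(ttest_rel(scores, base_scores).pvalue)
    return result
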