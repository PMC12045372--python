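"""Synthetic single-cell count data with known structure.

Generates labeled cell x gene count matrices carrying the statistical
features the rest of the package assumes: cell-type-specific gene programs,
donor and batch structure, condition shifts on chosen gene sets, paired
perturbation responses, and cross-species gene renames.  Counts follow a
negative-binomial noise model (mean ``mu``, dispersion ``theta``, variance
``mu + mu**2/theta``) with log-normal multiplicative batch effects on gene
means — count-like non-negative data, which is all downstream operations
require.

Everything is driven by an explicit seed: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "LabeledMatrix",
    "PerturbationPairs",
    "simulate_profiles",
    "apply_condition_shift",
    "simulate_perturbation",
    "relabel_species",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative model for one simulated dataset.

    ``program_log_fold`` is the natural-log elevation of a cell type's
    program genes over the shared baseline; ``batch_log_fold`` is the
    standard deviation of the per-(batch, gene) log-normal shift;
    ``nb_dispersion`` is the negative-binomial ``theta`` (larger = closer to
    Poisson); ``library_size_mean`` is the expected total counts per cell.
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_cell_types: int = 4
    n_donors: int = 6
    n_batches: int = 2
    program_size: int = 10
    program_log_fold: float = 1.0
    batch_log_fold: float = 0.3
    nb_dispersion: float = 2.0
    library_size_mean: float = 2500.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_cell_types", "n_donors", "n_batches", "program_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"SyntheticSpec.{name} must be >= 1, got {getattr(self, name)}")
        if self.program_size * self.n_cell_types > self.n_genes:
            raise ValueError(
                "SyntheticSpec: program_size * n_cell_types "
                f"({self.program_size * self.n_cell_types}) exceeds n_genes ({self.n_genes})"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("SyntheticSpec.nb_dispersion must be > 0")
        if self.library_size_mean <= 0:
            raise ValueError("SyntheticSpec.library_size_mean must be > 0")


@dataclass
class LabeledMatrix:
    """A cell x gene count matrix with per-cell labels.

    ``mean_`` optionally carries the simulator's latent negative-binomial
    mean matrix (same shape as ``counts``); operations that need to resample
    counts use it when present and fall back to per-cell-type empirical gene
    means otherwise.
    """

    counts: np.ndarray
    gene_names: np.ndarray
    cell_type: np.ndarray
    donor: np.ndarray
    batch: np.ndarray
    condition: np.ndarray
    mean_: np.ndarray | None = field(default=None, repr=False)
    nb_dispersion: float = 2.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cell x gene matrix")
        if not np.isfinite(self.counts).all() or (self.counts < 0).any():
            raise ValueError("counts must be finite and non-negative")
        n, g = self.counts.shape
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.gene_names.shape[0] != g:
            raise ValueError("gene_names length must equal n_genes")
        for name in ("cell_type", "donor", "batch", "condition"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length must equal n_cells")
            setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(
            counts=self.counts.copy(),
            gene_names=self.gene_names.copy(),
            cell_type=self.cell_type.copy(),
            donor=self.donor.copy(),
            batch=self.batch.copy(),
            condition=self.condition.copy(),
            mean_=None if self.mean_ is None else self.mean_.copy(),
            nb_dispersion=self.nb_dispersion,
        )

    def subset_cells(self, idx: np.ndarray) -> "LabeledMatrix":
        return LabeledMatrix(
            counts=self.counts[idx],
            gene_names=self.gene_names,
            cell_type=self.cell_type[idx],
            donor=self.donor[idx],
            batch=self.batch[idx],
            condition=self.condition[idx],
            mean_=None if self.mean_ is None else self.mean_[idx],
            nb_dispersion=self.nb_dispersion,
        )

    def subset_genes(self, idx: np.ndarray) -> "LabeledMatrix":
        return LabeledMatrix(
            counts=self.counts[:, idx],
            gene_names=self.gene_names[idx],
            cell_type=self.cell_type,
            donor=self.donor,
            batch=self.batch,
            condition=self.condition,
            mean_=None if self.mean_ is None else self.mean_[:, idx],
            nb_dispersion=self.nb_dispersion,
        )

    # ---------------------------------------------------------------- anndata
    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {
                "cell_type": pd.Categorical(self.cell_type.astype(str)),
                "donor": pd.Categorical(self.donor.astype(str)),
                "batch": pd.Categorical(self.batch.astype(str)),
                "condition": pd.Categorical(self.condition.astype(str)),
            },
            index=[f"cell{i}" for i in range(self.n_cells)],
        )
        var = pd.DataFrame(index=self.gene_names.astype(str))
        return ad.AnnData(X=self.counts.astype(np.float32), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "LabeledMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        X = np.asarray(X)

        def col(name: str) -> np.ndarray:
            if name in adata.obs:
                return adata.obs[name].astype(str).to_numpy(dtype=object)
            return np.array(["unknown"] * adata.n_obs, dtype=object)

        return cls(
            counts=np.rint(X).astype(np.int64),
            gene_names=adata.var_names.to_numpy(dtype=object),
            cell_type=col("cell_type"),
            donor=col("donor"),
            batch=col("batch"),
            condition=col("condition"),
        )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial via the Gamma–Poisson mixture (var = mu + mu^2/theta)."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam).astype(np.int64)


def simulate_profiles(spec: SyntheticSpec) -> LabeledMatrix:
    """Draw a labeled count matrix from the generative model in ``spec``.

    Gene baseline means are log-normal across genes; each cell type elevates
    its own disjoint block of ``program_size`` genes by
    ``exp(program_log_fold)``; each batch multiplies every gene mean by a
    log-normal factor with scale ``batch_log_fold``; per-cell means are
    rescaled so the expected library size is ``library_size_mean``.  Cell
    types are assigned in contiguous equal blocks; donors and batches
    round-robin within each cell type so holdouts stay stratified.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes

    base = np.exp(rng.normal(loc=0.0, scale=1.0, size=g))  # relative gene means

    # labels: contiguous type blocks, round-robin donors/batches within type
    cell_type = np.empty(n, dtype=object)
    donor = np.empty(n, dtype=object)
    batch = np.empty(n, dtype=object)
    type_of = np.repeat(np.arange(spec.n_cell_types), int(np.ceil(n / spec.n_cell_types)))[:n]
    for t in range(spec.n_cell_types):
        idx = np.where(type_of == t)[0]
        cell_type[idx] = f"type{t}"
        donor[idx] = [f"donor{i % spec.n_donors}" for i in range(idx.size)]
        batch[idx] = [f"batch{i % spec.n_batches}" for i in range(idx.size)]

    programs = {t: np.arange(t * spec.program_size, (t + 1) * spec.program_size) for t in range(spec.n_cell_types)}
    batch_factor = np.exp(rng.normal(0.0, spec.batch_log_fold, size=(spec.n_batches, g)))

    mean = np.tile(base, (n, 1))
    for t, genes in programs.items():
        rows = np.where(type_of == t)[0]
        mean[np.ix_(rows, genes)] *= np.exp(spec.program_log_fold)
    batch_idx = np.array([int(str(b)[5:]) for b in batch])
    mean *= batch_factor[batch_idx]

    lib = rng.lognormal(mean=0.0, sigma=0.2, size=n) * spec.library_size_mean
    mean *= (lib / mean.sum(axis=1))[:, None]

    counts = _nb_sample(rng, mean, spec.nb_dispersion)
    return LabeledMatrix(
        counts=counts,
        gene_names=np.array([f"G{j}" for j in range(g)], dtype=object),
        cell_type=cell_type,
        donor=donor,
        batch=batch,
        condition=np.array(["ctrl"] * n, dtype=object),
        mean_=mean,
        nb_dispersion=spec.nb_dispersion,
    )


def apply_condition_shift(
    data: LabeledMatrix,
    shifted_genes: Sequence[str],
    log_fold: float,
    target_types: Sequence[str],
    seed: int = 0,
) -> LabeledMatrix:
    """Resample chosen genes in chosen cell types with means scaled by exp(log_fold).

    Models a condition/disease shift: counts of ``shifted_genes`` in cells of
    ``target_types`` are redrawn from the negative binomial with the latent
    mean multiplied by ``exp(log_fold)``; every other entry is returned
    bit-identical.
    """
    shifted_genes = list(shifted_genes)
    target_types = list(target_types)
    name_to_col = {g: j for j, g in enumerate(data.gene_names)}
    unknown_genes = [g for g in shifted_genes if g not in name_to_col]
    unknown_types = [t for t in target_types if t not in set(data.cell_type)]
    if unknown_genes or unknown_types:
        raise ValueError(
            f"apply_condition_shift: unknown genes {unknown_genes}, unknown cell types {unknown_types}"
        )
    out = data.copy()
    if not shifted_genes:
        return out

    rng = np.random.default_rng(seed)
    cols = np.array([name_to_col[g] for g in shifted_genes])
    rows = np.where(np.isin(data.cell_type, target_types))[0]
    if rows.size == 0:
        return out

    if data.mean_ is not None:
        base_mean = data.mean_[np.ix_(rows, cols)]
    else:
        # empirical fallback: per-cell-type gene means
        base_mean = np.empty((rows.size, cols.size))
        for t in set(data.cell_type[rows]):
            sel = data.cell_type[rows] == t
            type_mean = data.counts[data.cell_type == t][:, cols].mean(axis=0)
            base_mean[sel] = type_mean
    new_mean = base_mean * np.exp(log_fold)
    out.counts[np.ix_(rows, cols)] = _nb_sample(rng, new_mean, data.nb_dispersion)
    if out.mean_ is not None:
        out.mean_[np.ix_(rows, cols)] = new_mean
    out.condition[rows] = "shifted"
    return out


@dataclass
class PerturbationPairs:
    """Paired control/perturbed profiles on the log1p-normalized scale.

    ``control_log1p[i]`` is the model input; ``perturbed_log1p[i]`` is the
    post-perturbation profile of a randomly paired cell of the same type.
    ``condition_tokens`` is the binary per-gene perturbation indicator
    (1 at the perturbed gene).  ``source_index`` records which cell each
    perturbed profile was generated from, for diagnostics.
    """

    control_log1p: np.ndarray
    perturbed_log1p: np.ndarray
    condition_tokens: np.ndarray
    gene_names: np.ndarray
    cell_type: np.ndarray
    target_gene: str
    source_index: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.control_log1p.shape[0]


def _log1p_normalize(counts: np.ndarray, total: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * total)


def simulate_perturbation(
    data: LabeledMatrix,
    target_gene: str,
    effect: np.ndarray,
    n_pairs: int,
    seed: int = 0,
    noise_sigma: float = 0.1,
) -> PerturbationPairs:
    """Build randomly paired control/perturbed cells for one perturbed gene.

    Perturbed profiles are unperturbed cells whose log1p-normalized
    expression is shifted by the per-gene ``effect`` vector plus Gaussian
    noise (sigma ``noise_sigma``); each control cell is paired with a
    perturbed cell of the same cell type.
    """
    if target_gene not in set(data.gene_names):
        raise ValueError(f"simulate_perturbation: unknown target gene {target_gene!r}")
    effect = np.asarray(effect, dtype=float)
    if effect.shape != (data.n_genes,):
        raise ValueError(f"effect must have length n_genes={data.n_genes}, got {effect.shape}")

    rng = np.random.default_rng(seed)
    log1p = _log1p_normalize(data.counts)

    types, counts_per_type = np.unique(data.cell_type.astype(str), return_counts=True)
    # draw pairs proportionally across types; both mates of a pair share a type
    per_type = np.maximum(1, np.round(n_pairs * counts_per_type / counts_per_type.sum()).astype(int))
    while per_type.sum() > n_pairs:
        per_type[np.argmax(per_type)] -= 1
    while per_type.sum() < n_pairs:
        per_type[np.argmax(counts_per_type - 2 * per_type)] += 1

    ctrl_rows, pert_rows = [], []
    for t, k in zip(types, per_type):
        pool = np.where(data.cell_type.astype(str) == t)[0]
        if k > pool.size:
            raise ValueError(
                f"n_pairs requires {k} cells of type {t!r} but only {pool.size} are available"
            )
        ctrl_rows.append(rng.choice(pool, size=k, replace=False))
        pert_rows.append(rng.choice(pool, size=k, replace=False))
    ctrl_rows = np.concatenate(ctrl_rows)
    pert_rows = np.concatenate(pert_rows)

    noise = rng.normal(0.0, noise_sigma, size=(pert_rows.size, data.n_genes)) if noise_sigma > 0 else 0.0
    perturbed = log1p[pert_rows] + effect[None, :] + noise

    tokens = np.zeros(data.n_genes, dtype=np.int64)
    tokens[np.where(data.gene_names == target_gene)[0][0]] = 1

    return PerturbationPairs(
        control_log1p=log1p[ctrl_rows],
        perturbed_log1p=perturbed,
        condition_tokens=tokens,
        gene_names=data.gene_names.copy(),
        cell_type=data.cell_type[ctrl_rows].copy(),
        target_gene=target_gene,
        source_index=pert_rows,
    )


def relabel_species(data: LabeledMatrix, orthologs: Mapping[str, str]) -> LabeledMatrix:
    """Rename genes via a one-to-one ortholog table (source -> human symbol).

    Genes without an ortholog keep their source name (vocabulary matching
    drops them later).  Raises if the renaming would create duplicate
    symbols.
    """
    out = data.copy()
    new_names = np.array([orthologs.get(g, g) for g in data.gene_names], dtype=object)
    uniq, counts = np.unique(new_names.astype(str), return_counts=True)
    dups = uniq[counts > 1]
    if dups.size:
        raise ValueError(f"relabel_species: duplicate gene symbols after renaming: {list(dups)}")
    out.gene_names = new_names
    return out
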