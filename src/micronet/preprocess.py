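"""Bulk expression preprocessing.

Takes a gene x sample FPKM table through the normalization route used for
module/trait analyses: quantile normalization across samples, per-gene
location/scale batch adjustment, an expression floor (mean FPKM > 1),
log2 transformation, per-gene covariate residualization, and finally the
per-module *meta-feature*: the mean of gene-wise z-scores over a module's
members, one value per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ModuleAssignment",
    "quantile_normalize",
    "adjust_batch",
    "filter_genes",
    "log2_transform",
    "residualize",
    "build_design",
    "meta_feature",
    "module_scores",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample abundance matrix with a unit tag.

    ``values`` is a pandas DataFrame with gene ids as the index and sample
    ids as columns. ``unit`` is one of ``fpkm``, ``log2``, ``residual``,
    ``zscore``.
    """

    values: pd.DataFrame
    unit: str = "fpkm"

    _UNITS = ("fpkm", "log2", "residual", "zscore")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {self._UNITS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.unit == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, unit: str = "fpkm") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), unit=unit)


@dataclass(frozen=True)
class ModuleAssignment:
    """Partition of genes into named co-expression modules.

    Module discovery itself is upstream of this package: assignments are
    consumed as an input (gene, module) table.
    """

    mapping: pd.Series  # index: gene_id, values: module_id

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            raise ValueError("a gene may belong to at most one module")

    @property
    def module_ids(self) -> list[str]:
        return sorted(self.mapping.unique().tolist())

    def genes(self, module_id: str) -> list[str]:
        genes = self.mapping.index[self.mapping == module_id].tolist()
        if not genes:
            raise KeyError(f"module {module_id!r} not present in assignment")
        return genes

    def sizes(self) -> pd.Series:
        return self.mapping.value_counts().sort_index()

    def analysis_modules(self, min_size: int = 20) -> list[str]:
        """Module ids with at least ``min_size`` genes (the analysis floor)."""
        sizes = self.sizes()
        return sizes.index[sizes >= min_size].tolist()

    def to_tsv(self, path) -> None:
        frame = self.mapping.rename("module_id").rename_axis("gene_id").reset_index()
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModuleAssignment":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.set_index("gene_id")["module_id"])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile profile.

    After normalization the sorted values of each column equal the
    across-column mean of sorted values. Ties within a column receive the
    mean of the reference values spanning their tied ranks, which keeps the
    operation idempotent.
    """
    x = m.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = reference.copy()
        # average the reference over each run of tied input values
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    assigned[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = assigned
    frame = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    return replace(m, values=frame)


def adjust_batch(m: ExpressionMatrix, batches) -> ExpressionMatrix:
    """Per-gene location/scale batch adjustment.

    Each batch is re-centered and re-scaled, gene by gene, to the pooled
    gene mean and standard deviation. This is the location/scale core of
    batch correction without empirical-Bayes shrinkage of the batch
    parameters.
    """
    batches = pd.Series(np.asarray(batches), index=m.sample_ids)
    levels = batches.unique()
    if len(levels) < 2:
        raise ValueError("batch adjustment requires at least 2 batches")
    counts = batches.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"batches with fewer than 3 samples: {small.index.tolist()}")
    x = m.values.to_numpy(dtype=float)
    pooled_mean = x.mean(axis=1, keepdims=True)
    pooled_sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(x)
    for level in levels:
        idx = np.flatnonzero((batches == level).to_numpy())
        sub = x[:, idx]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        scale = np.divide(pooled_sd, sd, out=np.ones_like(sd), where=sd > 0)
        out[:, idx] = (sub - mu) * scale + pooled_mean
    frame = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    return replace(m, values=frame)


def filter_genes(m: ExpressionMatrix, min_mean: float = 1.0) -> ExpressionMatrix:
    """Keep genes with mean FPKM strictly greater than ``min_mean``."""
    if m.unit != "fpkm":
        raise ValueError("expression floor is defined on the FPKM scale")
    keep = m.values.mean(axis=1) > min_mean
    if not keep.any():
        warnings.warn("no genes pass the expression floor", stacklevel=2)
    return replace(m, values=m.values.loc[keep])


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + offset); the offset keeps zeros finite."""
    if m.unit != "fpkm":
        raise ValueError("log2 transform expects FPKM input")
    return ExpressionMatrix(np.log2(m.values + offset), unit="log2")


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand a covariate table into a numeric design matrix (no intercept).

    Numeric and boolean columns pass through; categorical/object columns are
    expanded into 0/1 indicators with the first level as reference.
    """
    if covariates.shape[1] == 0:
        return pd.DataFrame(index=covariates.index)
    pieces = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            pieces.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            pieces.append(dummies)
    return pd.concat(pieces, axis=1)


def residualize(m: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Remove covariate effects gene by gene with ordinary least squares.

    The design always includes an intercept; each output gene is orthogonal
    to every covariate column. Input is expected on the log2 scale.
    """
    if m.unit != "log2":
        raise ValueError("residualize expects log2 input")
    if not m.sample_ids.equals(pd.Index(covariates.index)):
        covariates = covariates.loc[m.sample_ids]
    design = build_design(covariates)
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    names = ["intercept", *design.columns]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad, cols = [], [X[:, 0]]
        for j in range(1, X.shape[1]):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(X[:, j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    Y = m.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    frame = pd.DataFrame(resid.T, index=m.gene_ids, columns=m.sample_ids)
    return ExpressionMatrix(frame, unit="residual")


# ---------------------------------------------------------------------------
# module meta-features
# ---------------------------------------------------------------------------

def meta_feature(m: ExpressionMatrix, assignment: ModuleAssignment, module_id: str) -> pd.Series:
    """Per-sample module activity: mean of gene-wise z-scores over the module.

    Genes are standardized across samples (ddof=1) before averaging, so every
    gene contributes equally regardless of its expression scale. Genes with
    zero variance carry no signal and are excluded with a warning.
    """
    genes = [g for g in assignment.genes(module_id) if g in m.gene_ids]
    if not genes:
        raise KeyError(f"module {module_id!r} has no genes present in the matrix")
    sub = m.values.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"module {module_id}: excluded {int((~keep).sum())} zero-variance genes",
            stacklevel=2,
        )
        sub, sd = sub[keep], sd[keep]
        if sub.shape[0] == 0:
            raise ValueError(f"module {module_id!r}: all genes have zero variance")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(z.mean(axis=0), index=m.sample_ids, name=module_id)


def module_scores(
    m: ExpressionMatrix,
    assignment: ModuleAssignment,
    module_ids=None,
    min_size: int = 1,
) -> pd.DataFrame:
    """Meta-features for several modules at once: samples x modules."""
    if module_ids is None:
        module_ids = [
            mod
            for mod in assignment.module_ids
            if sum(g in m.gene_ids for g in assignment.genes(mod)) >= min_size
        ]
    return pd.DataFrame({mod: meta_feature(m, assignment, mod) for mod in module_ids})
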