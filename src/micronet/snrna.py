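"""Single-nucleus validation of module expression programs.

Raw nuclear counts are normalized to counts-per-million per cell, module
scores are the mean CPM over a module's detected genes (no per-gene
z-scoring at single-cell resolution), microglial cluster membership is
summarized as per-subject proportions over the four microglial clusters,
and a cluster's proportion is related to a pathology trait with a Huber
robust linear model (sex and PMI as covariates), which protects the
small-cohort fit from single-subject leverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .association import AssociationResult

__all__ = [
    "SnCountMatrix",
    "cpm",
    "cell_module_score",
    "cluster_proportions",
    "proportion_trait_assoc",
]

logger = logging.getLogger(__name__)


@dataclass
class SnCountMatrix:
    """Sparse cells x genes integer counts with per-cell metadata.

    ``metadata`` is indexed by cell id and carries ``subject_id`` and
    ``cluster`` columns.
    """

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("counts shape does not match cell/gene ids")
        data = self.counts.data
        if len(data) and ((data < 0).any() or not np.allclose(data, np.round(data))):
            raise ValueError("counts must be nonnegative integers")
        missing = {"subject_id", "cluster"} - set(self.metadata.columns)
        if missing:
            raise ValueError(f"cell metadata missing columns: {sorted(missing)}")
        if not self.metadata.index.equals(self.cell_ids):
            self.metadata = self.metadata.loc[self.cell_ids]

    def write(self, mtx_path, genes_path, cells_path, metadata_path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), self.counts)
        pd.Series(self.gene_ids).to_csv(genes_path, sep="\t", index=False, header=["gene_id"])
        pd.Series(self.cell_ids).to_csv(cells_path, sep="\t", index=False, header=["cell_id"])
        self.metadata.rename_axis("cell_id").to_csv(metadata_path)

    @classmethod
    def read(cls, mtx_path, genes_path, cells_path, metadata_path) -> "SnCountMatrix":
        from scipy.io import mmread

        counts = sp.csr_matrix(mmread(str(mtx_path)))
        genes = pd.read_csv(genes_path, sep="\t")["gene_id"]
        cells = pd.read_csv(cells_path, sep="\t")["cell_id"]
        metadata = pd.read_csv(metadata_path, index_col="cell_id")
        return cls(counts, pd.Index(cells), pd.Index(genes), metadata)


def cpm(counts: SnCountMatrix) -> pd.DataFrame:
    """Counts-per-million per cell; zero-total cells are dropped with a warning."""
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        logger.warning("dropped %d cells with zero total counts", int((~keep).sum()))
    mat = counts.counts[keep].astype(float)
    scaled = sp.diags(1e6 / totals[keep]) @ mat
    return pd.DataFrame(
        scaled.toarray(), index=counts.cell_ids[keep], columns=counts.gene_ids
    )


def cell_module_score(cpm_matrix: pd.DataFrame, assignment, module_id: str) -> pd.Series:
    """Mean CPM over a module's genes detected in the matrix, per cell."""
    genes = [g for g in assignment.genes(module_id) if g in cpm_matrix.columns]
    if not genes:
        raise ValueError(f"no genes of module {module_id!r} present in the matrix")
    return cpm_matrix[genes].mean(axis=1).rename(module_id)


def cluster_proportions(metadata: pd.DataFrame, clusters) -> pd.DataFrame:
    """Per-subject cell proportions over a fixed cluster subset.

    Each subject's counts over the listed clusters are normalized to sum to
    1; subjects with no cells in the subset are excluded with a warning.
    """
    clusters = list(clusters)
    sub = metadata[metadata["cluster"].isin(clusters)]
    counts = (
        sub.groupby(["subject_id", "cluster"], observed=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=clusters, fill_value=0)
    excluded = set(metadata["subject_id"].unique()) - set(counts.index)
    if excluded:
        logger.warning("excluded %d subjects with no cells in the subset", len(excluded))
    return counts.div(counts.sum(axis=1), axis=0)


def proportion_trait_assoc(
    proportions: pd.Series,
    trait: str,
    phen: pd.DataFrame,
    covariates=("sex", "pmi"),
    min_subjects: int = 10,
) -> AssociationResult:
    """Huber robust regression of a trait on one cluster's proportion.

    trait ~ proportion + covariates, M-estimated with the Huber psi at
    tuning constant 1.345 (95% Gaussian efficiency); returns the
    proportion term's coefficient, robust SE, and normal-approximation p.
    """
    name = proportions.name or "proportion"
    data = phen.loc[:, [trait, *covariates]].copy()
    data[name] = proportions.reindex(phen.index)
    data = data.dropna().astype(float)
    if len(data) < min_subjects:
        raise ValueError(f"need at least {min_subjects} subjects")
    if data[name].nunique() < 2:
        raise ValueError("constant proportions")
    exog = sm.add_constant(data[[name, *covariates]])
    fit = sm.RLM(data[trait], exog, M=sm.robust.norms.HuberT(t=1.345)).fit()
    return AssociationResult(
        predictor=name,
        trait=trait,
        beta=float(fit.params[name]),
        se=float(fit.bse[name]),
        t=float(fit.tvalues[name]),
        p=float(fit.pvalues[name]),
        n=len(data),
        covariates=tuple(covariates),
        model="huber_rlm",
    )
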