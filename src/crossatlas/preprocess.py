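"""Quality-control filtering, log-normalization and per-cluster pseudobulk profiles.

The default thresholds follow the common droplet-scRNA-seq workflow for plant
root atlases: cells kept with 500-6000 detected genes (inclusive), 500-40,000
total UMIs (inclusive) and at most 10% mitochondrial UMIs; genes kept when
expressed in at least three surviving cells.  Normalization is the standard
LogNormalize: ``ln(1 + count / cell_total * scale)`` with scale 10,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError, log_stage, warn_unmatched_annotation

__all__ = [
    "QCThresholds",
    "NormalizedMatrix",
    "ClusterProfile",
    "qc_filter",
    "lognormalize",
    "average_by_cluster",
]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive cell-level bounds plus the minimum gene prevalence.

    ``max_mito_fraction`` is vacuous when no mitochondrial genes are supplied.
    """

    min_genes: int = 500
    max_genes: int = 6000
    min_umi: int = 500
    max_umi: int = 40_000
    max_mito_fraction: float = 0.10
    min_cells_per_gene: int = 3


@dataclass
class NormalizedMatrix:
    """Cells x genes log-normalized expression with provenance."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: sp.csr_matrix  # cells x genes, float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.tocsr()
        if not np.all(np.isfinite(self.values.data)):
            raise ValidationError("non-finite normalized value encountered")


@dataclass
class ClusterProfile:
    """Cluster x gene matrix of mean expression plus per-cluster cell counts."""

    values: pd.DataFrame  # clusters (lexicographic) x genes
    n_cells: pd.Series
    space: str = "log"  # "log": mean of log values; "delog": mean of expm1 values

    def __post_init__(self) -> None:
        if (self.n_cells < 1).any():
            raise ValidationError("retained cluster with zero cells")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative value in cluster profile")


def qc_filter(
    matrix: CountMatrix,
    mito_gene_ids: set[str] | frozenset[str] = frozenset(),
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, dict]:
    """Apply cell-level QC criteria, then drop low-prevalence genes.

    Cells failing any criterion are removed first; genes expressed in fewer
    than ``min_cells_per_gene`` *surviving* cells are removed second.  The
    report counts cells failing each criterion independently (a cell may fail
    several).
    """
    thr = thresholds or QCThresholds()
    X = matrix.counts
    n_cells, n_genes = X.shape

    genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    umi_per_cell = np.asarray(X.sum(axis=1)).ravel()
    mito_idx = [i for i, g in enumerate(matrix.gene_ids) if g in mito_gene_ids]
    if mito_idx:
        mito_umi = np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(umi_per_cell > 0, mito_umi / np.maximum(umi_per_cell, 1), 0.0)
    else:
        mito_frac = np.zeros(n_cells)

    fail_genes = (genes_per_cell < thr.min_genes) | (genes_per_cell > thr.max_genes)
    fail_umi = (umi_per_cell < thr.min_umi) | (umi_per_cell > thr.max_umi)
    fail_mito = mito_frac > thr.max_mito_fraction
    keep_cells = ~(fail_genes | fail_umi | fail_mito)
    if not keep_cells.any():
        raise ValidationError("QC removed every cell (empty atlas)")

    sub = X[keep_cells]
    prevalence = np.asarray((sub > 0).sum(axis=0)).ravel()
    keep_genes = prevalence >= thr.min_cells_per_gene

    report = {
        "n_cells_in": int(n_cells),
        "n_genes_in": int(n_genes),
        "cells_failing_gene_bounds": int(fail_genes.sum()),
        "cells_failing_umi_bounds": int(fail_umi.sum()),
        "cells_failing_mito": int(fail_mito.sum()),
        "cells_removed": int((~keep_cells).sum()),
        "genes_removed": int((~keep_genes).sum()),
        "n_cells_out": int(keep_cells.sum()),
        "n_genes_out": int(keep_genes.sum()),
    }
    out = CountMatrix(
        species_id=matrix.species_id,
        cell_ids=[c for c, k in zip(matrix.cell_ids, keep_cells) if k],
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep_genes) if k],
        counts=sub[:, keep_genes],
    )
    log_stage("qc_filter", species=matrix.species_id, **report)
    return out, report


def lognormalize(matrix: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """LogNormalize: ``ln(1 + count / cell_total * scale)``.

    Zero counts map to zero exactly (the sparsity pattern is preserved).
    """
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(matrix.cell_ids, zero) if z]
        raise ValidationError(f"cell(s) with zero total count: {bad[:5]}")
    values = matrix.counts.astype(np.float64).tocsr()
    row_scale = scale / totals
    values.data *= np.repeat(row_scale, np.diff(values.indptr))
    np.log1p(values.data, out=values.data)
    return NormalizedMatrix(
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        values=values,
        provenance={"method": "LogNormalize", "scale_factor": scale, "log_base": "e"},
    )


def average_by_cluster(
    norm: NormalizedMatrix,
    ann: pd.DataFrame,
    space: str = "log",
) -> ClusterProfile:
    """Per-cluster arithmetic mean expression (pseudobulk), clusters sorted lexicographically.

    ``space='log'`` averages the log-normalized values directly; ``space='delog'``
    averages the de-logged values (``expm1``) and returns the linear-scale mean,
    matching the convention of common single-cell toolkits.  Both are monotone
    per gene, which is what the downstream rank-based specificity transform
    depends on.
    """
    if space not in ("log", "delog"):
        raise ValueError(f"space must be 'log' or 'delog', got {space!r}")
    warn_unmatched_annotation(ann, norm.cell_ids)
    label_of = dict(zip(ann["cell_id"], ann["cluster_label"]))
    missing = [c for c in norm.cell_ids if c not in label_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} cell(s) without a cluster label, e.g. {missing[:5]}"
        )
    labels = np.array([label_of[c] for c in norm.cell_ids])
    clusters = sorted(set(labels))
    V = norm.values
    if space == "delog":
        V = V.copy()
        np.expm1(V.data, out=V.data)
    rows = []
    counts = []
    for cl in clusters:
        mask = labels == cl
        counts.append(int(mask.sum()))
        rows.append(np.asarray(V[mask].mean(axis=0)).ravel())
    values = pd.DataFrame(rows, index=pd.Index(clusters, name="cluster"), columns=norm.gene_ids)
    profile = ClusterProfile(
        values=values,
        n_cells=pd.Series(counts, index=values.index, name="n_cells"),
        space=space,
    )
    log_stage("average_by_cluster", clusters=len(clusters), genes=values.shape[1], space=space)
    return profile
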