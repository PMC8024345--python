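"""Cluster-enriched genes, cluster-specific markers, conserved markers and gene modules.

The enrichment test is the one-vs-rest two-sided Wilcoxon rank-sum test on
log-normalized expression, restricted to genes detected in at least a minimum
fraction of either group and with an absolute log2 fold-change above a
threshold.  Fold changes are computed on de-logged group means with a
pseudocount of 1.  For small groups (both sides <= 8 cells) the p-value is an
exact tie-aware enumeration over all group assignments; larger groups use the
normal approximation with tie correction and continuity correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, log_stage
from .preprocess import NormalizedMatrix

__all__ = [
    "ranksum_pvalue",
    "cluster_enriched_genes",
    "cluster_specific_markers",
    "conserved_markers",
    "GeneModuleAssignment",
    "kmeans_modules",
    "conserved_gene_profiles",
]

MARKER_COLUMNS = ["cluster_label", "gene_id", "log2fc", "pct1", "pct2", "p_value", "p_adjusted"]

_EXACT_MAX = 8  # exact enumeration when both groups are at most this large


def ranksum_pvalue(x, y, exact_max: int = _EXACT_MAX) -> float:
    """Two-sided Wilcoxon rank-sum p-value with mid-ranks for ties.

    For ``len(x) <= exact_max`` and ``len(y) <= exact_max`` the p-value is the
    exact fraction of group assignments whose rank-sum deviates from its mean
    at least as much as the observed one.  Otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("rank-sum test requires non-empty groups")
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(w - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            ws = ranks[list(idx)].sum()
            total += 1
            if abs(ws - mu) >= dev - 1e-9:
                count += 1
        return count / total
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values tied
        return 1.0
    d = w - mu
    d -= np.sign(d) * 0.5  # continuity correction
    z = d / math.sqrt(sigma2)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def cluster_enriched_genes(
    norm: NormalizedMatrix,
    ann: pd.DataFrame,
    logfc_threshold: float = 0.58,
    min_fraction: float = 0.1,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest enrichment test per cluster.

    A gene is tested for a cluster when it is detected in at least
    ``min_fraction`` of cells in either the cluster or the rest (the usual
    ``min.pct`` semantics) *and* its absolute log2 fold-change — de-logged
    group means with pseudocount 1 — exceeds ``logfc_threshold``.  P-values
    are adjusted by Bonferroni (default) or Benjamini-Hochberg over the genes
    tested within each cluster comparison.
    """
    if adjust not in ("bonferroni", "bh"):
        raise ValueError(f"adjust must be 'bonferroni' or 'bh', got {adjust!r}")
    label_of = dict(zip(ann["cell_id"], ann["cluster_label"]))
    missing = [c for c in norm.cell_ids if c not in label_of]
    if missing:
        raise ValidationError(f"{len(missing)} cell(s) without a cluster label")
    labels = np.array([label_of[c] for c in norm.cell_ids])
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValidationError("enrichment test requires at least two clusters")

    X = np.asarray(norm.values.todense())
    expressed = X > 0
    E = np.expm1(X)
    records: list[dict] = []
    for cl in clusters:
        mask = labels == cl
        n_in = int(mask.sum())
        if n_in < 2:
            warnings.warn(f"cluster {cl!r} has fewer than 2 cells; skipped", stacklevel=2)
            continue
        pct1 = expressed[mask].mean(axis=0)
        pct2 = expressed[~mask].mean(axis=0)
        m_in = E[mask].mean(axis=0)
        m_out = E[~mask].mean(axis=0)
        log2fc = np.log2((m_in + 1.0) / (m_out + 1.0))
        tested = ((pct1 >= min_fraction) | (pct2 >= min_fraction)) & (
            np.abs(log2fc) > logfc_threshold
        )
        idx = np.where(tested)[0]
        pvals = np.array([ranksum_pvalue(X[mask, g], X[~mask, g]) for g in idx])
        if adjust == "bonferroni":
            padj = np.minimum(1.0, pvals * len(idx))
        else:
            from statsmodels.stats.multitest import multipletests

            padj = multipletests(pvals, method="fdr_bh")[1] if len(idx) else pvals
        for j, g in enumerate(idx):
            records.append(
                {
                    "cluster_label": cl,
                    "gene_id": norm.gene_ids[g],
                    "log2fc": float(log2fc[g]),
                    "pct1": float(pct1[g]),
                    "pct2": float(pct2[g]),
                    "p_value": float(pvals[j]),
                    "p_adjusted": float(padj[j]),
                }
            )
    out = pd.DataFrame(records, columns=MARKER_COLUMNS)
    log_stage("cluster_enriched_genes", clusters=len(clusters), records=len(out))
    return out


def cluster_specific_markers(
    records: pd.DataFrame,
    min_log2fc: float = 0.25,
    max_pct2: float = 0.10,
) -> pd.DataFrame:
    """Cluster-specific marker rule: log2FC > ``min_log2fc`` AND pct2 < ``max_pct2`` (both strict)."""
    if len(records) == 0:
        return records.copy()
    keep = (records["log2fc"] > min_log2fc) & (records["pct2"] < max_pct2)
    return records[keep].reset_index(drop=True)


def conserved_markers(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    cluster_pairing: dict[str, str],
    clusters_a=None,
    clusters_b=None,
) -> pd.DataFrame:
    """Ortholog pairs enriched in both clusters of each paired cluster.

    ``cluster_pairing`` maps a cluster label of species A to its homologous
    cluster of species B.  The combined p-value is the maximum of the two
    species' p-values (a gene is conserved only if it passes in both).
    """
    known_a = set(clusters_a) if clusters_a is not None else set(records_a["cluster_label"])
    known_b = set(clusters_b) if clusters_b is not None else set(records_b["cluster_label"])
    for ca, cb in cluster_pairing.items():
        if ca not in known_a:
            raise ValidationError(f"pairing references unknown cluster {ca!r} in species A")
        if cb not in known_b:
            raise ValidationError(f"pairing references unknown cluster {cb!r} in species B")
    b_of = dict(zip(ortholog_map["gene_a"], ortholog_map["gene_b"]))
    rows = []
    for ca, cb in cluster_pairing.items():
        ra = records_a[records_a["cluster_label"] == ca].set_index("gene_id")
        rb = records_b[records_b["cluster_label"] == cb].set_index("gene_id")
        for gene_a, rec_a in ra.iterrows():
            gene_b = b_of.get(gene_a)
            if gene_b is None or gene_b not in rb.index:
                continue
            rec_b = rb.loc[gene_b]
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "log2fc_a": float(rec_a["log2fc"]),
                    "log2fc_b": float(rec_b["log2fc"]),
                    "p_a": float(rec_a["p_value"]),
                    "p_b": float(rec_b["p_value"]),
                    "combined_p": float(max(rec_a["p_value"], rec_b["p_value"])),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster_a",
            "cluster_b",
            "gene_a",
            "gene_b",
            "log2fc_a",
            "log2fc_b",
            "p_a",
            "p_b",
            "combined_p",
        ],
    )
    log_stage("conserved_markers", pairs=len(cluster_pairing), conserved=len(out))
    return out


@dataclass
class GeneModuleAssignment:
    """gene -> module index in 1..k, plus per-module centroids."""

    modules: pd.Series
    centroids: pd.DataFrame
    inertia: float


def conserved_gene_profiles(
    profile_a,
    profile_b,
    conserved: pd.DataFrame,
) -> pd.DataFrame:
    """Concatenate the two species' cluster profiles for conserved ortholog pairs.

    Rows are ``gene_a|gene_b`` pairs; columns are species-A clusters followed
    by species-B clusters (species-tagged).  This is the input expected by
    :func:`kmeans_modules`.
    """
    pairs = conserved[["gene_a", "gene_b"]].drop_duplicates().reset_index(drop=True)
    va = profile_a.values[pairs["gene_a"].tolist()].T.to_numpy()
    vb = profile_b.values[pairs["gene_b"].tolist()].T.to_numpy()
    cols = [f"A:{c}" for c in profile_a.values.index] + [f"B:{c}" for c in profile_b.values.index]
    index = pd.Index(pairs["gene_a"] + "|" + pairs["gene_b"], name="gene_pair")
    return pd.DataFrame(np.hstack([va, vb]), index=index, columns=cols)


def kmeans_modules(
    profiles: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
    zscore: bool = True,
) -> GeneModuleAssignment:
    """Partition gene profiles into k modules by seeded k-means.

    Profiles are z-scored per gene across columns before clustering (rows with
    zero variance become all-zero).  Deterministic under ``seed`` with a fixed
    restart count.  Rows are fitted in canonical (sorted-index) order and
    modules renumbered 1..k by first appearance in that order, so the result
    is invariant to gene ordering given a fixed seed.
    """
    from sklearn.cluster import KMeans

    n_genes = profiles.shape[0]
    if n_genes < k:
        raise ValidationError(f"k-means needs at least k={k} genes, got {n_genes}")
    original_index = profiles.index
    profiles = profiles.sort_index(kind="stable")
    X = profiles.to_numpy(dtype=float)
    if zscore:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = np.where(sd > 0, (X - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trigger convergence warnings
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(X)
    raw = km.labels_
    # renumber by first appearance: stable, human-friendly 1..k
    order: dict[int, int] = {}
    for lbl in raw:
        if lbl not in order:
            order[lbl] = len(order) + 1
    modules = pd.Series([order[lbl] for lbl in raw], index=profiles.index, name="module")
    modules = modules.loc[original_index]
    centroid_rows = sorted(order, key=order.get)
    centroids = pd.DataFrame(
        km.cluster_centers_[centroid_rows],
        index=pd.Index([order[r] for r in centroid_rows], name="module"),
        columns=profiles.columns,
    )
    log_stage("kmeans_modules", genes=n_genes, k=k, seed=seed, inertia=round(km.inertia_, 6))
    return GeneModuleAssignment(modules=modules, centroids=centroids, inertia=float(km.inertia_))
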