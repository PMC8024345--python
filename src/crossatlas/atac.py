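"""ATAC/scRNA integration: differential peaks, peak-to-gene assignment, concordance.

Differentially accessible peaks between the root meristematic zone (MZ) and
elongation zone (EZ) are thresholded (|log2FC| >= 0.58, FDR < 0.05 by
default), assigned to genes by a nearest-TSS rule with a +/-3 kb promoter
preference, and intersected with per-cluster marker genes to count and rate
marker genes that are more accessible in the MZ or the EZ.  Accessibility
log2 fold-changes are oriented MZ-positive throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ValidationError, log_stage

__all__ = [
    "filter_differential_peaks",
    "assign_peaks_to_genes",
    "classify_correlation_sign",
    "concordance_summary",
]

MZ_OPEN = "MZ_open"
EZ_OPEN = "EZ_open"
NS = "ns"


def filter_differential_peaks(
    peaks: pd.DataFrame,
    min_abs_log2fc: float = 0.58,
    max_fdr: float = 0.05,
    fc_comparator: str = "ge",
) -> pd.DataFrame:
    """Keep peaks with |log2FC| >= threshold (or > with ``fc_comparator='gt'``) and FDR < max_fdr.

    Kept peaks gain a ``direction`` column: ``MZ_open`` if log2FC > 0 else
    ``EZ_open`` (fold changes are oriented MZ vs EZ).
    """
    if fc_comparator not in ("ge", "gt"):
        raise ValueError(f"fc_comparator must be 'ge' or 'gt', got {fc_comparator!r}")
    lfc = peaks["log2fc_mz_vs_ez"].abs()
    fc_pass = lfc >= min_abs_log2fc if fc_comparator == "ge" else lfc > min_abs_log2fc
    keep = fc_pass & (peaks["fdr"] < max_fdr)
    out = peaks[keep].copy()
    out["direction"] = np.where(out["log2fc_mz_vs_ez"] > 0, MZ_OPEN, EZ_OPEN)
    log_stage(
        "filter_differential_peaks",
        peaks_in=len(peaks),
        peaks_kept=len(out),
        mz_open=int((out["direction"] == MZ_OPEN).sum()),
        ez_open=int((out["direction"] == EZ_OPEN).sum()),
    )
    return out.reset_index(drop=True)


def _nearest_gene(mid: float, tss: np.ndarray, gene_ids: np.ndarray, window: float):
    """Nearest-TSS gene for one peak midpoint; prefer genes within +/-window.

    Ties (equidistant TSSs) break to the lexicographically smaller gene id.
    ``tss``/``gene_ids`` must be sorted by (tss, gene_id).
    """
    j = np.searchsorted(tss, mid)
    lo = max(0, j - 1)
    hi = min(len(tss), j + 1)
    # include neighbours with identical TSS on either side for exact tie-breaks
    while lo > 0 and tss[lo - 1] == tss[lo]:
        lo -= 1
    while hi < len(tss) and tss[hi - 1] == tss[hi]:
        hi += 1
    cand = list(range(lo, hi))
    dists = [abs(mid - tss[i]) for i in cand]
    within = [i for i, d in zip(cand, dists) if d <= window]
    pool = within if within else cand
    best_d = min(abs(mid - tss[i]) for i in pool)
    best = min(g for i in pool if abs(mid - tss[i]) == best_d for g in [gene_ids[i]])
    return best, best_d


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: int = 3000,
) -> tuple[pd.DataFrame, dict]:
    """Assign each peak to the gene with the nearest TSS (preferring +/-promoter_window).

    Peaks are summarized by their midpoint.  When several peaks land on one
    gene, the peak with the smallest FDR is retained (ties: largest |log2FC|,
    then lexicographic peak id).  Peaks on chromosomes without genes are left
    unassigned and counted in the report.

    Returns a per-gene accessibility table (``gene_id`` index; ``log2fc``,
    ``fdr``, ``direction``, ``peak_id``, ``distance_to_tss``) and a report.
    """
    if len(genes) == 0:
        raise ValidationError("empty gene annotation")
    peaks = peaks.copy()
    if "direction" not in peaks.columns:
        peaks["direction"] = NS
    by_chrom = {
        chrom: grp.sort_values(["tss", "gene_id"], kind="stable")
        for chrom, grp in genes.groupby("chrom")
    }
    assignments = []
    n_unassigned = 0
    for row in peaks.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            n_unassigned += 1
            continue
        mid = (row.start + row.end) / 2.0
        gene, dist = _nearest_gene(
            mid,
            grp["tss"].to_numpy(dtype=float),
            grp["gene_id"].to_numpy(),
            promoter_window,
        )
        assignments.append(
            {
                "gene_id": gene,
                "log2fc": float(row.log2fc_mz_vs_ez),
                "fdr": float(row.fdr),
                "direction": row.direction,
                "peak_id": row.peak_id,
                "distance_to_tss": float(dist),
            }
        )
    report = {"n_peaks": len(peaks), "n_unassigned": n_unassigned, "n_assigned": len(assignments)}
    if not assignments:
        empty = pd.DataFrame(
            columns=["log2fc", "fdr", "direction", "peak_id", "distance_to_tss"],
            index=pd.Index([], name="gene_id"),
        )
        return empty, report
    df = pd.DataFrame(assignments)
    df["abs_lfc"] = df["log2fc"].abs()
    df = df.sort_values(
        ["gene_id", "fdr", "abs_lfc", "peak_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    df = df.drop_duplicates("gene_id", keep="first").drop(columns="abs_lfc")
    df = df.set_index("gene_id")
    report["n_genes"] = len(df)
    log_stage("assign_peaks_to_genes", **report)
    return df, report


def classify_correlation_sign(
    access: pd.DataFrame,
    marker_records: pd.DataFrame,
    cluster_zone: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per marker gene: sign of the accessibility-expression relationship.

    ``positive`` when accessibility log2FC (MZ-positive) and the marker's
    expression log2FC are both positive or both negative; ``negative`` for
    opposite signs; ``undetermined`` when the gene is absent from the
    accessibility table, non-significant, or either value is zero.

    ``cluster_zone`` optionally maps cluster labels to ``'MZ'``/``'EZ'``; for
    EZ-identity clusters the accessibility value is negated first, so signs are
    read relative to the cluster's own zone.
    """
    rows = []
    for row in marker_records.itertuples(index=False):
        gene = row.gene_id
        expr = float(row.log2fc)
        rec = access.loc[gene] if gene in access.index else None
        if rec is None or rec["direction"] == NS:
            sign = "undetermined"
            acc = np.nan
        else:
            acc = float(rec["log2fc"])
            if cluster_zone is not None and cluster_zone.get(row.cluster_label) == "EZ":
                acc = -acc
            if acc > 0 and expr > 0 or acc < 0 and expr < 0:
                sign = "positive"
            elif acc == 0 or expr == 0:
                sign = "undetermined"
            else:
                sign = "negative"
        rows.append(
            {
                "cluster_label": row.cluster_label,
                "gene_id": gene,
                "accessibility_log2fc": acc,
                "expression_log2fc": expr,
                "sign": sign,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_label", "gene_id", "accessibility_log2fc", "expression_log2fc", "sign"],
    )


def _marker_sets(cluster_markers) -> dict[str, list[str]]:
    if isinstance(cluster_markers, pd.DataFrame):
        return {
            cl: grp["gene_id"].tolist()
            for cl, grp in cluster_markers.groupby("cluster_label")
        }
    return {cl: list(genes) for cl, genes in cluster_markers.items()}


def concordance_summary(access: pd.DataFrame, cluster_markers) -> pd.DataFrame:
    """Per-cluster counts and ratios of marker genes by accessibility direction.

    ``ratio_mz = n_mz_open / n_markers_total`` (likewise ``ratio_ez``); the
    denominator is the cluster's full marker list, so markers absent from the
    accessibility table count against the ratio.  Clusters with no markers, or
    whose markers carry no accessibility record at all, get zero ratios and
    the ``flagged`` bit.
    """
    sets = _marker_sets(cluster_markers)
    direction = access["direction"] if len(access) else pd.Series(dtype=object)
    rows = []
    for cl in sorted(sets):
        genes = sets[cl]
        n_total = len(genes)
        n_with = sum(1 for g in genes if g in direction.index)
        n_mz = sum(1 for g in genes if g in direction.index and direction[g] == MZ_OPEN)
        n_ez = sum(1 for g in genes if g in direction.index and direction[g] == EZ_OPEN)
        rows.append(
            {
                "cluster_label": cl,
                "n_mz_open": n_mz,
                "n_ez_open": n_ez,
                "n_markers_total": n_total,
                "n_with_accessibility": n_with,
                "ratio_mz": n_mz / n_total if n_total else 0.0,
                "ratio_ez": n_ez / n_total if n_total else 0.0,
                "flagged": n_total == 0 or n_with == 0,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster_label",
            "n_mz_open",
            "n_ez_open",
            "n_markers_total",
            "n_with_accessibility",
            "ratio_mz",
            "ratio_ez",
            "flagged",
        ],
    )
    log_stage("concordance_summary", clusters=len(out))
    return out
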