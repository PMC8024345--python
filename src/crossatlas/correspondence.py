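"""Cross-species cell-type correspondence by gene-specificity correlation.

The pipeline's headline computation: each species' pseudobulk profile is
transformed into a gene-specificity matrix (a gene's expression in one cell
type divided by its average across all cell types, so SI = 1 means no
specificity), all cluster pairs across species are compared by Spearman rank
correlation over one-to-one ortholog pairs, and significance is assessed
against a permutation null in which every gene's values are independently
shuffled across cell types.  The p-value is the plain fraction of shuffled
replicates whose absolute correlation is at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ValidationError, log_stage
from .orthology import AlignedProfiles, align_profiles
from .preprocess import ClusterProfile

__all__ = [
    "SpecificityMatrix",
    "CorrespondenceResult",
    "specificity_index",
    "pairwise_spearman",
    "permutation_pvalues",
    "call_correspondences",
    "cross_species_correspondence",
    "plot_correspondence",
]

_PERM_STREAM = 0x5EAC  # stream tag separating permutation draws from other RNG uses


@dataclass
class SpecificityMatrix:
    """Cluster x gene specificity values; genes with zero total are flagged."""

    values: pd.DataFrame
    zero_genes: pd.Series  # bool per gene

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative specificity value")


@dataclass
class CorrespondenceResult:
    """Cross-species rho matrix with permutation p-values and significance calls."""

    rho: pd.DataFrame  # clusters_a x clusters_b
    p: pd.DataFrame
    significant: pd.DataFrame  # bool
    undefined: pd.DataFrame  # bool: degenerate (constant) cluster vectors
    n_perm: int
    seed: int
    alpha: float
    n_genes_used: int


def specificity_index(profile: ClusterProfile | pd.DataFrame, mode: str = "mean") -> SpecificityMatrix:
    """Transform a cluster profile into a gene-specificity matrix.

    ``mode='mean'`` (default): SI(g, c) = expr(g, c) / mean_c' expr(g, c'), so
    every expressed gene has mean SI of exactly 1 across clusters.
    ``mode='sum'`` divides by the per-gene sum instead (values then average to
    1/C).  Both are equivalent up to a per-gene constant and give identical
    rank correlations downstream.  Genes with zero total expression get an
    all-zero row and are flagged.
    """
    values = profile.values if isinstance(profile, ClusterProfile) else profile
    if values.shape[0] < 2:
        raise ValidationError("specificity index is undefined for a single cluster")
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    X = values.to_numpy(dtype=float)
    denom = X.mean(axis=0) if mode == "mean" else X.sum(axis=0)
    zero = denom == 0
    safe = np.where(zero, 1.0, denom)
    si = np.where(zero[None, :], 0.0, X / safe[None, :])
    return SpecificityMatrix(
        values=pd.DataFrame(si, index=values.index, columns=values.columns),
        zero_genes=pd.Series(zero, index=values.columns, name="zero_gene"),
    )


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return rankdata(X, axis=1)


def _standardize_rows(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; return (standardized, constant-row mask)."""
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.sqrt((R**2).sum(axis=1))
    const = norms == 0
    R = R / np.where(const, 1.0, norms)[:, None]
    return R, const


def _spearman_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho for every row pair (mid-ranks for ties); constant rows -> NaN."""
    RA, const_a = _standardize_rows(_rank_rows(A))
    RB, const_b = _standardize_rows(_rank_rows(B))
    rho = np.clip(RA @ RB.T, -1.0, 1.0)
    undefined = const_a[:, None] | const_b[None, :]
    rho[undefined] = np.nan
    return rho, undefined


def _usable_columns(spec_a: SpecificityMatrix, spec_b: SpecificityMatrix) -> np.ndarray:
    if spec_a.values.shape[1] != spec_b.values.shape[1]:
        raise ValidationError(
            f"aligned widths differ: {spec_a.values.shape[1]} vs {spec_b.values.shape[1]}"
        )
    keep = ~(spec_a.zero_genes.to_numpy() | spec_b.zero_genes.to_numpy())
    if keep.sum() < 3:
        raise ValidationError(f"fewer than 3 usable genes ({int(keep.sum())})")
    return keep


def pairwise_spearman(spec_a: SpecificityMatrix, spec_b: SpecificityMatrix) -> pd.DataFrame:
    """Spearman rho for every cross-species cluster pair over shared usable genes.

    Genes flagged all-zero in either species are excluded; constant cluster
    vectors yield NaN (undefined) entries.
    """
    keep = _usable_columns(spec_a, spec_b)
    rho, _ = _spearman_matrix(
        spec_a.values.to_numpy(dtype=float)[:, keep],
        spec_b.values.to_numpy(dtype=float)[:, keep],
    )
    return pd.DataFrame(rho, index=spec_a.values.index, columns=spec_b.values.index)


def _permute_within_genes(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene's (column's) values across the cluster axis."""
    idx = np.argsort(rng.random(X.shape), axis=0)
    return np.take_along_axis(X, idx, axis=0)


def permutation_pvalues(
    spec_a: SpecificityMatrix,
    spec_b: SpecificityMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    shuffle_both: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Permutation p-values for the cross-species rho matrix.

    Per replicate, every gene's specificity values are independently permuted
    across cell types (a fresh permutation per gene per replicate), by default
    in both species' matrices; the shuffled rho matrix is recomputed and
    ``p = #{|rho_shuffled| >= |rho_observed|} / n_perm``.  The plain fraction
    is used, so p = 0 is attainable.  Deterministic under ``seed``: each
    replicate draws from its own stream keyed by (seed, replicate).

    Returns ``(p, rho_observed, undefined)`` as DataFrames.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    keep = _usable_columns(spec_a, spec_b)
    A = spec_a.values.to_numpy(dtype=float)[:, keep]
    B = spec_b.values.to_numpy(dtype=float)[:, keep]
    rho_obs, undefined = _spearman_matrix(A, B)
    abs_obs = np.abs(rho_obs)
    counts = np.zeros_like(abs_obs)
    for rep in range(n_perm):
        rng = np.random.default_rng([seed, _PERM_STREAM, rep])
        Ap = _permute_within_genes(A, rng)
        Bp = _permute_within_genes(B, rng) if shuffle_both else B
        rho_sh, _ = _spearman_matrix(Ap, Bp)
        with np.errstate(invalid="ignore"):
            counts += np.abs(rho_sh) >= abs_obs
    p = counts / n_perm
    p[undefined] = np.nan
    index, columns = spec_a.values.index, spec_b.values.index
    return (
        pd.DataFrame(p, index=index, columns=columns),
        pd.DataFrame(rho_obs, index=index, columns=columns),
        pd.DataFrame(undefined, index=index, columns=columns),
    )


def _mutual_best(rho: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of cluster pairs that are each other's highest-rho partner."""
    R = rho.to_numpy(dtype=float)
    filled = np.where(np.isnan(R), -np.inf, R)
    best_b = filled.argmax(axis=1)
    best_a = filled.argmax(axis=0)
    mask = np.zeros_like(R, dtype=bool)
    for i, j in enumerate(best_b):
        if np.isfinite(filled[i, j]) and best_a[j] == i:
            mask[i, j] = True
    return pd.DataFrame(mask, index=rho.index, columns=rho.columns)


def call_correspondences(result: CorrespondenceResult, alpha: float = 0.05):
    """Significance mask (p < alpha, strict; undefined never significant) and ranked pairs.

    The returned pair table lists significant pairs sorted by rho descending,
    annotated with whether each is a mutual best match.
    """
    defined = ~result.undefined
    significant = defined & (result.p < alpha)
    mutual = _mutual_best(result.rho)
    rows = []
    for a in result.rho.index:
        for b in result.rho.columns:
            if significant.loc[a, b]:
                rows.append(
                    {
                        "cluster_a": a,
                        "cluster_b": b,
                        "rho": float(result.rho.loc[a, b]),
                        "p_value": float(result.p.loc[a, b]),
                        "mutual_best": bool(mutual.loc[a, b]),
                    }
                )
    pairs = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "rho", "p_value", "mutual_best"])
    pairs = pairs.sort_values("rho", ascending=False, kind="stable").reset_index(drop=True)
    return significant, pairs


def cross_species_correspondence(
    profile_a: ClusterProfile,
    profile_b: ClusterProfile,
    ortholog_map: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    shuffle_both: bool = True,
    si_mode: str = "mean",
) -> CorrespondenceResult:
    """End-to-end correspondence: align orthologs, specificity, Spearman, permutation null.

    Runs on all one-to-one orthologs with nonzero totals in both species (no
    variable-gene restriction).  Cluster rows are sorted lexicographically
    before analysis so the RNG pairing is keyed by canonical order and the
    result is invariant to input row ordering.
    """
    aligned: AlignedProfiles = align_profiles(profile_a, profile_b, ortholog_map)
    va = aligned.values_a.sort_index(kind="stable")
    vb = aligned.values_b.sort_index(kind="stable")
    spec_a = specificity_index(va, mode=si_mode)
    spec_b = specificity_index(vb, mode=si_mode)
    p, rho, undefined = permutation_pvalues(
        spec_a, spec_b, n_perm=n_perm, seed=seed, shuffle_both=shuffle_both
    )
    defined = ~undefined
    significant = defined & (p < alpha)
    n_used = int((~(spec_a.zero_genes.to_numpy() | spec_b.zero_genes.to_numpy())).sum())
    log_stage(
        "correspondence",
        clusters_a=rho.shape[0],
        clusters_b=rho.shape[1],
        genes_used=n_used,
        n_perm=n_perm,
        seed=seed,
        significant=int(significant.to_numpy().sum()),
    )
    return CorrespondenceResult(
        rho=rho,
        p=p,
        significant=significant,
        undefined=undefined,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
        n_genes_used=n_used,
    )


def plot_correspondence(result: CorrespondenceResult, path) -> None:
    """Heatmap of rho with dots marking significant cluster pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * result.rho.shape[1], 1 + 0.5 * result.rho.shape[0]))
    im = ax.imshow(result.rho.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    sig = result.significant.to_numpy()
    ys, xs = np.nonzero(sig)
    ax.scatter(xs, ys, s=12, c="black", marker=".")
    ax.set_xticks(range(result.rho.shape[1]), result.rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(result.rho.shape[0]), result.rho.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
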