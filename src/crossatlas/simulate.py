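"""Paired two-species synthetic atlases with planted ground truth.

The generator emulates the structure the downstream stages assume: two
species' UMI count matrices drawn from a negative binomial (mean ``mu``,
variance ``mu + mu^2 * dispersion``) over clusters, with cluster-specific
mean shifts of ``2**effect_log2fc`` planted on disjoint marker-gene blocks.
Homologous cluster pairs boost the *same* one-to-one ortholog block in both
species; unpaired clusters boost blocks no other cluster uses.  Per-cell
library-size multipliers are lognormal(0, ``libsize_sigma``) and dropout is
independent zero-masking after sampling.  Ortholog-group lines contain every
one-to-one pair plus injected one-to-many, many-to-many and single-species
groups built from species-private genes, so one-to-one extraction recovers
exactly the planted pairs.  A companion peak simulator plants MZ/EZ
accessibility directions that agree with marker identity for a controlled
fraction of markers.

Every output object draws from its own RNG stream derived from the master
seed, so adding an output never perturbs existing ones; identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ConfigError, CountMatrix, ValidationError, log_stage

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_two_species_atlas",
    "simulate_gene_annotation",
    "simulate_peak_table",
]

# RNG stream tags (master seed, tag, ...) — one per output object
_STREAM_LIBSIZE_A, _STREAM_COUNTS_A, _STREAM_DROPOUT_A = 10, 11, 12
_STREAM_LIBSIZE_B, _STREAM_COUNTS_B, _STREAM_DROPOUT_B = 20, 21, 22
_STREAM_PEAKS = 30


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the paired-atlas simulation.

    ``homology_pairs`` lists (cluster_a_index, cluster_b_index) homologous
    cluster pairs; it must be injective in both coordinates.  Defaults model a
    well-powered two-species design: 8 fully paired clusters, 100 cells each,
    2000 one-to-one orthologs, 50 markers per cluster boosted 4-fold
    (``effect_log2fc = 2``), moderate overdispersion, 10% dropout and 0.3
    lognormal library-size spread.
    """

    n_clusters_a: int = 8
    n_clusters_b: int = 8
    homology_pairs: tuple = tuple((i, i) for i in range(8))
    n_orthologs: int = 2000
    n_private_a: int = 200
    n_private_b: int = 200
    markers_per_cluster: int = 50
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.5
    baseline_mean: float = 0.5
    cells_per_cluster: int = 100
    dropout_rate: float = 0.10
    libsize_sigma: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters_a < 1 or self.n_clusters_b < 1:
            raise ConfigError("need at least one cluster per species")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.libsize_sigma < 0 or self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigError("libsize_sigma >= 0, nb_dispersion > 0 and baseline_mean > 0 required")
        if self.effect_log2fc < 0:
            raise ConfigError(f"effect_log2fc must be >= 0, got {self.effect_log2fc}")
        a_idx = [a for a, _ in self.homology_pairs]
        b_idx = [b for _, b in self.homology_pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ConfigError("homology_pairs must be injective in both coordinates")
        if a_idx and (min(a_idx) < 0 or max(a_idx) >= self.n_clusters_a):
            raise ConfigError("homology pair references a cluster index outside species A")
        if b_idx and (min(b_idx) < 0 or max(b_idx) >= self.n_clusters_b):
            raise ConfigError("homology pair references a cluster index outside species B")
        if self.markers_per_cluster * max(self.n_clusters_a, self.n_clusters_b) > self.n_orthologs:
            raise ConfigError(
                "markers_per_cluster x max(n_clusters) exceeds n_orthologs"
            )
        n_blocks = self.n_clusters_a + (self.n_clusters_b - len(self.homology_pairs))
        if n_blocks * self.markers_per_cluster > self.n_orthologs:
            raise ConfigError(
                f"marker blocks infeasible: {n_blocks} disjoint blocks of "
                f"{self.markers_per_cluster} exceed {self.n_orthologs} orthologs"
            )


@dataclass
class SimTruth:
    """Planted ground truth: homologous cluster pairs, marker sets, directions."""

    homology_pairs: list  # [(cluster_label_a, cluster_label_b)]
    markers_a: dict  # cluster label -> ordered marker gene ids (species A)
    markers_b: dict
    one_to_one: list  # [(gene_a, gene_b)] planted one-to-one ortholog pairs
    cluster_zone_a: dict  # cluster label -> 'MZ' / 'EZ'
    accessibility_direction: dict  # species-A gene -> 'MZ' / 'EZ' (markers only)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["homology_pairs"] = [tuple(p) for p in d["homology_pairs"]]
        d["one_to_one"] = [tuple(p) for p in d["one_to_one"]]
        return cls(**d)


def _gene_ids(prefix: str, n_orth: int, n_priv: int) -> list[str]:
    return [f"{prefix}G{i:05d}" for i in range(n_orth)] + [
        f"{prefix}P{i:04d}" for i in range(n_priv)
    ]


def _simulate_species(
    cfg: SimConfig,
    n_clusters: int,
    marker_blocks: dict[int, np.ndarray],
    n_genes: int,
    seed_tags: tuple[int, int, int],
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Negative-binomial counts for one species; returns (counts, cluster index per cell)."""
    n_cells = n_clusters * cfg.cells_per_cluster
    cluster_of = np.repeat(np.arange(n_clusters), cfg.cells_per_cluster)

    cluster_means = np.full((n_clusters, n_genes), cfg.baseline_mean)
    boost = 2.0**cfg.effect_log2fc
    for c, block in marker_blocks.items():
        cluster_means[c, block] *= boost

    rng_lib = np.random.default_rng([cfg.seed, seed_tags[0]])
    rng_counts = np.random.default_rng([cfg.seed, seed_tags[1]])
    rng_drop = np.random.default_rng([cfg.seed, seed_tags[2]])

    libsize = rng_lib.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n_cells)
    mu = cluster_means[cluster_of] * libsize[:, None]
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng_counts.negative_binomial(r, p)
    if cfg.dropout_rate > 0:
        counts[rng_drop.random(counts.shape) < cfg.dropout_rate] = 0
    return sp.csr_matrix(counts), cluster_of


def simulate_two_species_atlas(config: SimConfig):
    """Generate the paired atlases, annotations, ortholog-group lines and truth.

    Returns ``(cm_a, ann_a, cm_b, ann_b, ortholog_group_lines, truth)``.
    Species A genes carry the ``OSA_`` prefix and species B the ``ATH_``
    prefix; one-to-one ortholog pairs share their numeric suffix.
    """
    cfg = config
    cfg.validate()
    m = cfg.markers_per_cluster
    genes_a = _gene_ids("OSA_", cfg.n_orthologs, cfg.n_private_a)
    genes_b = _gene_ids("ATH_", cfg.n_orthologs, cfg.n_private_b)

    # Disjoint ortholog marker blocks: A cluster i -> block i; a paired B
    # cluster reuses its partner's block, an unpaired one takes the next free.
    blocks_a = {c: np.arange(c * m, (c + 1) * m) for c in range(cfg.n_clusters_a)}
    partner_of_b = {b: a for a, b in cfg.homology_pairs}
    blocks_b: dict[int, np.ndarray] = {}
    next_free = cfg.n_clusters_a
    for c in range(cfg.n_clusters_b):
        if c in partner_of_b:
            blocks_b[c] = blocks_a[partner_of_b[c]]
        else:
            blocks_b[c] = np.arange(next_free * m, (next_free + 1) * m)
            next_free += 1

    counts_a, cl_a = _simulate_species(
        cfg, cfg.n_clusters_a, blocks_a, len(genes_a),
        (_STREAM_LIBSIZE_A, _STREAM_COUNTS_A, _STREAM_DROPOUT_A),
    )
    counts_b, cl_b = _simulate_species(
        cfg, cfg.n_clusters_b, blocks_b, len(genes_b),
        (_STREAM_LIBSIZE_B, _STREAM_COUNTS_B, _STREAM_DROPOUT_B),
    )

    cells_a = [f"OSA_cell{i:05d}" for i in range(counts_a.shape[0])]
    cells_b = [f"ATH_cell{i:05d}" for i in range(counts_b.shape[0])]
    labels_a = [f"A{c}" for c in cl_a]
    labels_b = [f"B{c}" for c in cl_b]
    cm_a = CountMatrix("osa", cells_a, genes_a, counts_a)
    cm_b = CountMatrix("ath", cells_b, genes_b, counts_b)
    ann_a = pd.DataFrame({"cell_id": cells_a, "cluster_label": labels_a})
    ann_b = pd.DataFrame({"cell_id": cells_b, "cluster_label": labels_b})

    # Ortholog groups: every one-to-one pair, then injected one-to-many,
    # many-to-many and single-species groups from private genes.
    lines = [
        f"OG{i:06d}: {genes_a[i]} {genes_b[i]}" for i in range(cfg.n_orthologs)
    ]
    priv_a = [g for g in genes_a if "_P" in g]
    priv_b = [g for g in genes_b if "_P" in g]
    ia = ib = 0
    g = cfg.n_orthologs
    while ia + 1 <= len(priv_a) - 1 and ib + 2 <= len(priv_b) and g < cfg.n_orthologs + 10:
        lines.append(f"OG{g:06d}: {priv_a[ia]} {priv_b[ib]} {priv_b[ib + 1]}")  # one-to-many
        ia += 1
        ib += 2
        g += 1
    while ia + 2 <= len(priv_a) and ib + 2 <= len(priv_b) and g < cfg.n_orthologs + 20:
        lines.append(
            f"OG{g:06d}: {priv_a[ia]} {priv_a[ia + 1]} {priv_b[ib]} {priv_b[ib + 1]}"
        )  # many-to-many
        ia += 2
        ib += 2
        g += 1
    for _ in range(3):  # single-species groups (no counterpart -> dropped downstream)
        if ia < len(priv_a):
            lines.append(f"OG{g:06d}: {priv_a[ia]}")
            ia += 1
            g += 1

    markers_a = {f"A{c}": [genes_a[i] for i in blocks_a[c]] for c in range(cfg.n_clusters_a)}
    markers_b = {f"B{c}": [genes_b[i] for i in blocks_b[c]] for c in range(cfg.n_clusters_b)}
    cluster_zone_a = {f"A{c}": ("MZ" if c % 2 == 0 else "EZ") for c in range(cfg.n_clusters_a)}
    direction = {
        gene: cluster_zone_a[cl] for cl, genes in markers_a.items() for gene in genes
    }
    truth = SimTruth(
        homology_pairs=[(f"A{a}", f"B{b}") for a, b in cfg.homology_pairs],
        markers_a=markers_a,
        markers_b=markers_b,
        one_to_one=[(genes_a[i], genes_b[i]) for i in range(cfg.n_orthologs)],
        cluster_zone_a=cluster_zone_a,
        accessibility_direction=direction,
    )
    log_stage(
        "simulate_two_species_atlas",
        cells_a=counts_a.shape[0],
        cells_b=counts_b.shape[0],
        genes_a=len(genes_a),
        genes_b=len(genes_b),
        seed=cfg.seed,
    )
    return cm_a, ann_a, cm_b, ann_b, lines, truth


def simulate_gene_annotation(
    gene_ids,
    genes_per_chrom: int = 500,
    spacing: int = 10_000,
    first_tss: int = 5_000,
) -> pd.DataFrame:
    """Minimal gene annotation: genes laid out on chromosomes at fixed TSS spacing."""
    rows = []
    for i, g in enumerate(gene_ids):
        rows.append(
            {
                "gene_id": g,
                "chrom": f"chr{1 + i // genes_per_chrom}",
                "strand": "+" if i % 2 == 0 else "-",
                "tss": first_tss + (i % genes_per_chrom) * spacing,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def simulate_peak_table(
    truth: SimTruth,
    gene_annotation: pd.DataFrame,
    frac_concordant: float,
    seed: int = 0,
) -> pd.DataFrame:
    """One peak near each species-A marker gene's TSS with planted MZ/EZ agreement.

    Per cluster, exactly ``floor(frac_concordant * n_markers)`` markers (a
    seeded sample) receive a peak whose log2FC sign matches the planted
    accessibility direction with FDR < 0.05; the remaining markers alternate
    between an opposite-sign significant peak and a same-sign non-significant
    one.  Peak midpoints fall within +/-1 kb of the TSS.
    """
    if not (0.0 <= frac_concordant <= 1.0):
        raise ConfigError(f"frac_concordant must be in [0, 1], got {frac_concordant}")
    tss_of = dict(zip(gene_annotation["gene_id"], gene_annotation["tss"]))
    chrom_of = dict(zip(gene_annotation["gene_id"], gene_annotation["chrom"]))
    rows = []
    for ci, cl in enumerate(sorted(truth.markers_a)):
        genes = truth.markers_a[cl]
        for gene in genes:
            if gene not in tss_of:
                raise ValidationError(f"marker gene {gene!r} absent from gene annotation")
        n = len(genes)
        n_conc = math.floor(frac_concordant * n)
        rng = np.random.default_rng([seed, _STREAM_PEAKS, ci])
        conc_idx = set(rng.choice(n, size=n_conc, replace=False).tolist())
        n_disc_seen = 0
        for gi, gene in enumerate(genes):
            planted = truth.accessibility_direction[gene]
            sign = 1.0 if planted == "MZ" else -1.0
            mag = float(rng.uniform(0.8, 2.0))
            offset = int(rng.integers(-900, 901))
            if gi in conc_idx:
                lfc, fdr = sign * mag, 0.01
            else:
                if n_disc_seen % 2 == 0:
                    lfc, fdr = -sign * mag, 0.01  # significant, opposite direction
                else:
                    lfc, fdr = sign * mag, 0.5  # right direction but non-significant
                n_disc_seen += 1
            mid = tss_of[gene] + offset
            rows.append(
                {
                    "peak_id": f"pk_{gene}",
                    "chrom": chrom_of[gene],
                    "start": int(mid - 100),
                    "end": int(mid + 100),
                    "log2fc_mz_vs_ez": lfc,
                    "fdr": fdr,
                }
            )
    out = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "log2fc_mz_vs_ez", "fdr"]
    )
    log_stage("simulate_peak_table", peaks=len(out), frac_concordant=frac_concordant, seed=seed)
    return out
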