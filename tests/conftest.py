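import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossatlas import (
    CountMatrix,
    SimConfig,
    average_by_cluster,
    extract_one_to_one,
    lognormalize,
    parse_ortholog_groups,
    qc_filter,
    simulate_two_species_atlas,
)


# A small but fully structured paired atlas: 4 homologous cluster pairs,
# 300 orthologs, 10 markers per cluster, 40 cells per cluster.
SMALL_CONFIG = SimConfig(
    n_clusters_a=4,
    n_clusters_b=4,
    homology_pairs=((0, 0), (1, 1), (2, 2), (3, 3)),
    n_orthologs=300,
    n_private_a=40,
    n_private_b=40,
    markers_per_cluster=10,
    cells_per_cluster=40,
    seed=11,
)


@pytest.fixture(scope="session")
def small_atlas():
    return simulate_two_species_atlas(SMALL_CONFIG)


# QC bounds rescaled to the small fixture's gene count (the defaults target
# full-size atlases with tens of thousands of genes).
SMALL_QC = __import__("crossatlas").QCThresholds(min_genes=20, max_genes=340, min_umi=20, max_umi=40_000)


@pytest.fixture(scope="session")
def small_profiles(small_atlas):
    import warnings

    cm_a, ann_a, cm_b, ann_b, lines, truth = small_atlas
    fa, _ = qc_filter(cm_a, thresholds=SMALL_QC)
    fb, _ = qc_filter(cm_b, thresholds=SMALL_QC)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pa = average_by_cluster(lognormalize(fa), ann_a)
        pb = average_by_cluster(lognormalize(fb), ann_b)
    omap = extract_one_to_one(parse_ortholog_groups(lines, "OSA_", "ATH_"))
    return pa, pb, omap, truth


def make_count_matrix(array, species="sp", cells=None, genes=None) -> CountMatrix:
    array = np.asarray(array)
    n_cells, n_genes = array.shape
    return CountMatrix(
        species_id=species,
        cell_ids=cells or [f"c{i}" for i in range(n_cells)],
        gene_ids=genes or [f"g{j}" for j in range(n_genes)],
        counts=sp.csr_matrix(array),
    )


def make_annotation(cell_ids, labels) -> pd.DataFrame:
    return pd.DataFrame({"cell_id": list(cell_ids), "cluster_label": list(labels)})
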