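"""Validated containers and readers/writers for every external table the pipeline touches.

External formats supported:

* 10x-style sparse triplets — MatrixMarket coordinate file (features x barcodes,
  optionally gzipped) plus ``barcodes.tsv`` and ``features.tsv``.
* Headered TSV for cell annotations, differential-peak tables (BED-like
  half-open coordinates plus log2FC and FDR), minimal gene annotations and
  ortholog maps.
* A flat ``key = value`` run-configuration file mirroring the CLI flags.

All genomic coordinates are 0-based half-open (BED convention) internally;
any 1-based input must be converted at the boundary by the caller.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("crossatlas")

__all__ = [
    "ValidationError",
    "SchemaError",
    "ConfigError",
    "CountMatrix",
    "TableSchema",
    "CELL_ANNOTATION_SCHEMA",
    "PEAK_SCHEMA",
    "GENE_ANNOTATION_SCHEMA",
    "ORTHOLOG_MAP_SCHEMA",
    "read_count_matrix",
    "write_count_matrix",
    "read_table",
    "write_table",
    "read_profile",
    "write_profile",
    "read_config",
    "log_stage",
]


class ValidationError(ValueError):
    """An input violates a container invariant."""


class SchemaError(ValidationError):
    """A table does not match its declared schema."""


class ConfigError(ValueError):
    """An infeasible or malformed run configuration."""


def log_stage(stage: str, **fields) -> None:
    """Emit one structured log line for a pipeline stage (shapes, counts, seed)."""
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in fields.items()))


def _first_duplicate(ids) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer UMI counts for one species.

    Invariants (enforced on construction): unique cell and gene identifiers,
    dimensions consistent with the id lists, all counts integral and >= 0.
    """

    species_id: str
    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix  # cells x genes

    def __post_init__(self) -> None:
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.validate()

    def validate(self) -> None:
        dup = _first_duplicate(self.cell_ids)
        if dup is not None:
            raise ValidationError(f"duplicate cell identifier: {dup!r}")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene identifier: {dup!r}")
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError(
                f"dimension mismatch: matrix is {n_cells} x {n_genes}, "
                f"expected {len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative count encountered")
            if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.round(data)):
                raise ValidationError("non-integral count encountered")
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_anndata(self):
        """Return the matrix as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(matrix_path, barcodes_path, features_path, species_id: str) -> CountMatrix:
    """Read a 10x-style triplet (MatrixMarket features x barcodes + id files).

    The features file may carry one, two or three columns (id / id+name /
    id+name+type); only the first column is used as the gene identifier.
    Identifier order is preserved from the input files.
    """
    with _open_text(matrix_path) as fh:
        mat = mmread(fh)
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(features):
        raise ValidationError(
            f"feature dimension mismatch: matrix has {n_genes} rows, "
            f"features file has {len(features)} entries"
        )
    if n_cells != len(barcodes):
        raise ValidationError(
            f"barcode dimension mismatch: matrix has {n_cells} columns, "
            f"barcodes file has {len(barcodes)} entries"
        )
    cm = CountMatrix(
        species_id=species_id,
        cell_ids=barcodes,
        gene_ids=features,
        counts=sp.csr_matrix(mat.T),
    )
    log_stage("read_count_matrix", species=species_id, cells=cm.shape[0], genes=cm.shape[1])
    return cm


def write_count_matrix(cm: CountMatrix, out_dir) -> None:
    """Write ``matrix.mtx`` / ``barcodes.tsv`` / ``features.tsv`` (10x layout)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), cm.counts.T.tocoo(), field="integer")
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.cell_ids))
    (out / "features.tsv").write_text("".join(f"{g}\n" for g in cm.gene_ids))


# ---------------------------------------------------------------------------
# Headered TSV tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSchema:
    """Declarative schema for a headered TSV: required typed columns + checks."""

    name: str
    columns: Mapping[str, type]
    checker: Callable[[pd.DataFrame], None] | None = None
    optional: tuple[str, ...] = ()


def _check_cell_annotation(df: pd.DataFrame) -> None:
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell_id in annotation: {dup.iloc[0]!r}")
    empty = df["cluster_label"].astype(str).str.len() == 0
    if empty.any():
        raise ValidationError(
            f"empty cluster label for cell {df.loc[empty, 'cell_id'].iloc[0]!r}"
        )


def _check_peaks(df: pd.DataFrame) -> None:
    dup = df["peak_id"][df["peak_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate peak_id: {dup.iloc[0]!r}")
    bad = df["start"] >= df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"peak {row['peak_id']!r}: start {row['start']} >= end {row['end']} "
            "(coordinates are 0-based half-open)"
        )
    out = (df["fdr"] < 0) | (df["fdr"] > 1)
    if out.any():
        row = df[out].iloc[0]
        raise ValidationError(f"peak {row['peak_id']!r}: fdr {row['fdr']} outside [0, 1]")


def _check_gene_annotation(df: pd.DataFrame) -> None:
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate gene_id in annotation: {dup.iloc[0]!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = df[bad_strand].iloc[0]
        raise ValidationError(f"gene {row['gene_id']!r}: strand must be '+' or '-'")
    if (df["tss"] < 0).any():
        row = df[df["tss"] < 0].iloc[0]
        raise ValidationError(f"gene {row['gene_id']!r}: negative TSS coordinate")


def _check_ortholog_map(df: pd.DataFrame) -> None:
    for col in ("gene_a", "gene_b"):
        dup = df[col][df[col].duplicated()]
        if len(dup):
            raise ValidationError(f"ortholog map is not a bijection: {dup.iloc[0]!r} repeated in {col}")


CELL_ANNOTATION_SCHEMA = TableSchema(
    name="cell_annotation",
    columns={"cell_id": str, "cluster_label": str},
    checker=_check_cell_annotation,
    optional=("batch",),
)

PEAK_SCHEMA = TableSchema(
    name="peaks",
    columns={
        "peak_id": str,
        "chrom": str,
        "start": int,
        "end": int,
        "log2fc_mz_vs_ez": float,
        "fdr": float,
    },
    checker=_check_peaks,
)

GENE_ANNOTATION_SCHEMA = TableSchema(
    name="gene_annotation",
    columns={"gene_id": str, "chrom": str, "strand": str, "tss": int},
    checker=_check_gene_annotation,
)

ORTHOLOG_MAP_SCHEMA = TableSchema(
    name="ortholog_map",
    columns={"gene_a": str, "gene_b": str},
    checker=_check_ortholog_map,
)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a headered TSV against *schema*.

    Rows failing numeric coercion are reported with their 1-based file line
    numbers (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name} table {path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    bad_lines: list[int] = []
    for col, typ in schema.columns.items():
        if typ is str:
            df[col] = df[col].fillna("").astype(str)
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if typ is int:
            nonint = coerced.notna() & (coerced != np.floor(coerced))
            bad |= nonint
        if bad.any():
            bad_lines.extend((df.index[bad] + 2).tolist())
            continue
        df[col] = coerced.astype(np.int64 if typ is int else np.float64)
    if bad_lines:
        raise SchemaError(
            f"{schema.name} table {path}: type coercion failed on line(s) {sorted(set(bad_lines))}"
        )
    keep = list(schema.columns) + [c for c in schema.optional if c in df.columns]
    df = df[keep].reset_index(drop=True)
    if schema.checker is not None:
        schema.checker(df)
    return df


def write_table(df: pd.DataFrame, path, schema: TableSchema | None = None) -> None:
    """Write a TSV in canonical column order so write->read round-trips byte-identically."""
    if schema is not None:
        cols = list(schema.columns) + [c for c in schema.optional if c in df.columns]
        df = df[cols]
    df.to_csv(path, sep="\t", index=False)


def read_profile(path) -> pd.DataFrame:
    """Read a cluster x gene profile TSV (clusters as the index column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profile(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def warn_unmatched_annotation(ann: pd.DataFrame, cell_ids) -> None:
    """Warn (but keep rows) when annotated cells are absent from a count matrix."""
    extra = set(ann["cell_id"]) - set(cell_ids)
    if extra:
        warnings.warn(
            f"{len(extra)} annotated cell(s) absent from the count matrix "
            f"(e.g. {sorted(extra)[0]!r}); rows retained for a later join",
            stacklevel=2,
        )
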