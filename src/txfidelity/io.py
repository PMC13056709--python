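"""Shared data model and readers/writers for the standard formats.

The pipeline's in-memory currency is :class:`CountMatrix` (sparse gene x cell
raw UMI counts with aligned identifier vectors) plus plain pandas tables for
per-cell metadata.  On disk we speak the 10x Genomics Matrix-Market triplet
(``matrix.mtx[.gz]``, ``features.tsv[.gz]``, ``barcodes.tsv[.gz]``), CSV with a
header row for tables, and GMT for gene-set collections.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class TxfidelityError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(TxfidelityError):
    """Bad inputs or configuration, detected before any computation."""


# CellTable column contract (a pandas DataFrame with these columns).
CELL_COLUMNS = (
    "cell_id",
    "sample_id",
    "timepoint",
    "label",
    "n_genes",
    "n_umis",
    "pct_mito",
    "keep",
)

TIMEPOINTS = ("day0", "day14")


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer gene x cell UMI count matrix.

    Parameters
    ----------
    values
        ``scipy.sparse`` matrix in gene x cell orientation.
    gene_ids, cell_ids
        Unique identifier vectors aligned to the rows / columns.  Cells are
        conventionally namespaced as ``sample_id + ":" + barcode`` so that
        concatenating samples never collides.
    gene_symbols
        Optional display symbols (annotation only; all joins are on id).
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    gene_symbols: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} identifiers")
        if self.values.nnz:
            data = self.values.data
            if np.any(data < 0) or np.any(data != np.round(data)):
                raise ValidationError("counts must be nonnegative integers")
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if len(self.gene_symbols) != len(self.gene_ids):
                raise ValidationError("gene_symbols length mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def depths(self) -> np.ndarray:
        """Per-cell total UMI counts (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def cell_index(self, cell_ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"unknown cell id {exc.args[0]!r}") from exc

    def subset_cells(self, cells: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Column subset by cell id list or boolean mask (order preserved)."""
        cells = np.asarray(cells)
        if cells.dtype == bool:
            idx = np.flatnonzero(cells)
        else:
            idx = self.cell_index(cells)
        return CountMatrix(
            self.values[:, idx], self.gene_ids, self.cell_ids[idx], self.gene_symbols
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([lookup[g] for g in arr], dtype=int)
        sym = None if self.gene_symbols is None else self.gene_symbols[idx]
        return CountMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids, sym)

    @staticmethod
    def concat_cells(matrices: Sequence["CountMatrix"]) -> "CountMatrix":
        """Concatenate matrices over cells; all must share the gene axis."""
        first = matrices[0]
        for m in matrices[1:]:
            if not np.array_equal(m.gene_ids, first.gene_ids):
                raise ValidationError("gene axes differ; cannot concatenate")
        return CountMatrix(
            sp.hstack([m.values for m in matrices]).tocsr(),
            first.gene_ids,
            np.concatenate([m.cell_ids for m in matrices]),
            first.gene_symbols,
        )


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with unique names (GMT semantics)."""

    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for candidate in (dirpath / stem, dirpath / (stem + ".gz")):
        if candidate.exists():
            return candidate
    raise ValidationError(f"missing {stem}[.gz] in {dirpath}")


def read_10x(path: str | Path) -> CountMatrix:
    """Read a 10x-style Matrix-Market triplet directory into a CountMatrix.

    Orientation on disk is inferred from the id-file lengths: whichever axis
    matches the feature count becomes the gene axis (gene x cell preferred on
    a square tie).  Gzipped members are handled transparently.
    """
    dirpath = Path(path)
    mtx = _find(dirpath, "matrix.mtx")
    features = _find(dirpath, "features.tsv")
    barcodes = _find(dirpath, "barcodes.tsv")

    with _open_maybe_gzip(mtx, "rb") as fh:
        values = scipy.io.mmread(fh)
    values = sp.csr_matrix(values)
    if values.nnz and np.any(values.data != np.round(values.data)):
        raise ValidationError(f"{mtx}: non-integer entries")

    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    if feat.shape[1] < 2:
        raise ValidationError(f"{features}: expected >= 2 columns (id, symbol)")
    with _open_maybe_gzip(barcodes) as fh:
        cells = np.array([line.strip() for line in fh if line.strip()], dtype=object)

    gene_ids = feat.iloc[:, 0].to_numpy(dtype=object)
    symbols = feat.iloc[:, 1].to_numpy(dtype=object)
    n_feat, n_cell = len(gene_ids), len(cells)
    if values.shape == (n_feat, n_cell):
        pass
    elif values.shape == (n_cell, n_feat):
        values = values.T.tocsr()
    else:
        raise ValidationError(
            f"matrix shape {values.shape} matches neither {n_feat} features x "
            f"{n_cell} barcodes nor its transpose"
        )
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValidationError("empty count matrix")
    return CountMatrix(values.astype(np.int64), gene_ids, cells, symbols)


def write_10x(path: str | Path, counts: CountMatrix, compress: bool = False) -> None:
    """Write a CountMatrix as a matrix.mtx / features.tsv / barcodes.tsv triplet."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    with _open_maybe_gzip(dirpath / ("matrix.mtx" + suffix), "wb") as fh:
        scipy.io.mmwrite(fh, counts.values.tocoo(), field="integer")
    symbols = counts.gene_symbols
    if symbols is None:
        symbols = counts.gene_ids
    with _open_maybe_gzip(dirpath / ("features.tsv" + suffix), "wt") as fh:
        for gid, sym in zip(counts.gene_ids, symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with _open_maybe_gzip(dirpath / ("barcodes.tsv" + suffix), "wt") as fh:
        for cid in counts.cell_ids:
            fh.write(f"{cid}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...) into a collection.

    Duplicate members within a set are deduplicated; the description column is
    discarded; a repeated set name is an error (the collection is ambiguous).
    """
    sets: dict[str, frozenset] = {}
    with _open_maybe_gzip(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(path: str | Path, collection: GeneSetCollection, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a per-cell metadata CSV (CellTable)."""
    table = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    missing = {"cell_id"} - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return table


def write_cells(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def validate_cell_table(table: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check CellTable invariants (one row per cell, known timepoints)."""
    if table["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id rows in cell table")
    if "timepoint" in table.columns:
        bad = set(table["timepoint"].dropna().unique()) - set(TIMEPOINTS)
        if bad:
            raise ValidationError(f"unknown timepoints {sorted(bad)}")
    if counts is not None:
        if set(table["cell_id"]) != set(counts.cell_ids):
            raise ValidationError("cell table does not cover the count matrix cells")


def namespace_cells(sample_id: str, barcodes: Iterable[str]) -> np.ndarray:
    """Globally unique cell ids: ``sample_id + ':' + barcode``."""
    return np.array([f"{sample_id}:{b}" for b in barcodes], dtype=object)
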