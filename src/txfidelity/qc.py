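"""Per-cell quality control.

Cells are kept when they satisfy gene complexity (>= 600 detected genes),
library size (>= 1000 UMIs), mitochondrial content (< 8% of UMIs), and fall
at or below per-sample upper outlier caps computed with the standard
1.5 x IQR rule on gene complexity and library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError


@dataclass
class QCThresholds:
    """Filter thresholds.  Minima are inclusive; the mito rule is strict
    (cells at exactly ``max_pct_mito`` are dropped)."""

    min_genes: int = 600
    min_umis: int = 1000
    max_pct_mito: float = 8.0
    iqr_mult: float = 1.5

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_umis, self.max_pct_mito) < 0:
            raise ValidationError("thresholds must be nonnegative")
        if self.iqr_mult <= 0:
            raise ValidationError("iqr_mult must be positive")


def compute_metrics(
    counts: CountMatrix,
    mito_genes,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute per-cell QC metrics, optionally merging sample metadata.

    Returns a CellTable-style DataFrame with ``n_genes`` (genes detected at
    count > 0), ``n_umis`` (column sum), and ``pct_mito`` (mito UMIs as a
    percentage of total UMIs; 0 for an all-zero cell).  ``meta``, if given,
    is joined on ``cell_id`` to carry sample_id / timepoint / label columns.
    """
    mito_genes = set(mito_genes)
    missing = mito_genes - set(counts.gene_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} mitochondrial genes absent from the matrix",
            stacklevel=2,
        )
    csc = counts.values.tocsc()
    n_umis = np.asarray(csc.sum(axis=0)).ravel()
    n_genes = np.diff(csc.indptr)  # nonzero entries per column
    mito_mask = np.isin(counts.gene_ids, list(mito_genes & set(counts.gene_ids)))
    mito_umis = np.asarray(csc[np.flatnonzero(mito_mask)].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_umis > 0, 100.0 * mito_umis / np.maximum(n_umis, 1), 0.0)

    table = pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_genes": n_genes.astype(int),
            "n_umis": n_umis.astype(int),
            "pct_mito": pct_mito,
        }
    )
    if meta is not None:
        table = table.merge(meta, on="cell_id", how="left", validate="1:1")
    cols = ["cell_id"] + [c for c in table.columns if c != "cell_id"]
    return table[cols]


def iqr_cap(values: np.ndarray, iqr_mult: float = 1.5) -> float:
    """Upper Tukey fence Q3 + iqr_mult * (Q3 - Q1), linear-interpolated quartiles."""
    q1, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.75])
    return float(q3 + iqr_mult * (q3 - q1))


def apply_qc(table: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Flag cells passing all QC rules (non-destructive: adds a ``keep`` column).

    Upper caps on ``n_genes`` and ``n_umis`` are computed per
    (sample_id, timepoint) group on the pre-filter values; if those columns
    are absent the whole table is one group.
    """
    thresholds = thresholds or QCThresholds()
    for col in ("n_genes", "n_umis", "pct_mito"):
        if col not in table.columns:
            raise ValidationError(f"metrics column {col!r} missing; run compute_metrics")
    out = table.copy()
    group_cols = [c for c in ("sample_id", "timepoint") if c in out.columns]
    if group_cols:
        grouped = out.groupby(group_cols, sort=False, dropna=False)
    else:
        grouped = [(None, out)]

    keep = pd.Series(False, index=out.index)
    for _, sub in grouped:
        if len(sub) == 0:
            raise ValidationError("empty sample group")
        cap_genes = iqr_cap(sub["n_genes"].to_numpy(), thresholds.iqr_mult)
        cap_umis = iqr_cap(sub["n_umis"].to_numpy(), thresholds.iqr_mult)
        keep.loc[sub.index] = (
            (sub["n_genes"] >= thresholds.min_genes)
            & (sub["n_umis"] >= thresholds.min_umis)
            & (sub["pct_mito"] < thresholds.max_pct_mito)
            & (sub["n_genes"] <= cap_genes)
            & (sub["n_umis"] <= cap_umis)
        )
    out["keep"] = keep.to_numpy()
    return out
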