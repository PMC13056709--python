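"""Reference-based broad cell-type annotation.

Each cell is labelled independently by Spearman rank correlation against a
collapsed reference profile matrix (gene x broad class), over a marker
feature space chosen from the reference's pairwise log fold differences —
the discriminative core of correlation-based annotators, reduced to a single
deterministic pass plus one refinement round between the two top-scoring
classes.  Rank correlation makes the assignment invariant to any monotone
transform of the query expression, so log-normalized queries and linear-scale
references compare cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import CountMatrix, ValidationError

MIN_COMMON_GENES = 20


@dataclass
class ReferenceProfile:
    """Collapsed reference: nonnegative gene x broad-class expression."""

    genes: np.ndarray
    broad_classes: np.ndarray
    expr: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.broad_classes = np.asarray(self.broad_classes, dtype=object)
        self.expr = np.asarray(self.expr, dtype=float)
        if self.expr.shape != (len(self.genes), len(self.broad_classes)):
            raise ValidationError("reference expr shape mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate reference genes")
        if self.expr.shape[1] == 0:
            raise ValidationError("empty reference")
        if np.any(self.expr < 0):
            raise ValidationError("reference expression must be nonnegative")
        if np.any(~self.expr.any(axis=0)):
            raise ValidationError("reference contains an all-zero class column")


def collapse_reference(fine_expr: pd.DataFrame, mapping: dict) -> ReferenceProfile:
    """Collapse a gene x fine-label median-expression table into broad classes.

    The broad column is the unweighted mean of its fine columns.  Broad class
    order follows first appearance among the fine columns.
    """
    unmapped = [c for c in fine_expr.columns if c not in mapping]
    if unmapped:
        raise ValidationError(f"unmapped fine labels: {unmapped}")
    broad_order: list[str] = []
    for col in fine_expr.columns:
        b = mapping[col]
        if b not in broad_order:
            broad_order.append(b)
    cols = []
    for b in broad_order:
        members = [c for c in fine_expr.columns if mapping[c] == b]
        cols.append(fine_expr[members].to_numpy(dtype=float).mean(axis=1))
    return ReferenceProfile(
        genes=fine_expr.index.to_numpy(dtype=object),
        broad_classes=np.array(broad_order, dtype=object),
        expr=np.column_stack(cols),
    )


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Depth-normalize then log-transform: ln(1 + scale * x / depth).

    Zero-depth cells map to all-zero columns.  Sparsity is preserved (zeros
    stay zeros).
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    depths = counts.depths().astype(float)
    inv = np.where(depths > 0, scale / np.maximum(depths, 1e-300), 0.0)
    mat = counts.values.tocsc().astype(float)
    mat = mat.multiply(inv.reshape(1, -1)).tocsc()
    mat.data = np.log1p(mat.data)
    return mat.tocsr()


def _pairwise_marker_space(ref_expr: np.ndarray, top_n: int, pairs=None) -> np.ndarray:
    """Union over ordered class pairs of the top-``top_n`` genes by log fold
    difference in the reference (log1p scale); returns sorted gene indices."""
    logref = np.log1p(ref_expr)
    n_classes = logref.shape[1]
    if pairs is None:
        pairs = [(i, j) for i in range(n_classes) for j in range(n_classes) if i != j]
    chosen: set[int] = set()
    for i, j in pairs:
        diff = logref[:, i] - logref[:, j]
        # stable sort => ties resolved by gene position
        order = np.argsort(-diff, kind="stable")[:top_n]
        chosen.update(order.tolist())
    return np.array(sorted(chosen), dtype=int)


def _spearman_scores(query_dense: np.ndarray, ref_block: np.ndarray) -> np.ndarray:
    """Spearman correlations between query columns and reference columns.

    ``query_dense``: features x cells; ``ref_block``: features x classes.
    Average ranks for ties; a constant vector (zero variance) scores 0.
    """
    qr = rankdata(query_dense, axis=0)
    rr = rankdata(ref_block, axis=0)
    qr = qr - qr.mean(axis=0, keepdims=True)
    rr = rr - rr.mean(axis=0, keepdims=True)
    qnorm = np.sqrt((qr**2).sum(axis=0))
    rnorm = np.sqrt((rr**2).sum(axis=0))
    denom = np.outer(qnorm, rnorm)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, (qr.T @ rr) / np.maximum(denom, 1e-300), 0.0)
    return scores  # cells x classes


def assign_labels(
    query: sp.spmatrix | np.ndarray,
    query_genes,
    query_cells,
    reference: ReferenceProfile,
    marker_top_n: int = 50,
) -> pd.DataFrame:
    """Label each query cell against the reference classes.

    Scores are Spearman correlations over the pairwise marker feature space on
    genes common to query and reference; the label is the argmax, with ties
    broken by class order.  A refinement round re-scores the two top classes
    on their mutual markers only.  Returns a DataFrame with cell_id, label,
    score, runner_up_label, delta (score minus runner-up score, >= 0).
    """
    query_genes = np.asarray(query_genes, dtype=object)
    query_cells = np.asarray(query_cells, dtype=object)
    ref_gene_pos = {g: i for i, g in enumerate(reference.genes)}
    common_q = np.array([i for i, g in enumerate(query_genes) if g in ref_gene_pos])
    if len(common_q) < MIN_COMMON_GENES:
        raise ValidationError(
            f"only {len(common_q)} genes shared with the reference "
            f"(need >= {MIN_COMMON_GENES})"
        )
    common_r = np.array([ref_gene_pos[g] for g in query_genes[common_q]])
    ref_expr = reference.expr[common_r]
    n_classes = len(reference.broad_classes)

    query = sp.csr_matrix(query) if sp.issparse(query) else np.asarray(query, float)

    def _dense_block(feature_idx: np.ndarray, cell_idx: np.ndarray) -> np.ndarray:
        rows = common_q[feature_idx]
        if sp.issparse(query):
            return np.asarray(query[np.ix_(rows, cell_idx)].todense())
        return query[np.ix_(rows, cell_idx)]

    feat = _pairwise_marker_space(ref_expr, marker_top_n)
    all_cells = np.arange(len(query_cells))
    scores = _spearman_scores(_dense_block(feat, all_cells), ref_expr[feat])

    if n_classes == 1:
        labels = np.repeat(reference.broad_classes[0], len(query_cells))
        return pd.DataFrame(
            {
                "cell_id": query_cells,
                "label": labels,
                "score": scores[:, 0],
                "runner_up_label": labels,
                "delta": 0.0,
            }
        )

    # initial top-2 per cell; argmax with ties toward earlier class order
    order = np.argsort(-scores, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]

    final_label = best.copy()
    final_score = scores[all_cells, best].copy()
    runner_label = second.copy()
    runner_score = scores[all_cells, second].copy()

    # refinement restricted to each top-2 pair's mutual markers
    pair_key = np.where(best < second, best * n_classes + second, second * n_classes + best)
    for key in np.unique(pair_key):
        a, b = int(key) // n_classes, int(key) % n_classes
        cells = np.flatnonzero(pair_key == key)
        feat_ab = _pairwise_marker_space(ref_expr, marker_top_n, pairs=[(a, b), (b, a)])
        sub = _spearman_scores(_dense_block(feat_ab, cells), ref_expr[feat_ab][:, [a, b]])
        winner_is_b = sub[:, 1] > sub[:, 0]  # tie keeps earlier class a
        final_label[cells] = np.where(winner_is_b, b, a)
        final_score[cells] = np.where(winner_is_b, sub[:, 1], sub[:, 0])
        runner_label[cells] = np.where(winner_is_b, a, b)
        runner_score[cells] = np.where(winner_is_b, sub[:, 0], sub[:, 1])

    return pd.DataFrame(
        {
            "cell_id": query_cells,
            "label": reference.broad_classes[final_label],
            "score": final_score,
            "runner_up_label": reference.broad_classes[runner_label],
            "delta": np.maximum(final_score - runner_score, 0.0),
        }
    )


def annotate_cells(
    counts: CountMatrix,
    reference: ReferenceProfile,
    scale: float = 1e4,
    marker_top_n: int = 50,
) -> pd.DataFrame:
    """Convenience wrapper: log-normalize a count matrix and assign labels."""
    normalized = log_normalize(counts, scale=scale)
    return assign_labels(normalized, counts.gene_ids, counts.cell_ids, reference, marker_top_n)


def read_reference(expr_path, mapping_path=None) -> ReferenceProfile:
    """Load a gene x fine-label CSV (first column = gene id) and an optional
    two-column fine,broad mapping CSV; identity mapping when absent."""
    fine = pd.read_csv(expr_path, index_col=0)
    if mapping_path is None:
        mapping = {c: c for c in fine.columns}
    else:
        mtab = pd.read_csv(mapping_path)
        if mtab.shape[1] < 2:
            raise ValidationError("mapping CSV needs two columns (fine, broad)")
        mapping = dict(zip(mtab.iloc[:, 0].astype(str), mtab.iloc[:, 1].astype(str)))
    return collapse_reference(fine, mapping)
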