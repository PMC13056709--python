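"""Preranked permutation GSEA over day-14 vs day-0 within-type DE.

Genes are ranked by log2 fold change (descending, ties lexicographic), the
classic weighted Kolmogorov-Smirnov running sum gives each gene set an
enrichment score, and a gene-label permutation null (random sets of the same
size) yields sign-stratified normalized enrichment scores and permutation
p-values.  A set "passes" when |NES| exceeds the threshold (default 1.5) and
its BH-adjusted permutation p-value clears alpha (default 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import DEConfig, bh_adjust, run_de
from .io import CountMatrix, GeneSetCollection, ValidationError


def temporal_de(
    counts: CountMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    de_config: DEConfig | None = None,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Within-type day-14 vs day-0 differential expression."""
    active = cells
    if "keep" in active.columns:
        active = active[active["keep"].astype(bool)]
    mine = active[active["label"] == cell_type]
    d14 = mine.loc[mine["timepoint"] == "day14", "cell_id"].tolist()
    d0 = mine.loc[mine["timepoint"] == "day0", "cell_id"].tolist()
    if len(d14) < min_cells or len(d0) < min_cells:
        raise ValidationError(
            f"{cell_type}: needs >= {min_cells} cells at both timepoints "
            f"(day14={len(d14)}, day0={len(d0)})"
        )
    return run_de(counts, d14, d0, de_config)


def rank_statistic(de_table: pd.DataFrame) -> pd.DataFrame:
    """(gene, stat) ranking by log2fc, descending; ties lexicographic by id."""
    if de_table.empty:
        raise ValidationError("empty DE table")
    ranked = de_table[["gene_id", "log2fc"]].rename(columns={"log2fc": "stat"})
    return ranked.sort_values(
        ["stat", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile.

    Hits increment by |stat|^weight / sum_hits |stat|^weight; misses decrement
    by 1/(N - N_hits); the score is the running sum's signed extremum.
    """
    genes = ranked["gene_id"].to_numpy(dtype=object)
    stats = ranked["stat"].to_numpy(dtype=float)
    hit = np.isin(genes, list(gene_set))
    n, n_hits = len(genes), int(hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValidationError("gene set covers the whole ranked list")
    w = np.abs(stats) ** weight
    w_hits = np.where(hit, w, 0.0)
    norm = w_hits.sum()
    inc = w_hits / norm if norm > 0 else hit / n_hits  # all-zero stats: uniform
    dec = np.where(hit, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(inc - dec)
    # extremum: ties in |deviation| resolve to the positive side, matching
    # the vectorized permutation path
    max_dev = float(running.max())
    min_dev = float(min(running.min(), 0.0))
    es = max_dev if max_dev >= -min_dev else min_dev
    return es, running


def _es_from_positions(pos: np.ndarray, absw: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets (rows).

    ``pos``: (m, k) sorted ascending hit positions; ``absw``: |stat|^weight
    over the full ranking.  The running sum is piecewise linear, so its
    extremum lies at a hit (candidate max) or just before one (candidate min).
    """
    m, k = pos.shape
    w = absw[pos]
    norm = w.sum(axis=1, keepdims=True)
    uniform = norm == 0
    if uniform.any():
        w = np.where(uniform, 1.0, w)
        norm = np.where(uniform, float(k), norm)
    cumw = np.cumsum(w, axis=1) / norm
    j = np.arange(k)[None, :]
    dec = 1.0 / (n - k)
    at_hit = cumw - (pos - j) * dec
    before_hit = np.concatenate([np.zeros((m, 1)), cumw[:, :-1]], axis=1) - (pos - j) * dec
    max_dev = at_hit.max(axis=1)
    min_dev = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def gsea(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    nes_min: float = 1.5,
    alpha: float = 0.05,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    The null resamples ``n_perm`` random position sets of matching size from
    the ranking; NES divides ES by the mean |null ES| of matching sign;
    ``p_perm = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign)``.
    BH across sets; ``passes`` requires |NES| > nes_min and p_adj < alpha.
    Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    genes = ranked["gene_id"].to_numpy(dtype=object)
    stats = ranked["stat"].to_numpy(dtype=float)
    n = len(genes)
    absw = np.abs(stats) ** weight
    rng = np.random.default_rng(seed)

    records = []
    for name, members in collection:
        present = np.flatnonzero(np.isin(genes, list(members)))
        k = len(present)
        if k == 0:
            raise ValidationError(f"gene set {name!r} does not intersect the ranking")
        if k >= n:
            raise ValidationError(f"gene set {name!r} covers the whole ranking")
        es = float(_es_from_positions(present[None, :], absw, n)[0])

        null_pos = np.sort(
            np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k], axis=1
        )
        null_es = _es_from_positions(null_pos, absw, n)

        same_sign = null_es > 0 if es > 0 else (null_es < 0 if es < 0 else null_es == 0)
        pool = null_es[same_sign]
        if es == 0:
            nes, p_perm = 0.0, 1.0
        else:
            if len(pool) > 0:
                nes = es / float(np.abs(pool).mean())
            else:  # no same-sign nulls at all: normalize by overall magnitude
                nes = es / float(np.abs(null_es).mean())
            p_perm = (1.0 + float((np.abs(pool) >= abs(es)).sum())) / (1.0 + len(pool))
        records.append((name, k, es, nes, min(p_perm, 1.0)))

    table = pd.DataFrame(records, columns=["set_name", "size", "es", "nes", "p_perm"])
    table["p_adj"] = bh_adjust(table["p_perm"].to_numpy())
    table["passes"] = (table["nes"].abs() > nes_min) & (table["p_adj"] < alpha)
    return table
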