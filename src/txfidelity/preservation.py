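"""Cross-timepoint transcriptional identity preservation.

For each cell type the day-0 profile is its log2 fold change against all
other day-0 cells; the day-14 profile substitutes the type's day-14 cells in
as the target while keeping the day-0 rest as baseline (the type's own day-0
counterpart is removed from the baseline).  Significantly variable genes from
any profile are compiled into a fixed gene universe, and the preservation
statistic is the Pearson correlation of a type's day-14 vs day-0 log2FC
vectors over that universe — all universe genes included regardless of
per-profile significance.  High diagonal correlations mean the type's
distinguishing expression profile survived the culture interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .de import DEConfig, filter_low_expression, run_de
from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

MIN_UNIVERSE_GENES = 3


@dataclass
class FoldChangeProfile:
    """One cell type's DE profile at one timepoint (vs the day-0 rest)."""

    cell_type: str
    timepoint: str
    table: pd.DataFrame  # run_de output, indexed implicitly by gene order
    n_target_cells: int

    @property
    def significant_genes(self) -> frozenset:
        return frozenset(self.table.loc[self.table["significant"], "gene_id"])

    def log2fc_for(self, universe) -> np.ndarray:
        """Universe-aligned log2FC vector; missing universe genes are an error."""
        series = self.table.set_index("gene_id")["log2fc"]
        missing = [g for g in universe if g not in series.index]
        if missing:
            raise ValidationError(
                f"{self.cell_type}@{self.timepoint}: {len(missing)} universe genes "
                f"missing from the DE table (e.g. {missing[:3]})"
            )
        return series.loc[list(universe)].to_numpy(dtype=float)


@dataclass
class PreservationMatrix:
    """Pearson r of day-14 vs day-0 log2FC profiles (rows: day-14 types)."""

    r: pd.DataFrame
    n_genes_used: int

    def to_long(self) -> pd.DataFrame:
        long = self.r.stack(future_stack=True).rename("r").reset_index()
        long.columns = ["t14", "t0", "r"]
        long["n_genes_used"] = self.n_genes_used
        return long


def _active_cells(cells: pd.DataFrame, aggregate=None) -> pd.DataFrame:
    out = cells
    if "keep" in out.columns:
        out = out[out["keep"].astype(bool)]
    if aggregate is not None:
        out = out[out["sample_id"].isin(set(aggregate))]
    if out.empty:
        raise ValidationError("no usable cells after keep/aggregate filtering")
    if "label" not in out.columns or "timepoint" not in out.columns:
        raise ValidationError("cells need 'label' and 'timepoint' columns")
    return out


def build_profiles(
    counts: CountMatrix,
    cells: pd.DataFrame,
    aggregate=None,
    min_cells: int = 20,
    de_config: DEConfig | None = None,
    exclude_day0_counterpart: bool = True,
) -> tuple[dict[str, FoldChangeProfile], dict[str, FoldChangeProfile]]:
    """DE profiles per cell type for both timepoints.

    Day-0 profile of type t: t@day0 vs all other day-0 cells.  Day-14 profile
    of type t: t@day14 vs the same day-0 rest (t's day-0 counterpart excluded
    from the baseline by default; ``exclude_day0_counterpart=False`` keeps it,
    for sensitivity analysis).  ``aggregate`` pools the listed samples' cells
    before any DE.  Types below ``min_cells`` at a timepoint are skipped with
    a logged notice.  Returns (day0_profiles, day14_profiles) keyed by type.
    """
    de_config = de_config or DEConfig()
    active = _active_cells(cells, aggregate)
    d0 = active[active["timepoint"] == "day0"]
    d14 = active[active["timepoint"] == "day14"]
    if d0.empty or d14.empty:
        raise ValidationError("cells must span both timepoints")

    # The low-expression floor ("average occurrence < 1 count") is applied
    # once across the whole dataset (all active cells of both timepoints), so
    # every profile shares one gene axis and universe alignment is guaranteed.
    used = counts.subset_cells(np.array(active["cell_id"], dtype=object))
    gene_mask = filter_low_expression(used, de_config.min_mean_count)
    if not gene_mask.any():
        raise ValidationError("no genes pass the dataset-level expression floor")
    counts = counts.subset_genes(gene_mask)
    de_config = replace(de_config, min_mean_count=0.0)

    day0_ids_by_type = {t: g["cell_id"].tolist() for t, g in d0.groupby("label", sort=False)}
    all_day0 = d0["cell_id"].tolist()

    profiles_d0: dict[str, FoldChangeProfile] = {}
    for t, ids in day0_ids_by_type.items():
        if len(ids) < min_cells:
            logger.info("skipping %s@day0: %d < %d cells", t, len(ids), min_cells)
            continue
        baseline = [c for c in all_day0 if c not in set(ids)]
        table = run_de(counts, ids, baseline, de_config)
        profiles_d0[t] = FoldChangeProfile(t, "day0", table, len(ids))

    profiles_d14: dict[str, FoldChangeProfile] = {}
    for t, g in d14.groupby("label", sort=False):
        ids = g["cell_id"].tolist()
        if len(ids) < min_cells:
            logger.info("skipping %s@day14: %d < %d cells", t, len(ids), min_cells)
            continue
        if exclude_day0_counterpart:
            counterpart = set(day0_ids_by_type.get(t, []))
            baseline = [c for c in all_day0 if c not in counterpart]
        else:
            baseline = list(all_day0)
        table = run_de(counts, ids, baseline, de_config)
        profiles_d14[t] = FoldChangeProfile(t, "day14", table, len(ids))
    return profiles_d0, profiles_d14


def compile_gene_universe(profiles, include_day14: bool = True) -> list[str]:
    """Sorted union of genes significant in at least one included profile.

    ``profiles`` may be any iterable of FoldChangeProfile; day-14 profiles are
    included only when ``include_day14`` is set.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles supplied")
    universe: set[str] = set()
    for p in profiles:
        if p.timepoint == "day14" and not include_day14:
            continue
        universe |= p.significant_genes
    if not universe:
        raise ValidationError("no significantly variable genes in any profile")
    return sorted(universe)


def preservation_matrix(
    profiles_d0: dict[str, FoldChangeProfile],
    profiles_d14: dict[str, FoldChangeProfile],
    universe,
) -> PreservationMatrix:
    """Pearson correlation of each day-14 type's log2FC vector against every
    day-0 type's, over the fixed gene universe.

    A constant vector has no defined correlation; such entries are NaN
    (reported as undefined, never coerced to 0).
    """
    universe = list(universe)
    if len(universe) < MIN_UNIVERSE_GENES:
        raise ValidationError(f"universe has {len(universe)} genes, need >= {MIN_UNIVERSE_GENES}")
    rows = list(profiles_d14)
    cols = list(profiles_d0)
    if not rows or not cols:
        raise ValidationError("need at least one profile per timepoint")
    vec14 = {t: profiles_d14[t].log2fc_for(universe) for t in rows}
    vec0 = {t: profiles_d0[t].log2fc_for(universe) for t in cols}
    r = np.full((len(rows), len(cols)), np.nan)
    for i, t14 in enumerate(rows):
        x = vec14[t14]
        for j, t0 in enumerate(cols):
            y = vec0[t0]
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # undefined, stays NaN
            r[i, j] = float(np.corrcoef(x, y)[0, 1])
    return PreservationMatrix(
        r=pd.DataFrame(r, index=pd.Index(rows, name="t14"), columns=pd.Index(cols, name="t0")),
        n_genes_used=len(universe),
    )


def composition(cells: pd.DataFrame, group_by: str = "sample_id") -> pd.DataFrame:
    """Cell counts and fractions per (group, timepoint, cell type).

    Fractions within each (group, timepoint) sum to 1.
    """
    active = cells
    if "keep" in active.columns:
        active = active[active["keep"].astype(bool)]
    if "label" not in active.columns:
        raise ValidationError("cells need a 'label' column")
    grouped = (
        active.groupby([group_by, "timepoint", "label"], sort=True, observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = grouped.groupby([group_by, "timepoint"], observed=True)["n_cells"].transform("sum")
    grouped["fraction"] = grouped["n_cells"] / totals
    return grouped
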