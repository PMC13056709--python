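"""Synthetic paired day-0 / day-14 snRNA-seq experiment generator.

Emulates the design the downstream statistics are built for: K discrete cell
types with disjoint marker-gene blocks, negative-binomial UMI counts
(variance = mu + phi*mu^2), lognormal per-cell depth factors, a mitochondrial
gene subset, and a day-14 sample whose per-type expression profiles are
drift-perturbed copies of the day-0 profiles, with a shifted cell-type
composition (neuron depletion).  Because the generator knows the truth —
type assignments, log-mean matrices, marker membership — every downstream
stage (QC, annotation, differential expression, preservation correlation)
can be validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError, namespace_cells, write_10x


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    day0_fraction: float
    day14_fraction: float


#: Default composition: four broad brain cell classes with the neuronal share
#: halved at day 14 (the depletion seen in cultured slices).
DEFAULT_CELL_TYPES = (
    CellTypeSpec("Glutamatergic_neurons", 0.40, 0.20),
    CellTypeSpec("Astrocytes", 0.25, 0.30),
    CellTypeSpec("Oligodendrocytes", 0.20, 0.28),
    CellTypeSpec("Microglia", 0.15, 0.22),
)


@dataclass
class SimConfig:
    """Parameters of the paired-timepoint generator.

    ``base_mean`` is the expected count per gene per cell before the per-gene
    lognormal spread ``gene_sigma``; ``dispersion`` is the NB overdispersion
    phi (variance = mu + phi*mu^2, phi = 0 means Poisson); ``drift_sd`` is the
    standard deviation of the independent Gaussian perturbation added to each
    (gene, type) log-mean at day 14 — the knob that stands in for two weeks of
    culture.  ``allocation`` selects deterministic largest-remainder rounding
    of the type fractions (exact composition, the default) or multinomial
    sampling.
    """

    n_genes: int = 2000
    n_cells_day0: int = 3000
    n_cells_day14: int = 3000
    cell_types: Sequence[CellTypeSpec] = DEFAULT_CELL_TYPES
    n_markers_per_type: int = 50
    marker_fold: float = 8.0
    base_mean: float = 0.8
    gene_sigma: float = 1.0
    dispersion: float = 0.5
    libsize_sigma: float = 0.35
    mito_fraction: float = 0.02
    mito_mean_scale: float = 1.0
    drift_sd: float = 0.3
    seed: int = 0
    allocation: str = "deterministic"
    sample_id_day0: str = "S1"
    sample_id_day14: str = "S1"

    def __post_init__(self) -> None:
        self.cell_types = tuple(
            CellTypeSpec(*t) if not isinstance(t, CellTypeSpec) else t
            for t in self.cell_types
        )
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate cell type names")
        for attr, frac in (
            ("day0", [t.day0_fraction for t in self.cell_types]),
            ("day14", [t.day14_fraction for t in self.cell_types]),
        ):
            if abs(sum(frac) - 1.0) > 1e-9:
                raise ValidationError(f"{attr} fractions sum to {sum(frac)}, not 1")
            if any(f < 0 or f > 1 for f in frac):
                raise ValidationError(f"{attr} fractions outside [0, 1]")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValidationError("marker blocks exceed the gene count")
        if self.marker_fold <= 1:
            raise ValidationError("marker_fold must exceed 1")
        if self.base_mean <= 0:
            raise ValidationError("base_mean must be positive")
        for attr in ("dispersion", "libsize_sigma", "drift_sd", "gene_sigma"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{attr} must be >= 0")
        if not 0 <= self.mito_fraction < 1:
            raise ValidationError("mito_fraction must lie in [0, 1)")
        if self.allocation not in ("deterministic", "multinomial"):
            raise ValidationError(f"unknown allocation mode {self.allocation!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``type_log_means`` / ``day14_log_means`` are gene x type matrices of
    per-cell log expected counts (before the depth factor); they are equal
    elementwise when ``drift_sd`` is 0.
    """

    gene_ids: np.ndarray
    type_names: tuple
    type_log_means: np.ndarray
    day14_log_means: np.ndarray
    marker_assignment: dict[str, str]
    cell_labels_day0: np.ndarray
    cell_labels_day14: np.ndarray
    mito_genes: frozenset
    config: SimConfig

    def markers_of(self, type_name: str) -> list[str]:
        return sorted(g for g, t in self.marker_assignment.items() if t == type_name)


def allocate_counts(fractions: Sequence[float], n: int, rng=None) -> np.ndarray:
    """Per-type cell counts from fractions.

    Largest-remainder rounding (exact composition) when ``rng`` is None,
    multinomial sampling otherwise.
    """
    fractions = np.asarray(fractions, dtype=float)
    if rng is not None:
        return rng.multinomial(n, fractions / fractions.sum())
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    # ties broken toward earlier types for determinism
    order = np.lexsort((np.arange(len(fractions)), -remainder))
    counts[order[:short]] += 1
    return counts


def _nb_sample(rng, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def generate_experiment(config: SimConfig) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Draw a paired day-0/day-14 experiment.

    Counts for cell c of type k at gene g are NB with mean
    ``L_c * exp(M[g, k])`` where ``L_c`` is the cell's lognormal depth factor
    and ``M`` is the timepoint's log-mean matrix.  Day-14 log-means are the
    day-0 log-means plus independent ``N(0, drift_sd^2)`` perturbations per
    (gene, type); markers are perturbed like any other gene.  Identical seeds
    give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, len(config.cell_types)
    type_names = tuple(t.name for t in config.cell_types)

    n_mito = int(round(config.mito_fraction * G))
    gene_ids = np.array(
        [f"G{i + 1:05d}" for i in range(G - n_mito)]
        + [f"MT-{i + 1}" for i in range(n_mito)],
        dtype=object,
    )
    mito_genes = frozenset(gene_ids[G - n_mito :])

    # per-gene lognormal base means, normalized so E[mean] = base_mean
    log_base = (
        np.log(config.base_mean)
        - config.gene_sigma**2 / 2
        + config.gene_sigma * rng.standard_normal(G)
    )
    if n_mito and config.mito_mean_scale != 1.0:
        log_base[G - n_mito :] += np.log(config.mito_mean_scale)

    M0 = np.tile(log_base[:, None], (1, K))
    marker_assignment: dict[str, str] = {}
    for k in range(K):
        block = slice(k * config.n_markers_per_type, (k + 1) * config.n_markers_per_type)
        M0[block, k] += np.log(config.marker_fold)
        for g in gene_ids[block]:
            marker_assignment[g] = type_names[k]

    M14 = M0 + rng.normal(0.0, config.drift_sd, size=(G, K))

    def _one_timepoint(n_cells: int, fractions, M: np.ndarray, sample_id: str, tag: str):
        alloc_rng = rng if config.allocation == "multinomial" else None
        per_type = allocate_counts(fractions, n_cells, alloc_rng)
        for spec, n_k in zip(config.cell_types, per_type):
            frac = getattr(spec, f"{tag.replace('d', 'day')}_fraction")
            if frac > 0 and n_k == 0:
                raise ValidationError(
                    f"type {spec.name!r} requested fraction {frac} but received 0 "
                    f"cells at {tag}; increase n_cells"
                )
        labels = np.repeat(type_names, per_type)
        depth = np.exp(
            config.libsize_sigma * rng.standard_normal(n_cells)
            - config.libsize_sigma**2 / 2
        )
        counts = np.empty((G, n_cells), dtype=np.int64)
        start = 0
        for k, n_k in enumerate(per_type):
            if n_k == 0:
                continue
            mu = np.exp(M[:, k])[:, None] * depth[None, start : start + n_k]
            counts[:, start : start + n_k] = _nb_sample(rng, mu, config.dispersion)
            start += n_k
        barcodes = [f"{tag}_cell{i + 1:05d}" for i in range(n_cells)]
        cm = CountMatrix(
            sp.csr_matrix(counts), gene_ids, namespace_cells(sample_id, barcodes)
        )
        return cm, np.asarray(labels, dtype=object)

    day0, labels0 = _one_timepoint(
        config.n_cells_day0,
        [t.day0_fraction for t in config.cell_types],
        M0,
        config.sample_id_day0,
        "d0",
    )
    day14, labels14 = _one_timepoint(
        config.n_cells_day14,
        [t.day14_fraction for t in config.cell_types],
        M14,
        config.sample_id_day14,
        "d14",
    )
    truth = SimTruth(
        gene_ids=gene_ids,
        type_names=type_names,
        type_log_means=M0,
        day14_log_means=M14,
        marker_assignment=marker_assignment,
        cell_labels_day0=labels0,
        cell_labels_day14=labels14,
        mito_genes=mito_genes,
        config=config,
    )
    return day0, day14, truth


def cell_table_from_truth(
    day0: CountMatrix, day14: CountMatrix, truth: SimTruth
) -> pd.DataFrame:
    """Per-cell metadata table (cell_id, sample_id, timepoint, true_label)."""
    cfg = truth.config
    frames = []
    for cm, labels, tp, sample in (
        (day0, truth.cell_labels_day0, "day0", cfg.sample_id_day0),
        (day14, truth.cell_labels_day14, "day14", cfg.sample_id_day14),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cm.cell_ids,
                    "sample_id": sample,
                    "timepoint": tp,
                    "true_label": labels,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_experiment(
    outdir: str | Path,
    day0: CountMatrix,
    day14: CountMatrix,
    truth: SimTruth,
    compress: bool = False,
) -> None:
    """Write 10x triplets (day0/, day14/), cells.csv, and truth.json."""
    outdir = Path(outdir)
    write_10x(outdir / "day0", day0, compress=compress)
    write_10x(outdir / "day14", day14, compress=compress)
    cell_table_from_truth(day0, day14, truth).to_csv(outdir / "cells.csv", index=False)
    payload = {
        "type_names": list(truth.type_names),
        "marker_assignment": truth.marker_assignment,
        "mito_genes": sorted(truth.mito_genes),
        "type_log_means": truth.type_log_means.tolist(),
        "day14_log_means": truth.day14_log_means.tolist(),
        "gene_ids": truth.gene_ids.tolist(),
        "config": {
            **{
                k: v
                for k, v in asdict(truth.config).items()
                if k != "cell_types"
            },
            "cell_types": [list(t) for t in asdict(truth.config)["cell_types"]],
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh)


def reference_from_truth(truth: SimTruth) -> pd.DataFrame:
    """Synthetic fine-label reference: expected day-0 expression per type.

    Stands in for an external median-expression atlas; columns are the true
    type profiles, so an identity fine-to-broad mapping applies.
    """
    return pd.DataFrame(
        np.exp(truth.type_log_means),
        index=pd.Index(truth.gene_ids, name="gene_id"),
        columns=list(truth.type_names),
    )


def reference_profile_from_truth(truth: SimTruth):
    """Collapsed (identity-mapped) ReferenceProfile built from the truth."""
    from .annotate import collapse_reference

    fine = reference_from_truth(truth)
    return collapse_reference(fine, {t: t for t in truth.type_names})
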