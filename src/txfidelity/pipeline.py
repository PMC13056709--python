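"""End-to-end pipeline orchestration from a single YAML/JSON config.

Stage order: simulate-or-read -> QC -> annotate -> fold-change profiles ->
gene universe -> preservation matrix -> composition -> temporal DE -> GSEA.
Every output is a CSV (plus a JSON manifest with per-file SHA-256 hashes,
stage log and seed), and re-running an identical config reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import io as txio
from . import simulate as sim
from .de import DEConfig
from .enrichment import gsea, rank_statistic, temporal_de
from .io import CountMatrix, ValidationError
from .preservation import (
    build_profiles,
    compile_gene_universe,
    composition,
    preservation_matrix,
)
from .qc import QCThresholds, apply_qc, compute_metrics

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see examples/pipeline_config.yaml)."""

    outdir: Path
    seed: int
    simulate: dict | None = None
    counts_day0: Path | None = None
    counts_day14: Path | None = None
    cells: Path | None = None
    reference: Path | None = None
    reference_mapping: Path | None = None
    gene_sets: Path | None = None
    mito_prefix: str = "MT-"
    qc: QCThresholds = field(default_factory=QCThresholds)
    de: DEConfig = field(default_factory=DEConfig)
    marker_top_n: int = 50
    log_norm_scale: float = 1e4
    aggregate: list | None = None
    min_cells: int = 20
    include_day14: bool = True
    n_perm: int = 1000
    nes_min: float = 1.5

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        if "outdir" not in raw or "seed" not in raw:
            raise ValidationError("config requires 'outdir' and 'seed'")

        def _p(key):
            return (base / raw[key]) if raw.get(key) else None

        cfg = cls(
            outdir=base / raw["outdir"],
            seed=int(raw["seed"]),
            simulate=raw.get("simulate"),
            counts_day0=_p("counts_day0"),
            counts_day14=_p("counts_day14"),
            cells=_p("cells"),
            reference=_p("reference"),
            reference_mapping=_p("reference_mapping"),
            gene_sets=_p("gene_sets"),
            mito_prefix=raw.get("mito_prefix", "MT-"),
            qc=QCThresholds(**raw.get("qc", {})),
            de=DEConfig(**raw.get("de", {})),
            marker_top_n=int(raw.get("marker_top_n", 50)),
            log_norm_scale=float(raw.get("log_norm_scale", 1e4)),
            aggregate=raw.get("aggregate"),
            min_cells=int(raw.get("min_cells", 20)),
            include_day14=bool(raw.get("include_day14", True)),
            n_perm=int(raw.get("n_perm", 1000)),
            nes_min=float(raw.get("nes_min", 1.5)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            for key in ("counts_day0", "counts_day14", "cells"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ValidationError(f"input path {key!r} missing: {path}")
            if self.reference is not None and not Path(self.reference).exists():
                raise ValidationError(f"reference path missing: {self.reference}")
        if self.gene_sets is not None and not Path(self.gene_sets).exists():
            raise ValidationError(f"gene_sets path missing: {self.gene_sets}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_to_disk(config: sim.SimConfig, outdir: str | Path) -> None:
    """Generate and write a synthetic experiment plus a truth-derived
    synthetic reference and a synthetic gene-set collection."""
    outdir = Path(outdir)
    day0, day14, truth = sim.generate_experiment(config)
    sim.write_experiment(outdir, day0, day14, truth)
    sim.reference_from_truth(truth).to_csv(outdir / "reference_synthetic.csv")
    rng = np.random.default_rng(config.seed + 1)
    sets = {
        f"SYN_SET_{i + 1:02d}": frozenset(
            rng.choice(truth.gene_ids, size=30, replace=False).tolist()
        )
        for i in range(25)
    }
    txio.write_gmt(outdir / "gene_sets_synthetic.gmt", txio.GeneSetCollection(sets))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    def _write(name: str, frame: pd.DataFrame, stage: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest["outputs"][name] = _sha256(path)
        manifest["stages"].append({"stage": stage, "output": name, "rows": len(frame)})

    def _stage_error(stage: str, exc: Exception):
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate or read -------------------------------------------------
    if config.simulate is not None:
        sim_cfg = sim.SimConfig(**{**config.simulate, "seed": config.seed})
        sim_dir = out / "sim"
        simulate_to_disk(sim_cfg, sim_dir)
        day0 = txio.read_10x(sim_dir / "day0")
        day14 = txio.read_10x(sim_dir / "day14")
        cells_meta = txio.read_cells(sim_dir / "cells.csv")
        reference = ann.read_reference(sim_dir / "reference_synthetic.csv")
        gene_sets_path = config.gene_sets or sim_dir / "gene_sets_synthetic.gmt"
    else:
        day0 = txio.read_10x(config.counts_day0)
        day14 = txio.read_10x(config.counts_day14)
        cells_meta = txio.read_cells(config.cells)
        reference = (
            ann.read_reference(config.reference, config.reference_mapping)
            if config.reference
            else None
        )
        gene_sets_path = config.gene_sets
    counts = CountMatrix.concat_cells([day0, day14])
    txio.validate_cell_table(cells_meta, counts)
    logger.info("loaded %d genes x %d cells", counts.n_genes, counts.n_cells)

    # --- QC ---------------------------------------------------------------
    mito = [g for g in counts.gene_ids if str(g).startswith(config.mito_prefix)]
    metrics = compute_metrics(counts, mito, meta=cells_meta)
    cells_qc = apply_qc(metrics, config.qc)
    _write("cells_qc.csv", cells_qc, "qc")
    kept = cells_qc["keep"].sum()
    logger.info("qc: kept %d / %d cells", kept, len(cells_qc))
    if kept == 0:
        raise ValidationError("stage 'qc' failed: no cells pass QC")

    # --- annotation -------------------------------------------------------
    kept_cells = cells_qc.loc[cells_qc["keep"], "cell_id"].tolist()
    sub = counts.subset_cells(np.array(kept_cells, dtype=object))
    if reference is not None:
        labels = ann.annotate_cells(
            sub, reference, scale=config.log_norm_scale, marker_top_n=config.marker_top_n
        )
    elif "label" in cells_qc.columns or "true_label" in cells_qc.columns:
        col = "label" if "label" in cells_qc.columns else "true_label"
        labels = cells_qc.loc[cells_qc["keep"], ["cell_id", col]].rename(
            columns={col: "label"}
        )
    else:
        raise ValidationError(
            "stage 'annotate' failed: no reference and no precomputed labels"
        )
    _write("labels.csv", labels, "annotate")

    cells_final = cells_qc.merge(
        labels[["cell_id", "label"]], on="cell_id", how="left", suffixes=("_meta", "")
    )

    # --- profiles / universe / preservation / composition -----------------
    p0, p14 = build_profiles(
        counts,
        cells_final,
        aggregate=config.aggregate,
        min_cells=config.min_cells,
        de_config=config.de,
    )
    prof_rows = [
        {"cell_type": p.cell_type, "timepoint": p.timepoint, **row}
        for p in [*p0.values(), *p14.values()]
        for row in p.table.to_dict("records")
    ]
    _write("profiles.csv", pd.DataFrame(prof_rows), "profiles")

    universe = compile_gene_universe(
        [*p0.values(), *p14.values()], include_day14=config.include_day14
    )
    _write("gene_universe.csv", pd.DataFrame({"gene_id": universe}), "universe")

    pres = preservation_matrix(p0, p14, universe)
    _write("preservation_long.csv", pres.to_long(), "preservation")
    matrix_csv = pres.r.reset_index()
    _write("preservation_matrix.csv", matrix_csv, "preservation")

    comp = composition(cells_final)
    _write("composition.csv", comp, "composition")

    # --- temporal DE + GSEA ----------------------------------------------
    shared_types = [t for t in p0 if t in p14]
    gsea_frames = []
    if gene_sets_path is not None:
        collection = txio.read_gmt(gene_sets_path)
        for t in shared_types:
            de_t = temporal_de(counts, cells_final, t, config.de, config.min_cells)
            ranked = rank_statistic(de_t)
            res = gsea(
                ranked,
                collection,
                n_perm=config.n_perm,
                seed=config.seed,
                nes_min=config.nes_min,
                alpha=config.de.alpha,
            )
            res.insert(0, "cell_type", t)
            gsea_frames.append(res)
        _write("gsea.csv", pd.concat(gsea_frames, ignore_index=True), "gsea")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
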