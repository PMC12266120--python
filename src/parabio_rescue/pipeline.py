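"""End-to-end orchestration: simulate (optional) -> QC -> normalize ->
cell typing -> differential expression -> rescue classification ->
gene-set scoring -> candidate prioritization, with deterministic
seeding, logged stage timing, and a machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .datatypes import CountMatrix, GeneSetCollection, UNASSIGNED, ValidationError
from .deg import CONTRASTS, find_all_degs
from .preprocess import QCThresholds, assign_cell_types, normalize, qc_filter
from .prioritize import frequency_rank, overlap_with_collections
from .rescue import classify_cell_type, pr_gene_union, responsiveness
from .scoring import compare_scores, module_score
from .simulate import GeneratorParams, generate_dataset, write_dataset

REPORT_SCHEMA_VERSION = 1

#: Thresholds whose defaults mirror the published analysis protocol; all
#: others are this package's own choices.
PROTOCOL_DEFAULTS = {"min_genes", "max_genes", "max_pct_mito", "fc_threshold", "alpha"}


@dataclass
class RunConfig:
    """One pipeline run: data source, thresholds and scopes.

    Either ``input_dir`` (an existing counts bundle with annotation and
    markers) or ``simulate`` (generator parameters) must be set.
    """

    out_dir: str
    seed: int = 0
    input_dir: str | None = None
    simulate: GeneratorParams | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    fc_threshold: float = 0.25
    alpha: float = 0.05
    min_cells: int = 3
    rescue_mode: str = "strict"
    cell_typing: str = "markers"  # "markers" | "annotation"
    min_margin: float = 0.05
    score_n_bins: int = 25
    score_n_ctrl: int = 100
    score_sets_gmt: str | None = None
    collections_gmt: list[str] = field(default_factory=list)
    frequency_scope: list[str] = field(default_factory=lambda: ["Aged", "Ahet"])

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValidationError("exactly one of input_dir or simulate must be set")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.fc_threshold < 0:
            raise ValidationError("fc_threshold must be non-negative")
        if self.cell_typing not in ("markers", "annotation"):
            raise ValidationError("cell_typing must be 'markers' or 'annotation'")
        if unknown := set(self.frequency_scope) - set(CONTRASTS):
            raise ValidationError(f"unknown contrasts in frequency_scope: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("baseline_log10_cp10k", "program_quantile_band"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = GeneratorParams(**sim)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QCThresholds(**raw["qc"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["baseline_log10_cp10k"] = list(sim["baseline_log10_cp10k"])
            sim["program_quantile_band"] = list(sim["program_quantile_band"])
            if isinstance(sim.get("rescue_fraction"), tuple):
                sim["rescue_fraction"] = list(sim["rescue_fraction"])
            if isinstance(sim.get("accel_fraction"), tuple):
                sim["accel_fraction"] = list(sim["accel_fraction"])
            d["simulate"] = sim
        d["qc"] = dataclasses.asdict(self.qc)
        return d

    def analysis_dict(self) -> dict:
        """Config without the output location: the analysis parameters
        that determine results byte-for-byte."""
        d = self.to_dict()
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage derived seed: stable hash of the stage name mixed with
    the master seed, kept below 2**31 so stages are independently
    reproducible."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) & 0x7FFFFFFF


def _log(stage: str, started: float, **info) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    print(f"[{stage}] {time.perf_counter() - started:.2f}s {extra}", file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage, write all intermediate tables under
    ``cfg.out_dir``, and return the JSON-serializable run report.

    Identical config and seed produce byte-identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.analysis_dict(),
        "protocol_defaults": sorted(PROTOCOL_DEFAULTS),
        "stages": {},
        "flags": [],
    }

    # --- simulate or load -------------------------------------------------
    t0 = time.perf_counter()
    markers: GeneSetCollection | None = None
    collections: list[GeneSetCollection] = []
    if cfg.simulate is not None:
        params = dataclasses.replace(cfg.simulate, seed=stage_seed(cfg.seed, "simulate"))
        cm, ann, truth = generate_dataset(params)
        write_dataset(out / "dataset", cm, ann, truth)
        markers = truth.marker_collection()
        if truth.aging_db_genes:
            collections.append(truth.aging_collection())
    else:
        cm = pio.read_counts_bundle(cfg.input_dir)
        ann = pio.read_annotation(Path(cfg.input_dir) / "annotation.tsv")
        marker_path = Path(cfg.input_dir) / "markers.gmt"
        if marker_path.exists():
            markers = pio.read_gmt(marker_path)
    for path in cfg.collections_gmt:
        collections.append(pio.read_gmt(path))
    report["stages"]["input"] = {"n_cells": cm.n_cells, "n_genes": cm.n_genes}
    _log("input", t0, cells=cm.n_cells, genes=cm.n_genes)

    # --- QC + normalize ---------------------------------------------------
    t0 = time.perf_counter()
    cm, ann = qc_filter(cm, ann, cfg.qc)
    cm = normalize(cm)
    report["stages"]["preprocess"] = {"n_cells_pass_qc": cm.n_cells}
    _log("preprocess", t0, cells_pass=cm.n_cells)

    # --- cell typing ------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.cell_typing == "markers":
        if markers is None:
            raise ValidationError("cell_typing='markers' but no marker GMT available")
        assignment = assign_cell_types(
            cm, markers, min_margin=cfg.min_margin,
            n_bins=cfg.score_n_bins, n_ctrl=cfg.score_n_ctrl,
            seed=stage_seed(cfg.seed, "cell_typing"),
        )
        ann = ann.copy()
        ann["cell_type"] = assignment["cell_type"].to_numpy()
    n_unassigned = int((ann["cell_type"] == UNASSIGNED).sum())
    pio.write_annotation(ann, out / "annotation_qc.tsv")
    report["stages"]["cell_typing"] = {
        "mode": cfg.cell_typing,
        "n_unassigned": n_unassigned,
        "counts": ann.loc[ann["cell_type"] != UNASSIGNED, "cell_type"]
        .value_counts().sort_index().to_dict(),
    }
    _log("cell_typing", t0, unassigned=n_unassigned)

    # --- differential expression -----------------------------------------
    t0 = time.perf_counter()
    deg_map = find_all_degs(
        cm, ann,
        fc_threshold=cfg.fc_threshold, alpha=cfg.alpha, min_cells=cfg.min_cells,
    )
    all_records = [r for recs in deg_map.values() for r in recs]
    pio.write_deg_table(all_records, out / "degs.tsv")
    report["stages"]["deg"] = {
        "n_records": len(all_records),
        "per_stratum": {f"{ct}:{c}": len(recs) for (ct, c), recs in sorted(deg_map.items())},
    }
    if not all_records:
        report["flags"].append("no DEGs")
    _log("deg", t0, records=len(all_records))

    # --- rescue classification -------------------------------------------
    t0 = time.perf_counter()
    cell_types = sorted({ct for ct, _ in deg_map})
    classifications = [
        classify_cell_type(
            deg_map.get((ct, "Aged"), []),
            deg_map.get((ct, "Ahet"), []),
            deg_map.get((ct, "Yhet"), []),
            mode=cfg.rescue_mode,
        )
        for ct in cell_types
    ]
    for c, ct in zip(classifications, cell_types):
        c.cell_type = ct  # empty strata carry no type information
    resp = responsiveness(classifications) if classifications else pd.DataFrame()
    pio.write_table(resp, out / "responsiveness.tsv")
    rescue_rows = [
        {"cell_type": c.cell_type, "class": cls, "gene": g,
         "aging_direction": dirs[0], "hp_direction": dirs[1]}
        for c in classifications
        for cls, table in (("PR", c.pr_degs), ("PG", c.pg_degs))
        for g, dirs in sorted(table.items())
    ]
    pio.write_table(
        pd.DataFrame(rescue_rows, columns=["cell_type", "class", "gene", "aging_direction", "hp_direction"]),
        out / "rescue.tsv",
    )
    report["stages"]["rescue"] = {
        "mode": cfg.rescue_mode,
        "responsiveness": resp.to_dict(orient="records"),
    }
    _log("rescue", t0, cell_types=len(classifications))

    # --- gene-set scoring -------------------------------------------------
    t0 = time.perf_counter()
    score_sets = None
    if cfg.score_sets_gmt is not None:
        score_sets = pio.read_gmt(cfg.score_sets_gmt)
    elif markers is not None:
        score_sets = markers
    score_frames = []
    comparisons = []
    if score_sets is not None:
        pairs = [("Aiso", "Yiso"), ("Ahet", "Aiso"), ("Yhet", "Yiso")]
        present = set(ann["group"])
        pairs = [p for p in pairs if set(p) <= present]
        for set_name, genes in score_sets:
            res = module_score(
                cm, genes, set_name=set_name,
                n_bins=cfg.score_n_bins, n_ctrl=cfg.score_n_ctrl,
                seed=stage_seed(cfg.seed, f"score:{set_name}"),
            )
            score_frames.append(res.to_frame())
            if pairs:
                comparisons.append(compare_scores(res, ann, pairs))
    pio.write_table(
        pd.concat(score_frames, ignore_index=True) if score_frames else pd.DataFrame(),
        out / "module_scores.tsv",
    )
    pio.write_table(
        pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame(),
        out / "score_comparisons.tsv",
    )
    report["stages"]["scoring"] = {"n_sets": 0 if score_sets is None else len(score_sets)}
    _log("scoring", t0, sets=report["stages"]["scoring"]["n_sets"])

    # --- prioritization ---------------------------------------------------
    t0 = time.perf_counter()
    pr_genes = pr_gene_union(classifications)
    candidates = pd.DataFrame()
    if collections and pr_genes:
        overlap = overlap_with_collections(pr_genes, collections)
        scope_tables = {
            ct: [r for c in cfg.frequency_scope for r in deg_map.get((ct, c), [])]
            for ct in cell_types
        }
        candidates = frequency_rank(overlap, scope_tables)
    pio.write_table(candidates, out / "candidates.tsv")
    report["stages"]["prioritize"] = {
        "n_pr_genes": len(pr_genes),
        "n_candidates": int(len(candidates)),
        "scope": list(cfg.frequency_scope),
        "top_candidates": candidates.head(10).to_dict(orient="records"),
    }
    if not collections:
        report["flags"].append("no collections; prioritization skipped")
    _log("prioritize", t0, candidates=len(candidates))

    pio.write_json(report, out / "report.json")
    return report
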