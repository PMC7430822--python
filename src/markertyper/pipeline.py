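"""End-to-end cell-typing pipeline with skip flags and a summary report.

Stages run in a fixed order — load → normalize → scale → [aggregate] →
score → assign → [CNV → malignant calling] — each optional stage guarded by
a config flag, mirroring the skip semantics of starting from a prepared
matrix.  All randomness derives from one seed, result tables are written
atomically, and every parameter that influenced the run is echoed in the
report so a run can be reproduced from its own documentation.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bundled
from .cnv import (CNVConfig, MalignantCalls, call_malignant, cnv_score,
                  detect_gene_clusters, infer_cnv)
from .marker_db import MarkerDB, load_marker_db, select_markers
from .preprocess import (CellMeta, ExpressionMatrix, GeneAnnotation,
                         ValidationError, aggregate_by_cluster, log_normalize,
                         read_annotation, read_cell_meta, read_matrix,
                         z_scale_genes)
from .typing import (TypingResult, TypingScores, assign_types, average_score,
                     build_templates, gsea_score, ntp_score)

log = logging.getLogger(__name__)

METHODS = ("ntp", "gsea", "average")
LEVELS = ("cell", "cluster")


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    File inputs may be left ``None`` when the corresponding objects are
    passed to :func:`run_pipeline` directly (in-memory mode).  ``db_path``
    accepts ``bundled:sctyper`` / ``bundled:cellmarker`` for the shipped
    databases.
    """

    matrix_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    db_path: str | None = "bundled:sctyper"
    marker_labels: list[str] | None = None
    marker_query: dict = field(default_factory=dict)
    method: str = "average"
    level: str = "cell"
    normalize: bool = True  # False: input matrix is already log-normalized
    fdr_cutoff: float = 0.05
    run_cnv: bool = False
    malignant_classes: list[str] = field(default_factory=lambda: ["Epithelial cell"])
    functional_set_labels: list[str] | None = None
    cnv: CNVConfig = field(default_factory=CNVConfig)
    n_perm: int = 1000
    seed: int = 0
    out_dir: str | None = None
    write_figures: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if isinstance(self.cnv, dict):
            self.cnv = CNVConfig(**self.cnv)
        for p in (self.matrix_path, self.meta_path, self.annotation_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cnv"] = dataclasses.asdict(self.cnv) if not isinstance(self.cnv, dict) else self.cnv
        return d


@dataclass
class Report:
    """Everything a rerun needs to know: parameters, attrition, outcomes."""

    parameters: dict
    stages: list[dict]
    assignment_counts: dict[str, int]
    malignant_summary: dict | None = None
    method_comparison: dict | None = None
    figures: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    typing: TypingResult
    scores: TypingScores
    malignant: MalignantCalls | None
    report: Report
    out_dir: Path | None


def _atomic_write_text(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_frame(frame: pd.DataFrame, path: Path, **kw) -> None:
    _atomic_write_text(frame.to_csv(sep="\t", **kw), path)


def _load_db(cfg: PipelineConfig) -> MarkerDB:
    if cfg.db_path == "bundled:sctyper":
        return bundled.sctyper_db()
    if cfg.db_path == "bundled:cellmarker":
        return bundled.cellmarker_db()
    if cfg.db_path is None:
        raise ValidationError("no marker database configured")
    return load_marker_db(cfg.db_path)


def run_pipeline(
    cfg: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    meta: CellMeta | None = None,
    annotation: GeneAnnotation | None = None,
    markers: list | None = None,
    functional_sets: list | None = None,
) -> PipelineResult:
    """Execute the configured stages and (optionally) write result tables.

    In-memory objects override the corresponding file paths in ``cfg``.
    Raises with the failing stage's name on any stage error.
    """
    stages: list[dict] = []
    stage = "load"
    try:
        if matrix is None:
            if cfg.matrix_path is None:
                raise ValidationError("no matrix given (neither object nor path)")
            matrix = read_matrix(cfg.matrix_path,
                                 layer_hint="counts" if cfg.normalize else "lognorm")
        if meta is None and cfg.meta_path is not None:
            meta = read_cell_meta(cfg.meta_path)
        if annotation is None and cfg.annotation_path is not None:
            annotation = read_annotation(cfg.annotation_path)
        if markers is None:
            db = _load_db(cfg)
            markers = select_markers(db, labels=cfg.marker_labels, **cfg.marker_query)
            if not markers:
                raise ValidationError("marker selection matched no sets")
        stages.append({"stage": "load", "n_genes": matrix.n_genes,
                       "n_cells": matrix.n_cells, "n_marker_sets": len(markers)})

        stage = "normalize"
        lognorm = log_normalize(matrix) if cfg.normalize else matrix
        stages.append({"stage": "normalize", "skipped": not cfg.normalize,
                       "n_cells": lognorm.n_cells})

        stage = "scale"
        scaled = z_scale_genes(lognorm)
        stages.append({"stage": "scale", "n_genes": scaled.n_genes})

        stage = "aggregate"
        if cfg.level == "cluster":
            if meta is None:
                raise ValidationError("cluster-level typing needs cell metadata")
            unit_matrix = aggregate_by_cluster(scaled, meta)
            stages.append({"stage": "aggregate", "n_clusters": unit_matrix.n_cells})
        else:
            unit_matrix = scaled
            stages.append({"stage": "aggregate", "skipped": True})

        stage = f"score:{cfg.method}"
        rng = np.random.default_rng(cfg.seed)
        if cfg.method == "ntp":
            templates = build_templates(markers, unit_matrix)
            scores = ntp_score(unit_matrix, templates, n_perm=cfg.n_perm, rng=rng)
        elif cfg.method == "gsea":
            scores = gsea_score(unit_matrix, markers)
        else:
            scores = average_score(unit_matrix, markers)
        stages.append({"stage": "score", "method": cfg.method,
                       "n_units": len(scores.unit_ids)})

        stage = "assign"
        result = assign_types(scores, fdr_cutoff=cfg.fdr_cutoff, level=cfg.level)
        if cfg.level == "cluster":
            result = result.broadcast_to_cells(meta.aligned_to(scaled))
        counts = result.table["assigned_type"].value_counts().to_dict()
        stages.append({"stage": "assign", "n_types": len(counts)})

        malignant = None
        if cfg.run_cnv:
            stage = "cnv"
            if annotation is None:
                raise ValidationError("CNV stage needs a gene annotation")
            if meta is None:
                raise ValidationError("CNV stage needs cell metadata (reference flags)")
            meta_aligned = meta.aligned_to(lognorm)
            reference = meta_aligned.reference_cells()
            clusters = detect_gene_clusters(annotation, functional_sets or [], cfg.cnv)
            cnv = infer_cnv(lognorm, annotation, reference, clusters, cfg.cnv)
            stages.append({"stage": "cnv", "n_gene_clusters_removed": len(clusters),
                           **{f"genes_{k}": v for k, v in cnv.attrition.items()}})
            stage = "call_malignant"
            scores_per_cell = cnv_score(cnv, cfg.cnv.score_statistic)
            malignant = call_malignant(scores_per_cell, reference, result,
                                       cfg.malignant_classes, cfg.cnv)
            stages.append({"stage": "call_malignant",
                           "threshold": malignant.threshold,
                           "n_malignant": int(malignant.table["final_malignant"].sum())})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = Report(
        parameters=cfg.to_dict(),
        stages=stages,
        assignment_counts={str(k): int(v) for k, v in sorted(counts.items())},
        malignant_summary=(
            None if malignant is None else {
                "threshold": malignant.threshold,
                "quantile": malignant.quantile,
                "n_malignant": int(malignant.table["final_malignant"].sum()),
                "n_cnv_flag": int(malignant.table["cnv_flag"].sum()),
                "n_marker_flag": int(malignant.table["marker_flag"].sum()),
            }
        ),
    )

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        _atomic_write_frame(result.table, out_dir / "typing_result.tsv", index=False)
        _atomic_write_frame(scores.scores.round(10), out_dir / "typing_scores.tsv",
                            index_label="unit_id")
        if malignant is not None:
            _atomic_write_frame(malignant.table, out_dir / "malignant_calls.tsv", index=False)
        if cfg.write_figures:
            report.figures = _write_figures(scores, result, out_dir)
        _atomic_write_text(render_report(report, "markdown"), out_dir / "report.md")
        _atomic_write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True),
                           out_dir / "config_used.yaml")
    return PipelineResult(typing=result, scores=scores, malignant=malignant,
                          report=report, out_dir=out_dir)


def _write_figures(scores: TypingScores, result: TypingResult, out_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []
    fig, ax = plt.subplots(figsize=(6, 4))
    mat = scores.scores.to_numpy()
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(scores.class_labels)))
    ax.set_xticklabels(scores.class_labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("units")
    ax.set_title(f"{scores.method} scores")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    p = out_dir / "score_heatmap.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    files.append(p.name)

    counts = result.table["assigned_type"].value_counts().sort_index()
    fig, ax = plt.subplots(figsize=(6, 3))
    counts.plot.bar(ax=ax)
    ax.set_ylabel("cells")
    fig.tight_layout()
    p = out_dir / "type_proportions.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    files.append(p.name)
    return files


# --------------------------------------------------------------------------
# method comparison
# --------------------------------------------------------------------------


def compare_methods(results: list[TypingResult]) -> dict:
    """Cross-tabulate assignments from several scoring methods.

    Returns per-method type proportions, a pairwise agreement matrix
    (fraction of units assigned identically) and, per type, the membership
    overlap regions across methods (Venn-style counts keyed by the subset of
    methods containing each unit).
    """
    if not results:
        raise ValidationError("no results to compare")
    ids = [tuple(r.table["unit_id"]) for r in results]
    if len({frozenset(i) for i in ids}) != 1:
        raise ValidationError("results cover different unit sets")
    methods = [r.method for r in results]
    if len(set(methods)) != len(methods):
        methods = [f"{m}_{i}" for i, m in enumerate(methods)]
    assign = {m: r.assignments for m, r in zip(methods, results)}
    units = sorted(ids[0])
    proportions = pd.DataFrame({
        m: assign[m].value_counts(normalize=True) for m in methods
    }).fillna(0.0)

    agreement = pd.DataFrame(index=methods, columns=methods, dtype=float)
    for a in methods:
        for b in methods:
            agreement.loc[a, b] = float((assign[a].loc[units].to_numpy() ==
                                         assign[b].loc[units].to_numpy()).mean())

    all_types = sorted(set().union(*[set(a.unique()) for a in assign.values()]))
    overlaps: dict[str, dict[str, int]] = {}
    for t in all_types:
        members = {m: set(assign[m][assign[m] == t].index) for m in methods}
        regions: dict[str, int] = {}
        every = set().union(*members.values())
        for u in every:
            key = "&".join(m for m in methods if u in members[m])
            regions[key] = regions.get(key, 0) + 1
        overlaps[t] = dict(sorted(regions.items()))
    return {"proportions": proportions, "agreement": agreement, "overlaps": overlaps}


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------


def _frame_to_markdown(frame: pd.DataFrame) -> str:
    header = "| " + " | ".join(str(c) for c in frame.columns) + " |"
    sep = "|" + "|".join(["---"] * len(frame.columns)) + "|"
    rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in frame.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, str]]:
    out = []
    for k in sorted(d):
        v = d[k]
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.extend(_flatten(v, prefix=f"{key}."))
        else:
            out.append((key, repr(v)))
    return out


def render_report(report: Report, fmt: str = "markdown", path: str | Path | None = None) -> str:
    """Render a run report as a self-contained document.

    Tables are embedded as text and figures referenced by relative filename;
    the parameters section exhaustively echoes the configuration.  Rendering
    the same report twice is byte-identical (stable ordering, no
    timestamps).
    """
    if fmt not in ("markdown", "html"):
        raise ValidationError(f"unknown report format {fmt!r}")
    lines = ["# Cell typing run report", ""]
    lines += ["## Parameters", ""]
    params = pd.DataFrame(_flatten(report.parameters), columns=["parameter", "value"])
    lines += [_frame_to_markdown(params), ""]
    lines += ["## Stages", ""]
    for s in report.stages:
        detail = ", ".join(f"{k}={v}" for k, v in s.items() if k != "stage")
        lines.append(f"- **{s['stage']}**: {detail}")
    lines.append("")
    lines += ["## Assignments", ""]
    counts = pd.DataFrame(sorted(report.assignment_counts.items()),
                          columns=["type", "n_units"])
    lines += [_frame_to_markdown(counts), ""]
    if report.malignant_summary is not None:
        lines += ["## Malignant calls", ""]
        ms = pd.DataFrame(sorted(report.malignant_summary.items()),
                          columns=["statistic", "value"])
        lines += [_frame_to_markdown(ms), ""]
    if report.method_comparison is not None:
        lines += ["## Method comparison", ""]
        prop = report.method_comparison.get("proportions")
        if prop is not None:
            lines += [_frame_to_markdown(prop.round(4).reset_index(names="type")), ""]
    if report.figures:
        lines += ["## Figures", ""]
        lines += [f"![{f}]({f})" for f in report.figures] + [""]
    text = "\n".join(lines)
    if fmt == "html":
        text = ("<!DOCTYPE html><html><head><meta charset='utf-8'>"
                "<title>Cell typing run report</title></head><body><pre>\n"
                + text + "\n</pre></body></html>")
    if path is not None:
        _atomic_write_text(text, Path(path))
    return text
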