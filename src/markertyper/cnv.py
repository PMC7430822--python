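"""Copy-number inference from expression and malignant-cell calling.

Relative DNA copy-number profiles are estimated from log-normalized
expression in the usual way: genes are ordered along the genome, centered on
a reference (copy-number-normal) cell population, clipped, smoothed with a
moving average that never crosses a chromosome boundary, and median-centered
per cell.  Two additions matter for tumour data:

* **Gene-cluster filtering.**  Families of functionally related genes that
  sit within ~1 Mb of each other (e.g. co-located paralogs) can be
  co-expressed and mimic a focal copy-number change.  Such clusters are
  detected by windowed hypergeometric enrichment of each functional set
  along the genome and removed before smoothing.
* **Q90 malignant calling.**  Each cell gets a CNV score (sum of squared
  smoothed deviations by default); cells scoring above the 90th percentile
  of the reference cells are flagged as copy-number aberrant.  The final
  malignant call is that flag OR a marker-based assignment to a designated
  malignant class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .marker_db import MarkerSet
from .preprocess import ExpressionMatrix, GeneAnnotation, ValidationError
from .typing import TypingResult

log = logging.getLogger(__name__)


@dataclass
class CNVConfig:
    """Tunable parameters of the CNV stage.

    window_genes
        odd number of genes in the moving-average smoothing span.
    clip
        centered log-ratios are clipped to ±clip before smoothing.
    min_mean_expr
        genes with mean log-expression below this (across all cells) are
        dropped before centering.
    cluster_window_bp / cluster_alpha / cluster_min_genes
        genomic window, unadjusted p cutoff, and minimum member count for
        gene-cluster detection.
    score_quantile
        reference-score quantile defining the aberration threshold.
    score_statistic
        per-cell score: ``sum_sq`` (sum of squared deviations, default) or
        ``mean_abs``.
    """

    window_genes: int = 101
    clip: float = 3.0
    min_mean_expr: float = 0.1
    cluster_window_bp: int = 1_000_000
    cluster_alpha: float = 0.05
    cluster_min_genes: int = 5
    score_quantile: float = 0.90
    score_statistic: str = "sum_sq"

    def __post_init__(self):
        if self.window_genes < 1 or self.window_genes % 2 == 0:
            raise ValidationError("window_genes must be an odd integer >= 1")
        if not 0 < self.score_quantile < 1:
            raise ValidationError("score_quantile must lie in (0, 1)")
        if self.score_statistic not in ("sum_sq", "mean_abs"):
            raise ValidationError("score_statistic must be 'sum_sq' or 'mean_abs'")


def _chrom_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, MT, then others lexicographic."""
    c = re.sub("^chr", "", str(chrom), flags=re.IGNORECASE)
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if c.upper() in special:
        return (special[c.upper()], "")
    return (26, c)


def order_genes(annotation: GeneAnnotation, m: ExpressionMatrix):
    """Order the matrix genes genomically.

    Returns ``(ordered_symbols, boundaries)`` where boundaries is a list of
    ``(chrom, start_index, end_index)`` half-open blocks into the ordered
    list.  Genes absent from the annotation are excluded (count logged).
    """
    present = set(m.gene_ids)
    t = annotation.table[annotation.table["symbol"].isin(present)].copy()
    if t.empty:
        raise ValidationError("no matrix gene has a genomic annotation")
    n_unannotated = len(present) - len(t)
    if n_unannotated:
        log.info("order_genes: %d matrix genes lack annotation and are excluded", n_unannotated)
    t["_key"] = t["chrom"].map(_chrom_key)
    t = t.sort_values(["_key", "start"], kind="stable").reset_index(drop=True)
    symbols = t["symbol"].tolist()
    boundaries = []
    start = 0
    for chrom, grp in t.groupby("chrom", sort=False):
        boundaries.append((str(chrom), start, start + len(grp)))
        start += len(grp)
    return symbols, boundaries


@dataclass(frozen=True)
class GeneCluster:
    """A co-located, enriched slice of one functional gene set."""

    chrom: str
    start: int
    end: int
    member_genes: tuple[str, ...]
    source_set: str
    p: float


def detect_gene_clusters(
    annotation: GeneAnnotation,
    functional_sets: list[MarkerSet],
    cfg: CNVConfig | None = None,
) -> list[GeneCluster]:
    """Find genomic windows where a functional gene set is enriched.

    For each set and chromosome, a window of ``cluster_window_bp`` is
    anchored at each member gene's start.  Windows holding at least
    ``cluster_min_genes`` members are tested with the hypergeometric upper
    tail (population = all annotated genes, successes = annotated set size,
    draws = genes in the window); windows with unadjusted p below
    ``cluster_alpha`` are reported, overlapping windows of the same set
    merged (union of members, minimum p).
    """
    cfg = cfg or CNVConfig()
    if not functional_sets:
        return []
    t = annotation.table
    M = len(t)
    clusters: list[GeneCluster] = []
    for s in functional_sets:
        members = t[t["symbol"].str.upper().isin(set(s.genes_upper))]
        n_set = len(members)
        if n_set == 0:
            continue
        candidates: list[GeneCluster] = []
        for chrom, chrom_members in members.groupby("chrom"):
            chrom_all = t[t["chrom"] == chrom]
            starts_all = chrom_all["start"].to_numpy()
            for anchor in chrom_members["start"].to_numpy():
                lo, hi = anchor, anchor + cfg.cluster_window_bp
                in_win = chrom_members[(chrom_members["start"] >= lo) & (chrom_members["start"] <= hi)]
                k = len(in_win)
                if k < cfg.cluster_min_genes:
                    continue
                n_window = int(((starts_all >= lo) & (starts_all <= hi)).sum())
                p = float(hypergeom.sf(k - 1, M, n_set, n_window))
                if p < cfg.cluster_alpha:
                    candidates.append(
                        GeneCluster(
                            chrom=str(chrom),
                            start=int(in_win["start"].min()),
                            end=int(in_win["end"].max()),
                            member_genes=tuple(in_win["symbol"]),
                            source_set=s.cell_type or s.label,
                            p=p,
                        )
                    )
        clusters.extend(_merge_overlapping(candidates))
    return clusters


def _merge_overlapping(cands: list[GeneCluster]) -> list[GeneCluster]:
    out: list[GeneCluster] = []
    for c in sorted(cands, key=lambda c: (_chrom_key(c.chrom), c.start)):
        if out and out[-1].chrom == c.chrom and c.start <= out[-1].end:
            prev = out[-1]
            genes = tuple(dict.fromkeys(prev.member_genes + c.member_genes))
            out[-1] = GeneCluster(
                chrom=prev.chrom,
                start=min(prev.start, c.start),
                end=max(prev.end, c.end),
                member_genes=genes,
                source_set=prev.source_set,
                p=min(prev.p, c.p),
            )
        else:
            out.append(c)
    return out


@dataclass
class CNVMatrix:
    """Smoothed, centered log-ratio values in genomic gene order."""

    values: np.ndarray  # genes x cells
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    boundaries: list  # (chrom, start_idx, end_idx)
    attrition: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


def _moving_average_blocks(values: np.ndarray, boundaries, window: int) -> np.ndarray:
    """Per-chromosome moving average with symmetric truncation at block ends.

    At index i within a block of length L the half-width shrinks to
    min(h, i, L−1−i), so the window stays centered and never crosses a
    chromosome boundary; window=1 is the identity.
    """
    if window == 1:
        return values.copy()
    h = window // 2
    out = np.empty_like(values)
    for _, lo, hi in boundaries:
        block = values[lo:hi]
        L = block.shape[0]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        idx = np.arange(L)
        half = np.minimum(h, np.minimum(idx, L - 1 - idx))
        upper = idx + half + 1
        lower = idx - half
        out[lo:hi] = (csum[upper] - csum[lower]) / (upper - lower)[:, None]
    return out


def infer_cnv(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    reference_cells,
    clusters_to_remove: list[GeneCluster] | None = None,
    cfg: CNVConfig | None = None,
) -> CNVMatrix:
    """Estimate relative copy-number profiles from log-normalized expression.

    Stages, in order: (1) drop genes in ``clusters_to_remove``; (2) drop
    genes whose mean expression across all cells is below
    ``cfg.min_mean_expr``; (3) center each gene on its reference-cell mean;
    (4) clip to ±cfg.clip; (5) smooth per chromosome over
    ``cfg.window_genes`` genes; (6) subtract each cell's median.  Per-stage
    gene attrition is recorded on the result.
    """
    cfg = cfg or CNVConfig()
    if m.layer != "lognorm":
        raise ValidationError(f"infer_cnv expects a lognorm matrix, got {m.layer!r}")
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValidationError("reference_cells must be non-empty")
    cell_pos = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in reference_cells if c not in cell_pos]
    if missing:
        raise ValidationError(f"reference cells absent from matrix: {missing[:5]}")
    ref_idx = np.array([cell_pos[c] for c in reference_cells])

    symbols, _ = order_genes(annotation, m)
    attrition = {"input_genes": m.n_genes, "genomically_ordered": len(symbols)}

    removed = set()
    for c in clusters_to_remove or []:
        removed |= {g.upper() for g in c.member_genes}
    symbols = [g for g in symbols if g.upper() not in removed]
    attrition["after_cluster_filter"] = len(symbols)

    sub = m.subset_genes(symbols)
    mean_expr = sub.values.mean(axis=1)
    keep = mean_expr >= cfg.min_mean_expr
    symbols = [g for g, k in zip(symbols, keep) if k]
    attrition["after_min_expression"] = len(symbols)
    if not symbols:
        raise ValidationError(f"no genes left after filtering; attrition: {attrition}")
    sub = ExpressionMatrix(sub.values[keep], np.array(symbols, dtype=object),
                           sub.cell_ids, "lognorm")
    _, boundaries = order_genes(annotation, sub)

    centered = sub.values - sub.values[:, ref_idx].mean(axis=1, keepdims=True)
    np.clip(centered, -cfg.clip, cfg.clip, out=centered)
    smoothed = _moving_average_blocks(centered, boundaries, cfg.window_genes)
    smoothed -= np.median(smoothed, axis=0, keepdims=True)
    return CNVMatrix(
        values=smoothed,
        gene_ids=sub.gene_ids.copy(),
        cell_ids=sub.cell_ids.copy(),
        boundaries=boundaries,
        attrition=attrition,
    )


def cnv_score(c: CNVMatrix, statistic: str = "sum_sq") -> pd.Series:
    """Per-cell CNV score: total squared deviation (or mean |deviation|)."""
    if statistic == "sum_sq":
        s = np.square(c.values).sum(axis=0)
    elif statistic == "mean_abs":
        s = np.abs(c.values).mean(axis=0)
    else:
        raise ValidationError(f"unknown statistic {statistic!r}")
    return pd.Series(s, index=list(c.cell_ids), name="cnv_score")


@dataclass
class MalignantCalls:
    """Per-cell malignancy calls and the reference threshold used."""

    table: pd.DataFrame  # cell_id, cnv_score, cnv_flag, marker_flag, final_malignant, final_type
    threshold: float
    quantile: float


def call_malignant(
    scores: pd.Series,
    reference_cells,
    typing: TypingResult,
    malignant_classes,
    cfg: CNVConfig | None = None,
) -> MalignantCalls:
    """Flag malignant cells by the reference-quantile rule OR marker class.

    The threshold is the empirical ``cfg.score_quantile`` quantile (linear
    interpolation between order statistics) of the reference cells' scores;
    cells scoring strictly above it are copy-number aberrant.  Cells assigned
    to any of ``malignant_classes`` by marker typing are malignant regardless
    of score; flagged cells are relabelled ``Malignant``.
    """
    cfg = cfg or CNVConfig()
    reference_cells = [c for c in reference_cells if c in scores.index]
    if not reference_cells:
        raise ValidationError("no reference cell has a CNV score")
    if len(reference_cells) < 10:
        log.warning("only %d reference cells: quantile threshold will be unstable",
                    len(reference_cells))
    ref_scores = scores.loc[reference_cells].to_numpy()
    threshold = float(np.quantile(ref_scores, cfg.score_quantile))  # linear / type-7
    assigned = typing.assignments.reindex(scores.index)
    malignant_classes = set(malignant_classes)
    cnv_flag = scores.to_numpy() > threshold
    marker_flag = assigned.isin(malignant_classes).to_numpy()
    final = cnv_flag | marker_flag
    table = pd.DataFrame(
        {
            "cell_id": scores.index,
            "cnv_score": scores.to_numpy(),
            "cnv_flag": cnv_flag,
            "marker_flag": marker_flag,
            "final_malignant": final,
            "final_type": np.where(final, "Malignant", assigned.fillna("Unresolved")),
        }
    )
    return MalignantCalls(table=table, threshold=threshold, quantile=cfg.score_quantile)
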