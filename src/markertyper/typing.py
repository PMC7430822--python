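"""Marker-expression scoring and cell-type assignment.

Three scoring engines are provided:

* **Nearest template prediction (NTP)** — each candidate type is a binary
  template vector over the marker genes; a cell is scored by its cosine
  distance to each template, assigned to the nearest one, and the assignment
  is given a resampling p-value from random templates of the same sizes.
* **Pre-ranked GSEA** — per cell, genes are ranked by expression and each
  marker set gets a weighted Kolmogorov–Smirnov-style enrichment score (ES):
  the signed maximal deviation of a running sum that steps up at marker
  genes and down elsewhere.
* **Average expression** — the mean scaled expression of each set's genes.

Scoring can run at cell level or, after cluster aggregation, at cluster
level; assignment picks the best class per unit with an FDR filter for NTP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .marker_db import MarkerSet
from .preprocess import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

UNRESOLVED = "Unresolved"


@dataclass
class TemplateSet:
    """Binary class templates over the marker genes present in a matrix."""

    class_labels: tuple[str, ...]
    feature_genes: np.ndarray  # matrix spellings, order of first appearance
    template_matrix: np.ndarray  # features x classes, 0/1
    dropped_genes: dict[str, int]  # per class: markers absent from the matrix

    def __post_init__(self):
        sums = self.template_matrix.sum(axis=0)
        if (sums < 1).any():
            empty = [c for c, s in zip(self.class_labels, sums) if s < 1]
            raise ValidationError(f"template class(es) with no genes: {empty}")

    @property
    def genes_per_class(self) -> np.ndarray:
        return self.template_matrix.sum(axis=0).astype(int)


@dataclass
class TypingScores:
    """Per-unit scores for every candidate type.

    ``scores`` is units × classes: NTP stores distances in [0, 1] (smaller is
    better); GSEA stores ES in [−1, 1]; average stores mean scaled
    expression (larger is better for both).
    """

    method: str
    scores: pd.DataFrame
    pvalues: pd.Series | None = None
    fdr: pd.Series | None = None
    unresolved: pd.Series | None = None

    @property
    def unit_ids(self) -> list:
        return list(self.scores.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class TypingResult:
    """Final per-unit type assignments."""

    table: pd.DataFrame  # unit_id, assigned_type, score, p, fdr
    method: str
    level: str = "cell"

    @property
    def assignments(self) -> pd.Series:
        return self.table.set_index("unit_id")["assigned_type"]

    def broadcast_to_cells(self, meta) -> "TypingResult":
        """Expand cluster-level assignments to the member cells."""
        if self.level != "cluster":
            return self
        t = meta.table
        lut = self.table.set_index("unit_id")
        rows = lut.loc[t["cluster"].astype(str)].reset_index(drop=True)
        rows.insert(0, "unit_id", t["cell_id"].to_numpy())
        return TypingResult(table=rows, method=self.method, level="cell")


def build_templates(markers: list[MarkerSet], m: ExpressionMatrix) -> TemplateSet:
    """Build binary class templates over the union of present marker genes.

    Gene matching is case-insensitive; genes shared by several sets keep a 1
    in every owning column.  A class with no genes in the matrix is an error;
    partially absent classes are reported via ``dropped_genes``.
    """
    if len(markers) < 2:
        raise ValidationError("need at least 2 marker sets to build templates")
    labels = tuple(s.cell_type for s in markers)
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate class labels among marker sets")
    by_upper = {str(g).upper(): g for g in m.gene_ids}
    feature_order: list[str] = []
    seen: set[str] = set()
    dropped: dict[str, int] = {}
    present_per_class: list[list[str]] = []
    for s in markers:
        present = []
        n_absent = 0
        for g in s.genes_upper:
            if g in by_upper:
                present.append(by_upper[g])
                if g not in seen:
                    seen.add(g)
                    feature_order.append(by_upper[g])
            else:
                n_absent += 1
        dropped[s.cell_type] = n_absent
        if n_absent:
            log.warning("class %r: %d of %d marker genes absent from matrix",
                        s.cell_type, n_absent, len(s.genes))
        if not present:
            raise ValidationError(f"marker set for class {s.cell_type!r} has no genes in the matrix")
        present_per_class.append(present)
    feat = np.array(feature_order, dtype=object)
    pos = {g: i for i, g in enumerate(feat)}
    tmpl = np.zeros((len(feat), len(markers)))
    for k, present in enumerate(present_per_class):
        for g in present:
            tmpl[pos[g], k] = 1.0
    return TemplateSet(labels, feat, tmpl, dropped)


def _cosine_to_templates(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Cosine similarity of every column of X (genes × units) to every column
    of T (genes × classes); rows with zero templates contribute nothing."""
    xnorm = np.linalg.norm(X, axis=0)
    tnorm = np.linalg.norm(T, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (T.T @ X) / np.outer(tnorm, xnorm)
    return cos  # classes x units; nan where a norm is zero


def ntp_score(
    m: ExpressionMatrix,
    t: TemplateSet,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TypingScores:
    """Nearest-template distances with resampling significance.

    The matrix is restricted to the template feature space (the union of
    present marker genes); distance(u, k) = (1 − cos(x_u, t_k)) / 2 ∈ [0, 1]
    over that space, winner = argmin.  Significance comes from resampled
    gene labels: each of the ``n_perm`` null draws applies a random
    permutation to the template rows — keeping every class's gene count and
    the between-class overlap structure intact — and records the minimum
    distance over classes; p(u) = (1 + #{null_min ≤ observed_min(u)}) /
    (1 + n_perm) with Benjamini–Hochberg FDR across units.  Because a row
    permutation preserves the joint template structure, observed and null
    statistics are exchangeable under a no-signal matrix and the p-values
    are uniform there.  Units with an all-zero profile are flagged
    unresolved with p = 1.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(seed)
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in t.feature_genes if g not in pos]
    if missing:
        raise ValidationError(f"template genes absent from matrix: {missing[:5]}")
    K = len(t.class_labels)
    T = t.template_matrix
    G = len(t.feature_genes)

    X = m.values[np.array([pos[g] for g in t.feature_genes]), :]
    cos = _cosine_to_templates(X, T)  # K x U
    dist = (1.0 - cos) / 2.0
    zero_units = np.linalg.norm(X, axis=0) == 0
    obs_min = np.nanmin(np.where(np.isnan(dist), np.inf, dist), axis=0)

    # Shared null draws: each permutation relabels the feature genes (a row
    # permutation of the template matrix), statistic = min distance over
    # the K permuted class templates.
    xnorm = np.linalg.norm(X, axis=0)
    tnorm = np.linalg.norm(T, axis=0)
    null_min = np.full((n_perm, m.n_cells), np.inf)
    for b in range(n_perm):
        perm = rng.permutation(G)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_b = (T.T @ X[perm, :]) / np.outer(tnorm, xnorm)
        d_b = (1.0 - cos_b) / 2.0
        null_min[b] = np.min(np.where(np.isnan(d_b), np.inf, d_b), axis=0)
    exceed = (null_min <= obs_min[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[zero_units] = 1.0
    q = bh_fdr(p)

    scores = pd.DataFrame(dist.T, index=list(m.cell_ids), columns=list(t.class_labels))
    return TypingScores(
        method="ntp",
        scores=scores,
        pvalues=pd.Series(p, index=scores.index),
        fdr=pd.Series(q, index=scores.index),
        unresolved=pd.Series(zero_units, index=scores.index),
    )


def _running_es(metric_sorted: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """ES of one set on one ranked list: signed max deviation of the running sum."""
    n = len(metric_sorted)
    n_hit = int(hit_mask.sum())
    w = np.abs(metric_sorted[hit_mask]) ** weight
    denom = w.sum()
    steps = np.where(hit_mask, 0.0, -1.0 / (n - n_hit))
    if denom > 0:
        steps[hit_mask] = (np.abs(metric_sorted[hit_mask]) ** weight) / denom
    else:  # all hit metrics zero: fall back to equal steps
        steps[hit_mask] = 1.0 / n_hit
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_score(
    m: ExpressionMatrix,
    markers: list[MarkerSet],
    weight: float = 1.0,
) -> TypingScores:
    """Per-unit pre-ranked GSEA enrichment scores for each marker set.

    Genes are ranked per unit by expression, descending (ties broken by gene
    order, deterministic).  Hit steps are |metric|^weight normalized to sum
    to 1 over the set's genes; miss steps are −1/(N − N_hit).  ES is the
    running sum's signed maximal deviation, always in [−1, 1].  weight=0
    gives the classic unweighted Kolmogorov–Smirnov form.
    """
    labels = [s.cell_type for s in markers]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate class labels among marker sets")
    upper_ids = np.array([str(g).upper() for g in m.gene_ids])
    N = m.n_genes
    masks = []
    for s in markers:
        mask = np.isin(upper_ids, np.array(s.genes_upper))
        n_hit = int(mask.sum())
        if n_hit < 1:
            raise ValidationError(f"marker set for class {s.cell_type!r} has no genes in the matrix")
        if n_hit >= N:
            raise ValidationError(
                f"marker set for class {s.cell_type!r} covers all {N} genes; miss step undefined"
            )
        masks.append(mask)
    es = np.empty((m.n_cells, len(markers)))
    for u in range(m.n_cells):
        metric = m.values[:, u]
        order = np.argsort(-metric, kind="stable")
        metric_sorted = metric[order]
        for k, mask in enumerate(masks):
            es[u, k] = _running_es(metric_sorted, mask[order], weight)
    scores = pd.DataFrame(es, index=list(m.cell_ids), columns=labels)
    return TypingScores(method="gsea", scores=scores)


def average_score(m: ExpressionMatrix, markers: list[MarkerSet]) -> TypingScores:
    """Mean scaled expression of each set's present genes, per unit."""
    labels = [s.cell_type for s in markers]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate class labels among marker sets")
    by_upper = {str(g).upper(): i for i, g in enumerate(m.gene_ids)}
    cols = []
    for s in markers:
        rows = [by_upper[g] for g in s.genes_upper if g in by_upper]
        if not rows:
            raise ValidationError(f"marker set for class {s.cell_type!r} has no genes in the matrix")
        cols.append(m.values[rows, :].mean(axis=0))
    scores = pd.DataFrame(np.column_stack(cols), index=list(m.cell_ids), columns=labels)
    return TypingScores(method="average", scores=scores)


def assign_types(s: TypingScores, fdr_cutoff: float = 0.05, level: str = "cell") -> TypingResult:
    """Pick the winning class per unit.

    NTP: argmin distance, demoted to ``Unresolved`` when the winning FDR
    exceeds the cutoff (or the unit was flagged).  GSEA / average: argmax
    score, no significance filter.  Ties go deterministically to the first
    class in declared order and are logged.
    """
    vals = s.scores.to_numpy()
    if s.method == "ntp":
        best = np.argmin(vals, axis=1)
        best_val = vals[np.arange(len(best)), best]
        n_tied = int((np.sum(vals == best_val[:, None], axis=1) > 1).sum())
    else:
        best = np.argmax(vals, axis=1)
        best_val = vals[np.arange(len(best)), best]
        n_tied = int((np.sum(vals == best_val[:, None], axis=1) > 1).sum())
    if n_tied:
        log.warning("assign_types: %d unit(s) had tied scores; first class wins", n_tied)
    classes = np.array(s.class_labels, dtype=object)
    assigned = classes[best]
    p = s.pvalues.to_numpy() if s.pvalues is not None else np.full(len(best), np.nan)
    q = s.fdr.to_numpy() if s.fdr is not None else np.full(len(best), np.nan)
    if s.method == "ntp":
        bad = q > fdr_cutoff
        if s.unresolved is not None:
            bad |= s.unresolved.to_numpy()
        assigned = np.where(bad, UNRESOLVED, assigned)
    table = pd.DataFrame(
        {
            "unit_id": s.unit_ids,
            "assigned_type": assigned,
            "score": best_val,
            "p": p,
            "fdr": q,
        }
    )
    return TypingResult(table=table, method=s.method, level=level)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
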