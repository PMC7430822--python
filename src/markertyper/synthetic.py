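"""Seeded synthetic scRNA-seq data with planted cell types and CNV blocks.

The generator emulates droplet-based count data: per-gene baseline means are
log-normal, per-cell library sizes are log-normal, and counts are negative
binomial (gamma–Poisson).  Cell types are planted by shifting each group's
marker genes up by a declared log2 fold; copy-number events are planted by
scaling counts over contiguous genomic blocks; and a co-located
over-expressed gene family can be planted to create the false-CNV confound
that gene-cluster filtering is meant to remove.  Every output is
bit-reproducible under a fixed seed, and a ground-truth record accompanies
each dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_db import MarkerDB, MarkerSet
from .preprocess import CellMeta, ExpressionMatrix, GeneAnnotation, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CellGroup:
    """One planted cell population."""

    label: str
    n_cells: int
    n_marker_genes: int = 20
    marker_log2_fold: float = 2.0
    is_malignant: bool = False
    is_reference: bool = False


@dataclass
class CNVRegion:
    """A planted copy-number event over a genomic interval."""

    chrom: str
    start: int
    end: int
    log2_shift: float
    affected_groups: tuple[str, ...]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a typical 10x-like experiment: 2000 genes on three
    chromosomes, log-normal baseline means giving a median of ~3000 UMIs
    per cell, moderate library-size spread (sigma 0.3) and
    negative-binomial dispersion theta=2 (variance = mu + mu^2/2).
    """

    groups: list[CellGroup]
    n_genes: int = 2000
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"1": 120_000_000, "2": 100_000_000, "3": 80_000_000}
    )
    cnv_regions: list[CNVRegion] = field(default_factory=list)
    base_log_mean: float = 0.0
    base_log_sd: float = 1.0
    marker_min_base_mean: float = 0.5
    lib_size_sigma: float = 0.3
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or not self.groups:
            raise ValidationError("need at least one gene and one cell group")
        if any(g.n_cells < 1 for g in self.groups):
            raise ValidationError("every group needs at least one cell")
        for r in self.cnv_regions:
            if r.chrom not in self.chromosomes or not (0 <= r.start < r.end <= self.chromosomes[r.chrom]):
                raise ValidationError(f"CNV region {r} outside chromosome bounds")


@dataclass
class GroundTruth:
    """What was actually planted, for verification."""

    cell_types: pd.Series  # index cell_id
    malignant: pd.Series  # index cell_id, bool
    marker_genes: dict[str, list[str]]
    cnv_region_genes: list[list[str]]
    cluster_family_genes: list[str] = field(default_factory=list)


def make_annotation(spec: SimulationSpec) -> GeneAnnotation:
    """Place genes at uniform intervals along the declared chromosomes.

    Genes are apportioned to chromosomes proportionally to length and named
    ``G0000``… in genomic order; deterministic for a given spec.
    """
    total = sum(spec.chromosomes.values())
    rows = []
    counts = {}
    assigned = 0
    chroms = list(spec.chromosomes)
    for i, c in enumerate(chroms):
        if i == len(chroms) - 1:
            counts[c] = spec.n_genes - assigned
        else:
            counts[c] = int(round(spec.n_genes * spec.chromosomes[c] / total))
            assigned += counts[c]
    gi = 0
    for c in chroms:
        n = counts[c]
        spacing = spec.chromosomes[c] // max(n, 1)
        for j in range(n):
            start = j * spacing + 1
            rows.append({"symbol": f"G{gi:04d}", "chrom": c, "start": start,
                         "end": start + 999, "strand": "+"})
            gi += 1
    return GeneAnnotation(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma–Poisson negative binomial with var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam).astype(float)


def simulate_counts(spec: SimulationSpec):
    """Draw a counts matrix with planted marker-driven cell types.

    Returns ``(ExpressionMatrix[counts], CellMeta, GroundTruth, MarkerDB)``
    where the toy database lists each group's true marker genes.  Planted
    CNV regions in the spec are NOT applied here — use :func:`plant_cnv` —
    but their genes are excluded from marker selection so typing and CNV
    signals stay separable.
    """
    rng = np.random.default_rng(spec.seed)
    ann = make_annotation(spec)
    genes = np.array(ann.symbols, dtype=object)
    G = spec.n_genes

    base = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd, size=G))

    # exclude genes inside declared CNV regions from marker eligibility
    in_region = np.zeros(G, dtype=bool)
    t = ann.table
    for r in spec.cnv_regions:
        in_region |= ((t["chrom"] == r.chrom) & (t["start"] >= r.start) & (t["start"] <= r.end)).to_numpy()
    eligible = np.flatnonzero(~in_region)
    need = sum(g.n_marker_genes for g in spec.groups)
    if need > len(eligible):
        raise ValidationError(f"not enough genes for {need} disjoint markers")
    marker_idx = rng.choice(eligible, size=need, replace=False)
    # curated markers are detectably expressed in their type: floor their
    # baseline so the planted fold change is observable at all
    base[marker_idx] = np.maximum(base[marker_idx], spec.marker_min_base_mean)

    marker_genes: dict[str, list[str]] = {}
    offset = 0
    group_mult = np.ones((G, len(spec.groups)))
    for k, g in enumerate(spec.groups):
        idx = marker_idx[offset: offset + g.n_marker_genes]
        offset += g.n_marker_genes
        marker_genes[g.label] = [str(s) for s in genes[idx]]
        group_mult[idx, k] = 2.0 ** g.marker_log2_fold

    cells, types, malignant, reference = [], [], [], []
    for g in spec.groups:
        for j in range(g.n_cells):
            cells.append(f"{g.label.replace(' ', '_')}_{j:04d}")
            types.append(g.label)
            malignant.append(g.is_malignant)
            reference.append(g.is_reference)
    n_cells = len(cells)
    lib = np.exp(rng.normal(0.0, spec.lib_size_sigma, size=n_cells))

    group_of_cell = np.repeat(np.arange(len(spec.groups)), [g.n_cells for g in spec.groups])
    mean = base[:, None] * group_mult[:, group_of_cell] * lib[None, :]
    counts = _nb_draw(rng, mean, spec.nb_dispersion)

    m = ExpressionMatrix(counts, genes, np.array(cells, dtype=object), "counts")
    meta = CellMeta(pd.DataFrame({
        "cell_id": cells,
        "cluster": [t.replace(" ", "_") for t in types],
        "sample": "synthetic",
        "is_reference": reference,
    }))
    truth = GroundTruth(
        cell_types=pd.Series(types, index=cells),
        malignant=pd.Series(malignant, index=cells),
        marker_genes=marker_genes,
        cnv_region_genes=[],
    )
    db = MarkerDB(
        sets=[
            MarkerSet.from_label(
                "Synthetic.2020.Simulated.TME", g.label, marker_genes[g.label],
                pmid="0", source_db="user",
            )
            for g in spec.groups
        ],
        source="synthetic",
    )
    return m, meta, truth, db


def plant_cnv(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    spec: SimulationSpec,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Apply the spec's CNV regions to a counts matrix.

    Counts of in-region genes in affected cells are rescaled to expectation
    count × 2^shift: gains add an independent Poisson top-up
    (Poisson(count·(2^s − 1))), losses binomially thin (keep probability
    2^s).  A zero shift is exactly the identity, so unaffected entries are
    bit-identical.  ``truth.cnv_region_genes`` is updated in place.
    """
    if m.layer != "counts":
        raise ValidationError("plant_cnv operates on the counts layer")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    counts = m.values.copy()
    t = annotation.table.set_index("symbol")
    gene_chrom = t.reindex(list(m.gene_ids))["chrom"].to_numpy()
    gene_start = t.reindex(list(m.gene_ids))["start"].to_numpy()
    group_of_cell = {}
    for g in spec.groups:
        for j in range(g.n_cells):
            group_of_cell[f"{g.label.replace(' ', '_')}_{j:04d}"] = g.label
    cell_groups = np.array([group_of_cell.get(c, "") for c in m.cell_ids])

    region_genes_out = []
    for r in spec.cnv_regions:
        gsel = (gene_chrom == r.chrom) & (gene_start >= r.start) & (gene_start <= r.end)
        if not gsel.any():
            log.warning("planted CNV region %s:%d-%d covers zero genes", r.chrom, r.start, r.end)
            region_genes_out.append([])
            continue
        region_genes_out.append([str(s) for s in m.gene_ids[gsel]])
        csel = np.isin(cell_groups, r.affected_groups)
        if r.log2_shift == 0 or not csel.any():
            continue
        block = counts[np.ix_(gsel, csel)]
        factor = 2.0 ** r.log2_shift
        if factor > 1:
            block = block + rng.poisson(block * (factor - 1.0))
        else:
            block = rng.binomial(block.astype(int), factor).astype(float)
        counts[np.ix_(gsel, csel)] = block
    if truth is not None:
        truth.cnv_region_genes = region_genes_out
    return ExpressionMatrix(counts, m.gene_ids.copy(), m.cell_ids.copy(), "counts")


def plant_gene_cluster(
    m: ExpressionMatrix,
    annotation: GeneAnnotation,
    family_size: int,
    span_bp: int,
    overexpressing_cells,
    log2_fold: float = 2.0,
    seed: int = 0,
    truth: GroundTruth | None = None,
):
    """Plant a co-located over-expressed gene family (the false-CNV confound).

    Picks ``family_size`` consecutive mid-chromosome genes on the first
    chromosome, compacts their coordinates to sit within ``span_bp`` (dense
    packing is what makes a paralog cluster a cluster), and boosts their
    counts by 2^log2_fold in the designated cells.  Returns
    ``(modified_matrix, family_marker_set, modified_annotation)``.  A family
    size of 0 is a no-op returning the inputs and ``None``.
    """
    if family_size == 0:
        return m, None, annotation
    rng = np.random.default_rng(seed)
    t = annotation.table
    chrom = t["chrom"].iloc[0]
    chrom_len = int(t.loc[t["chrom"] == chrom, "end"].max())
    if span_bp > chrom_len:
        raise ValidationError("span_bp exceeds chromosome length")
    ct = t[t["chrom"] == chrom].sort_values("start").reset_index(drop=True)
    anchor_pos = len(ct) // 2
    if anchor_pos + family_size > len(ct):
        raise ValidationError(f"chromosome {chrom} has too few genes for the family")
    picked = ct.loc[anchor_pos: anchor_pos + family_size - 1]
    family = [str(s) for s in picked["symbol"]]
    # repack the family within span_bp starting at the anchor gene
    anchor_start = int(picked["start"].iloc[0])
    spacing = max(span_bp // max(family_size - 1, 1) - 1000, 1)
    new_t = t.copy().set_index("symbol")
    for j, g in enumerate(family):
        s0 = anchor_start + j * spacing
        new_t.loc[g, ["start", "end"]] = (s0, s0 + 999)
    new_ann = GeneAnnotation(new_t.reset_index())

    gsel = np.isin(m.gene_ids, family)
    csel = np.isin(m.cell_ids, list(overexpressing_cells))
    counts = m.values.copy()
    block = counts[np.ix_(gsel, csel)]
    counts[np.ix_(gsel, csel)] = block + rng.poisson(block * (2.0 ** log2_fold - 1.0))
    if truth is not None:
        truth.cluster_family_genes = family
    family_set = MarkerSet.from_label(
        "Synthetic.2020.Simulated.GeneFamily", "Co-located paralog family", family,
        pmid="0", source_db="user",
    )
    out = ExpressionMatrix(counts, m.gene_ids.copy(), m.cell_ids.copy(), "counts")
    return out, family_set, new_ann


# --------------------------------------------------------------------------
# canned study conditions
# --------------------------------------------------------------------------


def separation_spec(seed: int = 0, n_cells_per_group: int = 100,
                    marker_log2_fold: float = 2.0) -> SimulationSpec:
    """Three well-separated cell types (300 cells total by default): strong
    planted markers and low count dispersion, the regime where all scoring
    methods should agree with the truth."""
    groups = [
        CellGroup("Epithelial cell", n_cells_per_group, marker_log2_fold=marker_log2_fold,
                  is_malignant=True),
        CellGroup("T cell", n_cells_per_group, marker_log2_fold=marker_log2_fold,
                  is_reference=True),
        CellGroup("Fibroblast", n_cells_per_group, marker_log2_fold=marker_log2_fold),
    ]
    return SimulationSpec(groups=groups, nb_dispersion=8.0, seed=seed)


def cnv_spec(seed: int = 0, n_malignant: int = 150, n_reference: int = 250,
             log2_shift: float = 1.0) -> SimulationSpec:
    """Malignant cells carrying a 200-gene single-copy-like gain on
    chromosome 1, with an immune reference population; a deeply sequenced
    run (~5000 UMIs/cell), where expression-based CNV inference is at its
    best."""
    groups = [
        CellGroup("Epithelial cell", n_malignant, is_malignant=True),
        CellGroup("T cell", n_reference, is_reference=True),
    ]
    # chr1 has ~800 of 2000 genes over 120 Mb: 30 Mb ≈ 200 genes
    region = CNVRegion("1", 30_000_000, 60_000_000, log2_shift, ("Epithelial cell",))
    return SimulationSpec(groups=groups, cnv_regions=[region],
                          base_log_mean=0.5, seed=seed)
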