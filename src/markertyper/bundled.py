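"""Bundled marker databases (synthetic reconstructions).

The package ships two ready-to-use marker databases in the layout of
:mod:`markertyper.marker_db`:

* ``sctyper_db()`` — a tumour-centric database of 213 marker sets covering
  121 cell types from 22 studies, with dedicated categories for
  cancer-associated fibroblasts (CAF, n=21), tumour-infiltrating lymphocytes
  (TIL, n=33), tumour-associated macrophages (TAM, n=4), malignant cells from
  different tissues (n=13) and a broad immune repertoire (149 immune sets in
  total, 62 of them T-cell states).
* ``cellmarker_db()`` — a large general-purpose database of 2867 sets over
  467 cell types from 1764 studies.

Both tables are SYNTHETIC reconstructions: the original curated supplements
are not redistributed here, so the builders generate tables that match the
published summary statistics exactly.  Well-known cell types carry their
canonical human marker genes (e.g. CD3D/CD3E for T cells, PECAM1/VWF for
endothelium); filler sets carry deterministic pool-sampled symbols.  Written
files are named ``*.synthetic.tsv`` to make this explicit.  The databases are
fully deterministic: building twice yields identical tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .marker_db import MarkerDB, MarkerSet, db_summary, write_marker_db

# --------------------------------------------------------------------------
# shared gene-symbol pool
# --------------------------------------------------------------------------

#: Canonical human marker genes for well-characterised cell types.
CANONICAL_MARKERS: dict[str, list[str]] = {
    "Epithelial cell": ["KRT14", "KRT17", "KRT6A", "KRT5", "EPCAM", "SFN", "KRT16", "KRT75"],
    "Fibroblast": ["COL1A1", "COL1A2", "COL3A1", "DCN", "FAP", "PDGFRA", "LUM"],
    "Myocyte": ["ACTA1", "DES", "MYL1", "TNNT3", "MYH2"],
    "Macrophage": ["CD68", "CD163", "CSF1R", "LYZ", "AIF1"],
    "Endothelial cell": ["PECAM1", "VWF", "CDH5", "CLDN5", "FLT1"],
    "T cell": ["CD3D", "CD3E", "CD3G", "CD2", "TRAC", "IL7R"],
    "B cell": ["CD79A", "CD79B", "MS4A1", "CD19", "IGHM"],
    "Dendritic cell": ["CD1C", "FCER1A", "CLEC9A", "ITGAX", "LILRA4"],
    "Mast cell": ["TPSAB1", "TPSB2", "CPA3", "KIT", "MS4A2"],
    "NK cell": ["NKG7", "GNLY", "KLRD1", "NCAM1", "KLRF1"],
    "Cancer-associated fibroblast": ["FAP", "ACTA2", "PDPN", "PDGFRB", "COL11A1"],
    "Tumor-associated macrophage": ["CD68", "MRC1", "MSR1", "CCL2", "SPP1"],
    "CD4+ T cell": ["CD4", "IL7R", "CD3D", "CCR7"],
    "CD8+ T cell": ["CD8A", "CD8B", "GZMK", "CD3D"],
    "Regulatory T cell": ["FOXP3", "IL2RA", "CTLA4", "IKZF2"],
    "Exhausted T cell": ["PDCD1", "HAVCR2", "LAG3", "TIGIT", "TOX"],
    "Malignant cell": ["MKI67", "EPCAM", "SOX2", "MYC"],
    "Plasma cell": ["SDC1", "MZB1", "XBP1", "IGHG1"],
    "Neutrophil": ["FCGR3B", "CSF3R", "S100A8", "S100A9"],
    "Monocyte": ["CD14", "FCN1", "VCAN", "S100A12"],
}

_BASE_SYMBOLS = [
    "ACTB", "GAPDH", "ALB", "APOE", "AXL", "BCL2", "BRCA1", "CCND1", "CCL5", "CCR5",
    "CD24", "CD27", "CD38", "CD44", "CD5", "CD6", "CD7", "CD9", "CDK4", "CEACAM5",
    "CFTR", "CXCL9", "CXCL10", "CXCR4", "EGFR", "ERBB2", "FCGR2A", "FGFR1", "FN1", "FOXA1",
    "GATA3", "GZMA", "GZMB", "HLA-DRA", "HLA-DRB1", "ICAM1", "IFNG", "IGF1R", "IL10", "IL2",
    "IL6", "ITGAM", "ITGB1", "JAK2", "KDR", "KLRB1", "KRAS", "LGALS3", "LGR5", "LYN",
    "MET", "MMP9", "MPO", "MUC1", "NES", "NOTCH1", "OLIG2", "PAX5", "PDGFB", "PDL1",
    "PRF1", "PTPRC", "RUNX1", "SELL", "SELP", "SNAI1", "SOX9", "STAT3", "TAGLN", "TGFB1",
    "THY1", "TNF", "TP63", "TYR", "VIM", "WT1", "ZEB1", "CD69", "CD80", "CD86",
    "CLEC4C", "CSF2", "CX3CR1", "ENG", "FABP4", "FOLR2", "GFAP", "GYPA", "HBB", "ITGA2B",
    "MAG", "MBP", "MLANA", "PMEL", "NPHS1", "PDGFRL", "PECAM2", "RBFOX3", "SFTPC", "SPARC",
]


def _symbol_pool(n: int) -> list[str]:
    """Deterministic pool of gene symbols: real symbols first, then synthetic
    placeholders (``SYNxxxx``) once the real list is exhausted."""
    pool = list(_BASE_SYMBOLS)
    i = 1
    while len(pool) < n:
        pool.append(f"SYN{i:04d}")
        i += 1
    return pool[:n]


def _genes_for(cell_type: str, rng: np.random.Generator, pool: list[str]) -> list[str]:
    if cell_type in CANONICAL_MARKERS:
        return list(CANONICAL_MARKERS[cell_type])
    size = int(rng.integers(5, 12))
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[j] for j in sorted(idx)]


# --------------------------------------------------------------------------
# scTyper-style tumour database: 213 sets / 121 cell types / 22 studies
# --------------------------------------------------------------------------

#: 25 T-cell states (every name contains the literal substring "T cell").
T_TYPES = [
    "T cell", "CD4+ T cell", "CD8+ T cell", "Regulatory T cell", "Exhausted T cell",
    "Exhausted CD8+ T cell", "Naive CD4+ T cell", "Naive CD8+ T cell",
    "Memory CD4+ T cell", "Memory CD8+ T cell", "Effector memory T cell",
    "Central memory T cell", "Follicular helper T cell", "Th1-polarized T cell",
    "Th2-polarized T cell", "Th17-polarized T cell", "Gamma delta T cell",
    "Cytotoxic T cell", "Activated CD4+ T cell", "Activated CD8+ T cell",
    "Tissue-resident memory T cell", "Terminally exhausted T cell",
    "Progenitor exhausted T cell", "Proliferating T cell",
    "Mucosal-associated invariant T cell",
]

#: The nine tumour-microenvironment cell types of the HNSCC reference family.
PURAM_TYPES = [
    "Epithelial cell", "Fibroblast", "Myocyte", "Macrophage", "Endothelial cell",
    "T cell", "B cell", "Dendritic cell", "Mast cell",
]

CAF_TYPES = [
    "Cancer-associated fibroblast", "Myofibroblastic CAF", "Inflammatory CAF",
    "Antigen-presenting CAF", "Vascular CAF", "Matrix CAF",
]

TAM_TYPES = ["Tumor-associated macrophage", "M1 macrophage", "M2 macrophage"]

MALIGNANT_TYPES = [
    "Malignant cell", "Malignant epithelial cell", "Malignant hepatocyte",
    "Malignant melanocyte", "Malignant astrocyte", "Malignant ductal cell",
    "Malignant basal cell", "Malignant luminal cell", "Malignant squamous cell",
    "Malignant glandular cell",
]

TME_EXTRA_TYPES = [
    "NK cell", "Pericyte", "Myeloid cell", "Plasma cell", "Melanocyte",
    "Smooth muscle cell", "Lymphatic endothelial cell", "Vascular endothelial cell",
    "Adipocyte", "Schwann cell", "Astrocyte", "Oligodendrocyte", "Neuron", "Hepatocyte",
]

IMMUNE_OTHER_TYPES = [
    "Naive B cell", "Memory B cell", "Germinal center B cell", "Plasmablast",
    "Classical monocyte", "Non-classical monocyte", "Intermediate monocyte",
    "CD14+ monocyte", "CD16+ monocyte", "Conventional dendritic cell", "cDC1", "cDC2",
    "Plasmacytoid dendritic cell", "Monocyte-derived dendritic cell", "Langerhans cell",
    "Kupffer cell", "Microglia", "Alveolar macrophage", "Peritoneal macrophage",
    "Red pulp macrophage", "Neutrophil", "Eosinophil", "Basophil",
    "CD56bright NK cell", "CD56dim NK cell", "Adaptive NK cell", "ILC1", "ILC2", "ILC3",
    "Myeloid-derived suppressor cell", "Monocytic MDSC", "Granulocytic MDSC",
    "Hematopoietic stem cell", "Common lymphoid progenitor", "Common myeloid progenitor",
    "Megakaryocyte", "Erythrocyte", "Erythroid progenitor", "Platelet",
    "Pro-B cell", "Pre-B cell", "Immature B cell", "Transitional B cell",
    "Marginal zone B cell", "Regulatory B cell", "Follicular B cell",
    "Atypical memory B cell", "IgA plasma cell", "IgG plasma cell", "IgM plasma cell",
    "Monocyte", "Macrophage progenitor", "Dendritic cell progenitor", "Granulocyte",
    "Promyelocyte",
]

#: The 22 source studies: (first author, year, tissue/cancer type, PMID).
STUDIES = {
    "Puram": ("Puram", 2017, "HNSCC", "29198524"),
    "Tirosh": ("Tirosh", 2016, "Melanoma", "27124452"),
    "Zheng": ("Zheng", 2017, "HCC", "28622514"),
    "Lambrechts": ("Lambrechts", 2018, "NSCLC", "29988129"),
    "Li": ("Li", 2017, "CRC", "28319088"),
    "Chung": ("Chung", 2017, "Breast", "28474673"),
    "Venteicher": ("Venteicher", 2017, "Glioma", "28360267"),
    "Patel": ("Patel", 2014, "GBM", "24925914"),
    "Darmanis": ("Darmanis", 2017, "GBM", "29091775"),
    "Savas": ("Savas", 2018, "Breast", "29942092"),
    "Guo": ("Guo", 2018, "NSCLC", "29942094"),
    "Zhang": ("Zhang", 2018, "CRC", "30479382"),
    "Azizi": ("Azizi", 2018, "Breast", "29961579"),
    "Jerby-Arnon": ("Jerby-Arnon", 2018, "Melanoma", "30388455"),
    "Costa": ("Costa", 2018, "Breast", "29634945"),
    "Elyada": ("Elyada", 2019, "PDAC", "31197017"),
    "Ohlund": ("Ohlund", 2017, "PDAC", "28232471"),
    "Villani": ("Villani", 2017, "Blood", "28428369"),
    "Zilionis": ("Zilionis", 2019, "NSCLC", "30979687"),
    "Aran": ("Aran", 2019, "Mixed", "30643263"),
    "Newman": ("Newman", 2015, "Mixed", "25822800"),
    "Sade-Feldman": ("Sade-Feldman", 2018, "Melanoma", "30388456"),
}

#: Allocation of marker sets to (study, category, cell types).  The block
#: layout realises the published tallies: 213 sets, 121 distinct cell types,
#: 22 studies; TME 30, CAF 21, TIL 33, TAM 4, Malignant 13, Immune 112
#: (so immune overall = TIL + TAM + Immune = 149, with 62 T-cell states).
_SCTYPER_BLOCKS: list[tuple[str, str, list[str]]] = [
    ("Puram", "TME", PURAM_TYPES),
    ("Tirosh", "TME", TME_EXTRA_TYPES[0:11]),
    ("Sade-Feldman", "TME", TME_EXTRA_TYPES[4:14]),
    ("Costa", "CAF", CAF_TYPES[0:6]),
    ("Ohlund", "CAF", CAF_TYPES[0:6]),
    ("Elyada", "CAF", CAF_TYPES[0:6]),
    ("Puram", "CAF", CAF_TYPES[0:3]),
    ("Zheng", "TIL", T_TYPES[0:12]),
    ("Guo", "TIL", T_TYPES[12:23]),
    ("Savas", "TIL", T_TYPES[23:25] + T_TYPES[0:8]),
    ("Azizi", "TAM", TAM_TYPES[0:3]),
    ("Zhang", "TAM", TAM_TYPES[0:1]),
    ("Patel", "Malignant", MALIGNANT_TYPES[0:3]),
    ("Venteicher", "Malignant", MALIGNANT_TYPES[3:6]),
    ("Chung", "Malignant", MALIGNANT_TYPES[6:9]),
    ("Li", "Malignant", MALIGNANT_TYPES[0:2]),
    ("Lambrechts", "Malignant", MALIGNANT_TYPES[8:10]),
    ("Zhang", "Immune", T_TYPES[0:15]),
    ("Jerby-Arnon", "Immune", T_TYPES[15:25] + T_TYPES[0:4]),
    ("Villani", "Immune", IMMUNE_OTHER_TYPES[0:20]),
    ("Zilionis", "Immune", IMMUNE_OTHER_TYPES[20:40]),
    ("Aran", "Immune", IMMUNE_OTHER_TYPES[40:55]),
    ("Newman", "Immune", IMMUNE_OTHER_TYPES[0:15]),
    ("Darmanis", "Immune", IMMUNE_OTHER_TYPES[15:28]),
]


def sctyper_db() -> MarkerDB:
    """Build the bundled tumour-centric marker database (synthetic).

    Deterministic; reproduces the published summary counts, which are
    asserted at build time.
    """
    rng = np.random.default_rng(20200804)
    pool = _symbol_pool(400)
    sets: list[MarkerSet] = []
    for study_key, category, cell_types in _SCTYPER_BLOCKS:
        author, year, tissue, pmid = STUDIES[study_key]
        label = f"{author}.{year}.{tissue}.{category}"
        for ct in cell_types:
            sets.append(
                MarkerSet.from_label(
                    label, ct, _genes_for(ct, rng, pool),
                    species="Homo sapiens", pmid=pmid, source_db="scTyper.db",
                )
            )
    db = MarkerDB(sets=sets, source="bundled:sctyper")
    s = db_summary(db)
    assert (s.n_sets, s.n_cell_types, s.n_studies) == (213, 121, 22), s
    assert s.category_counts["CAF"] == 21 and s.category_counts["TIL"] == 33
    assert s.category_counts["TAM"] == 4 and s.category_counts["Malignant"] == 13
    assert s.n_immune == 149 and s.n_t_cell_sets == 62
    return db


# --------------------------------------------------------------------------
# CellMarker-style general database: 2867 sets / 467 cell types / 1764 studies
# --------------------------------------------------------------------------

_CM_SURNAMES = [
    "Zhang", "Wang", "Li", "Liu", "Chen", "Yang", "Kim", "Lee", "Park", "Smith",
    "Johnson", "Brown", "Garcia", "Miller", "Davis", "Martinez", "Lopez", "Wilson",
    "Anderson", "Taylor", "Thomas", "Moore", "Jackson", "Martin", "Thompson", "White",
    "Harris", "Sanchez", "Clark", "Lewis", "Robinson", "Walker", "Young", "Allen",
    "King", "Wright", "Scott", "Torres", "Nguyen", "Hill",
]

_CM_TISSUES = [
    "Blood", "BoneMarrow", "Brain", "Breast", "Colon", "Esophagus", "Eye", "Heart",
    "Intestine", "Kidney", "Liver", "Lung", "LymphNode", "Muscle", "Ovary", "Pancreas",
    "Placenta", "Prostate", "Skin", "Spleen", "Stomach", "Testis", "Thymus", "Thyroid",
    "Uterus",
]

_CM_CATEGORIES = ["Immune", "Stromal", "Epithelial", "Malignant", "Neural", "Other"]

_CM_CELL_BASES = [
    "B cell", "T cell", "NK cell", "Monocyte", "Macrophage", "Dendritic cell",
    "Neutrophil", "Eosinophil", "Basophil", "Mast cell", "Plasma cell", "Fibroblast",
    "Endothelial cell", "Epithelial cell", "Pericyte", "Adipocyte", "Hepatocyte",
    "Cholangiocyte", "Enterocyte", "Goblet cell", "Paneth cell", "Tuft cell",
    "Stem cell", "Progenitor cell", "Neuron", "Astrocyte", "Oligodendrocyte",
    "Microglia", "Schwann cell", "Cardiomyocyte", "Myocyte", "Keratinocyte",
    "Melanocyte", "Osteoblast", "Osteoclast", "Chondrocyte", "Podocyte",
    "Mesangial cell", "Alveolar cell", "Club cell", "Ciliated cell", "Basal cell",
    "Luminal cell", "Acinar cell", "Ductal cell", "Islet cell", "Germ cell",
]

_CM_MODIFIERS = [
    "", "Activated", "Naive", "Memory", "Immature", "Mature", "Progenitor-like",
    "Proliferating", "Resident", "Circulating", "Fetal", "Adult",
]


def _cellmarker_cell_types(n: int = 467) -> list[str]:
    names: list[str] = []
    for mod in _CM_MODIFIERS:
        for base in _CM_CELL_BASES:
            names.append(f"{mod} {base}".strip())
            if len(names) == n:
                return names
    raise AssertionError("cell-type name pool exhausted")


def cellmarker_db() -> MarkerDB:
    """Build the bundled general-purpose marker database (synthetic).

    2867 sets over 467 cell types from 1764 studies; deterministic, counts
    asserted at build time.
    """
    n_sets, n_types, n_studies = 2867, 467, 1764
    rng = np.random.default_rng(20181012)
    pool = _symbol_pool(600)
    cell_types = _cellmarker_cell_types(n_types)
    sets: list[MarkerSet] = []
    for i in range(n_sets):
        s = i % n_studies
        author = _CM_SURNAMES[s % 40] + ("" if s < 40 else str(s // 40))
        year = 2000 + (s * 7) % 20
        tissue = _CM_TISSUES[s % len(_CM_TISSUES)]
        pmid = str(16000000 + s)
        category = _CM_CATEGORIES[i % len(_CM_CATEGORIES)]
        ct = cell_types[i % n_types]
        label = f"{author}.{year}.{tissue}.{category}"
        size = int(rng.integers(3, 11))
        idx = rng.choice(len(pool), size=size, replace=False)
        genes = [pool[j] for j in sorted(idx)]
        sets.append(
            MarkerSet.from_label(
                label, ct, genes,
                species="Homo sapiens" if i % 3 else "Mus musculus",
                pmid=pmid, source_db="CellMarker",
            )
        )
    db = MarkerDB(sets=sets, source="bundled:cellmarker")
    s = db_summary(db)
    assert (s.n_sets, s.n_cell_types, s.n_studies) == (n_sets, n_types, n_studies), s
    return db


def write_bundled_db(out_dir: str | Path) -> dict[str, Path]:
    """Write both bundled databases as ``*.synthetic.tsv`` files.

    Returns a mapping ``{"sctyper": path, "cellmarker": path}``; the files
    load back with :func:`markertyper.marker_db.load_marker_db`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sctyper": write_marker_db(sctyper_db(), out_dir / "sctyper.db.synthetic.tsv"),
        "cellmarker": write_marker_db(cellmarker_db(), out_dir / "cellmarker.synthetic.tsv"),
    }
    return paths
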