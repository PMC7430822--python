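"""Curated cell-type marker gene-set databases.

A marker database is a flat tab-separated table, one row per (study, cell type)
marker set.  Sets are labelled with a dotted nomenclature concatenating the
first author of the source publication, the publication year, the tissue or
cancer type, and the cell-composition category — e.g. ``Puram.2017.HNSCC.TME``.
One label covers a *family* of sets (one per cell type described by that
study), so the uniqueness key within a database is ``(label, cell_type)``.

The on-disk layout (``generic`` / ``sctyper`` dialect) is a UTF-8 TSV with a
header row and columns::

    identifier  study  species  tissue_type  category  cell_type  gene_symbols  pmid

``gene_symbols`` is a delimiter-joined list (default ``,``).  The whole
database is deliberately a plain replaceable file: swapping it out is how
users bring their own markers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

GENERIC_COLUMNS = [
    "identifier",
    "study",
    "species",
    "tissue_type",
    "category",
    "cell_type",
    "gene_symbols",
    "pmid",
]

#: Required columns per dialect.  ``cellmarker`` follows the published
#: CellMarker export layout; missing author/year there are synthesised from
#: the PMID when no explicit columns are present.
DIALECT_COLUMNS = {
    "sctyper": GENERIC_COLUMNS,
    "generic": GENERIC_COLUMNS,
    "cellmarker": ["speciesType", "tissueType", "cellName", "geneSymbol", "PMID"],
}

#: Categories counted together as "immune" in summaries: tumour-infiltrating
#: lymphocytes and tumour-associated macrophages are immune repertoires too.
IMMUNE_CATEGORIES = frozenset({"TIL", "TAM", "Immune"})


class MarkerDBFormatError(ValueError):
    """A marker table does not conform to the declared dialect."""


class MarkerDBValidationError(ValueError):
    """A structurally valid table violates a database invariant."""


class LabelParseError(ValueError):
    """A set label does not follow the dotted nomenclature."""

    def __init__(self, label: str, reason: str):
        self.label = label
        super().__init__(f"cannot parse marker-set label {label!r}: {reason}")


@dataclass(frozen=True)
class ParsedLabel:
    """Components of a dotted marker-set label."""

    first_author: str
    year: int
    tissue_type: str
    category: str

    def format(self) -> str:
        return f"{self.first_author}.{self.year}.{self.tissue_type}.{self.category}"


def parse_label(label: str) -> ParsedLabel:
    """Split a dotted label into (first_author, year, tissue_type, category).

    The first four dot-delimited tokens map positionally; any extra trailing
    tokens are folded into the category so labels like ``A.1999.X.Y.Z`` parse
    as category ``Y.Z``.
    """
    tokens = str(label).split(".")
    if len(tokens) < 4:
        raise LabelParseError(label, f"expected >= 4 dot-separated tokens, got {len(tokens)}")
    author, year_tok, tissue = tokens[0], tokens[1], tokens[2]
    category = ".".join(tokens[3:])
    try:
        year = int(year_tok)
    except ValueError as exc:
        raise LabelParseError(label, f"year token {year_tok!r} is not an integer") from exc
    return ParsedLabel(author, year, tissue, category)


def _dedup_genes(genes, label: str):
    """Case-insensitive de-duplication keeping first occurrence and spelling."""
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        g = str(g).strip()
        if not g:
            continue
        key = g.upper()
        if key in seen:
            continue
        seen.add(key)
        out.append(g)
    n_dropped = sum(1 for g in genes if str(g).strip()) - len(out)
    if n_dropped:
        log.info("marker set %s: dropped %d duplicate gene symbols", label, n_dropped)
    return tuple(out)


@dataclass(frozen=True)
class MarkerSet:
    """One curated marker gene set: a cell type described by one study.

    ``genes`` preserves the input spelling and order; matching elsewhere is
    case-insensitive via :attr:`genes_upper`.
    """

    label: str
    cell_type: str
    genes: tuple[str, ...]
    first_author: str = ""
    year: int = 0
    tissue_type: str = ""
    category: str = ""
    species: str = "Homo sapiens"
    pmid: str = ""
    source_db: str = "user"

    def __post_init__(self):
        if not self.genes:
            raise MarkerDBValidationError(f"marker set {self.label!r}/{self.cell_type!r} has no genes")
        upper = [g.upper() for g in self.genes]
        if len(set(upper)) != len(upper):
            raise MarkerDBValidationError(
                f"marker set {self.label!r}/{self.cell_type!r} contains duplicate genes"
            )

    @property
    def genes_upper(self) -> tuple[str, ...]:
        return tuple(g.upper() for g in self.genes)

    @property
    def study_key(self) -> tuple[str, int, str]:
        """Identity of the source study; author+year alone may collide."""
        return (self.first_author, self.year, self.pmid)

    @classmethod
    def from_label(cls, label: str, cell_type: str, genes, **kw) -> "MarkerSet":
        p = parse_label(label)
        return cls(
            label=label,
            cell_type=cell_type,
            genes=_dedup_genes(tuple(genes), label),
            first_author=p.first_author,
            year=p.year,
            tissue_type=p.tissue_type,
            category=p.category,
            **kw,
        )


@dataclass
class MarkerDB:
    """An ordered collection of marker sets with a provenance record."""

    sets: list[MarkerSet]
    source: str | None = None

    def __post_init__(self):
        keys = [(s.label, s.cell_type) for s in self.sets]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise MarkerDBValidationError(f"duplicate (label, cell_type) entries: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "identifier": s.label,
                "study": f"{s.first_author} {s.year}".strip(),
                "species": s.species,
                "tissue_type": s.tissue_type,
                "category": s.category,
                "cell_type": s.cell_type,
                "gene_symbols": ",".join(s.genes),
                "pmid": s.pmid,
            }
            for s in self.sets
        ]
        return pd.DataFrame(rows, columns=GENERIC_COLUMNS)


def load_marker_db(
    path: str | Path,
    dialect: str = "sctyper",
    gene_delimiter: str = ",",
    source_db: str | None = None,
) -> MarkerDB:
    """Load a marker database TSV in the declared dialect.

    Rows whose gene list is empty after trimming are rejected with a logged
    warning; a missing required column raises :class:`MarkerDBFormatError`
    naming the column.
    """
    path = Path(path)
    if dialect not in DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMNS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = DIALECT_COLUMNS[dialect]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise MarkerDBFormatError(
            f"{path}: missing required column(s) {missing} for dialect {dialect!r}"
        )
    default_source = {"sctyper": "scTyper.db", "cellmarker": "CellMarker"}.get(dialect, "user")
    src = source_db or default_source

    sets: list[MarkerSet] = []
    n_empty = 0
    for idx, row in table.iterrows():
        if dialect == "cellmarker":
            pmid = row["PMID"].strip()
            author = row.get("firstAuthor", "").strip() or f"PMID{pmid or idx}"
            year_txt = row.get("year", "").strip() or "0"
            tissue = row["tissueType"].strip().replace(".", "-") or "NA"
            cell_type = row["cellName"].strip()
            category = row.get("category", "").strip().replace(".", "-") or "CellMarker"
            label = f"{author}.{int(year_txt)}.{tissue}.{category}"
            genes_txt = row["geneSymbol"]
            species = row["speciesType"].strip() or "Homo sapiens"
        else:
            label = row["identifier"].strip()
            cell_type = row["cell_type"].strip()
            genes_txt = row["gene_symbols"]
            species = row["species"].strip() or "Homo sapiens"
            pmid = row["pmid"].strip()
        genes = _dedup_genes(tuple(genes_txt.split(gene_delimiter)), label)
        if not genes:
            n_empty += 1
            log.warning("%s row %d (%s): empty gene list, row rejected", path.name, idx, label)
            continue
        p = parse_label(label)
        sets.append(
            MarkerSet(
                label=label,
                cell_type=cell_type,
                genes=genes,
                first_author=p.first_author,
                year=p.year,
                tissue_type=p.tissue_type,
                category=p.category,
                species=species,
                pmid=pmid,
                source_db=src,
            )
        )
    if n_empty:
        log.warning("%s: rejected %d rows with empty gene lists", path.name, n_empty)
    return MarkerDB(sets=sets, source=str(path))


def write_marker_db(db: MarkerDB, path: str | Path) -> Path:
    """Write a database in the generic TSV layout (lossless round trip)."""
    path = Path(path)
    db.to_frame().to_csv(path, sep="\t", index=False)
    return path


def select_markers(
    db: MarkerDB,
    cell_type: str | None = None,
    tissue_type: str | None = None,
    study: str | None = None,
    category: str | None = None,
    labels: list[str] | None = None,
) -> list[MarkerSet]:
    """Filter marker sets by exact, case-insensitive field matches.

    Filters are conjunctive; ``study`` matches either the first author alone
    or ``author.year``.  ``labels`` selects whole label families, so one
    dotted label returns every cell type that study describes.  Input order
    is preserved; an empty result is returned (and logged), not an error.
    """

    def norm(x: str) -> str:
        return str(x).strip().lower()

    wanted_labels = {norm(l) for l in labels} if labels is not None else None
    out = []
    for s in db.sets:
        if cell_type is not None and norm(s.cell_type) != norm(cell_type):
            continue
        if tissue_type is not None and norm(s.tissue_type) != norm(tissue_type):
            continue
        if category is not None and norm(s.category) != norm(category):
            continue
        if study is not None and norm(study) not in (
            norm(s.first_author),
            norm(f"{s.first_author}.{s.year}"),
        ):
            continue
        if wanted_labels is not None and norm(s.label) not in wanted_labels:
            continue
        out.append(s)
    if not out:
        log.info("select_markers: query matched no sets")
    return out


@dataclass
class DBSummary:
    """Aggregate counts over a marker database."""

    n_sets: int
    n_cell_types: int
    n_studies: int
    category_counts: dict[str, int]
    tissue_counts: dict[str, int]
    n_immune: int
    n_t_cell_sets: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_sets", self.n_sets),
            ("n_cell_types", self.n_cell_types),
            ("n_studies", self.n_studies),
            ("n_immune", self.n_immune),
            ("n_t_cell_sets", self.n_t_cell_sets),
        ]
        rows += [(f"category:{k}", v) for k, v in sorted(self.category_counts.items())]
        rows += [(f"tissue:{k}", v) for k, v in sorted(self.tissue_counts.items())]
        return pd.DataFrame(rows, columns=["statistic", "count"])


def db_summary(db: MarkerDB) -> DBSummary:
    """Summarise a database: set/type/study counts and per-category tallies.

    A study is the tuple (first_author, year, pmid).  ``n_immune`` counts the
    sets whose category is in :data:`IMMUNE_CATEGORIES`; ``n_t_cell_sets``
    counts the immune sets whose cell type names a T-cell state (contains
    ``"T cell"``), i.e. the T-cell slice of the immune repertoire.  Counts
    are invariant to row order by construction.
    """
    cats: dict[str, int] = {}
    tissues: dict[str, int] = {}
    for s in db.sets:
        cats[s.category] = cats.get(s.category, 0) + 1
        tissues[s.tissue_type] = tissues.get(s.tissue_type, 0) + 1
    return DBSummary(
        n_sets=len(db.sets),
        n_cell_types=len({s.cell_type for s in db.sets}),
        n_studies=len({s.study_key for s in db.sets}),
        category_counts=cats,
        tissue_counts=tissues,
        n_immune=sum(cats.get(c, 0) for c in IMMUNE_CATEGORIES),
        n_t_cell_sets=sum(
            1
            for s in db.sets
            if s.category in IMMUNE_CATEGORIES and "T cell" in s.cell_type
        ),
    )
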