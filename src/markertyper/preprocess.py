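"""Expression-matrix I/O, normalization, scaling and cluster aggregation.

The in-memory container is a genes × cells matrix with explicit layer
semantics (``counts`` → ``lognorm`` → ``scaled``).  Normalization follows the
standard single-cell convention: per-cell library-size scaling to a fixed
total followed by log1p, so downstream scoring is comparable across cells
regardless of sequencing depth.  Clustering itself is out of scope — cluster
labels arrive precomputed via :class:`CellMeta`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

LAYERS = ("counts", "lognorm", "scaled")


class MatrixFormatError(ValueError):
    """An input matrix file is malformed or inconsistent."""


class ValidationError(ValueError):
    """Inputs violate an operation precondition."""


@dataclass
class ExpressionMatrix:
    """A genes × cells expression matrix with layer semantics.

    ``values`` is dense float64, rows = genes, columns = cells.  Gene and
    cell identifiers are unique and index-aligned with the matrix.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids are not unique")
        if self.layer == "counts" and self.values.size and self.values.min() < 0:
            raise ValidationError("counts layer contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells × genes) view."""
        import anndata

        return anndata.AnnData(
            X=self.values.T.copy(),
            obs=pd.DataFrame(index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows, :], np.array(list(genes), dtype=object),
                                self.cell_ids.copy(), self.layer)


@dataclass
class CellMeta:
    """Per-cell metadata: cluster label, sample of origin, reference flag.

    Reference cells are the presumed copy-number-normal population (immune
    cells by convention) used for CNV centering and thresholding.
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id",)

    def __post_init__(self):
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"cell metadata missing required column {col!r}")
        if t["cell_id"].duplicated().any():
            raise ValidationError("cell metadata contains duplicate cell_ids")
        if "cluster" not in t.columns:
            t["cluster"] = pd.NA
        if "sample" not in t.columns:
            t["sample"] = "sample1"
        if "is_reference" not in t.columns:
            t["is_reference"] = False
        t["is_reference"] = t["is_reference"].astype(bool)
        self.table = t.reset_index(drop=True)

    def aligned_to(self, m: ExpressionMatrix) -> "CellMeta":
        """Reorder rows to match matrix cells; the sets must coincide."""
        t = self.table.set_index("cell_id")
        missing = [c for c in m.cell_ids if c not in t.index]
        extra = [c for c in t.index if c not in set(m.cell_ids)]
        if missing or extra:
            raise ValidationError(
                f"cell metadata does not match matrix cells "
                f"({len(missing)} missing, {len(extra)} extra)"
            )
        return CellMeta(t.loc[list(m.cell_ids)].reset_index())

    def reference_cells(self) -> list:
        return list(self.table.loc[self.table["is_reference"], "cell_id"])


def read_cell_meta(path: str | Path) -> CellMeta:
    """Read a per-cell metadata TSV (columns: cell_id[, cluster, sample, is_reference])."""
    t = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return CellMeta(t)


@dataclass
class GeneAnnotation:
    """Genomic coordinates per gene symbol, 1-based inclusive."""

    table: pd.DataFrame  # columns: symbol, chrom, start, end, strand

    def __post_init__(self):
        t = self.table.copy()
        required = ["symbol", "chrom", "start", "end"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"gene annotation missing column(s) {missing}")
        if "strand" not in t.columns:
            t["strand"] = "unknown"
        n0 = len(t)
        t = t.drop_duplicates(subset="symbol", keep="first").reset_index(drop=True)
        if len(t) < n0:
            log.warning("gene annotation: dropped %d duplicate symbols", n0 - len(t))
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "symbol"].tolist()
            raise ValidationError(f"annotation start > end for {bad[:5]}")
        t["chrom"] = t["chrom"].astype(str)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def symbols(self) -> list[str]:
        return list(self.table["symbol"])


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene coordinates from BED (0-based half-open, converted to 1-based
    inclusive) or a 4/5-column TSV (symbol, chrom, start, end[, strand])."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        t = pd.read_csv(path, sep="\t", header=None, comment="#")
        t = t.iloc[:, :6] if t.shape[1] >= 6 else t
        cols = ["chrom", "start", "end", "symbol", "score", "strand"][: t.shape[1]]
        t.columns = cols
        t["start"] = t["start"].astype(int) + 1  # BED start is 0-based
        t["end"] = t["end"].astype(int)
        if "strand" not in t.columns:
            t["strand"] = "unknown"
        return GeneAnnotation(t[["symbol", "chrom", "start", "end", "strand"]])
    t = pd.read_csv(path, sep="\t")
    return GeneAnnotation(t)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> Path:
    path = Path(path)
    ann.table[["symbol", "chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------------
# matrix I/O
# --------------------------------------------------------------------------


def _looks_like_barcodes(labels) -> bool:
    """Heuristic: all labels are >= 6-mers over ACGT (optionally '-1' suffixed)."""
    labels = list(labels)
    if not labels:
        return False
    ok = 0
    for lab in labels[:50]:
        core = str(lab).split("-")[0]
        if len(core) >= 6 and set(core) <= set("ACGT"):
            ok += 1
    return ok == len(labels[:50])


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.index.duplicated().any():
        n = int(frame.index.duplicated().sum())
        log.warning("collapsing %d duplicate gene rows by summing", n)
        frame = frame.groupby(level=0, sort=False).sum()
    return frame


def read_matrix(
    path: str | Path,
    layer_hint: str = "counts",
    orientation: str = "auto",
) -> ExpressionMatrix:
    """Read an expression matrix from a 10x MTX triplet directory or a dense
    delimited file.

    ``orientation`` is one of ``genes_by_cells``, ``cells_by_genes`` or
    ``auto`` (dense input only; MTX triplets are genes × cells by
    convention).  ``auto`` transposes when row labels look like cell
    barcodes.  Duplicate gene symbols are collapsed by summing, logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_mtx_triplet(path, layer_hint)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"{path}: cannot parse dense matrix ({exc})") from exc
    if frame.empty:
        raise MatrixFormatError(f"{path}: empty matrix file")
    non_numeric = frame.columns[~frame.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(non_numeric):
        col = non_numeric[0]
        bad = frame[col].map(lambda v: not isinstance(v, (int, float))).idxmax()
        raise MatrixFormatError(f"{path}: non-numeric value at row {bad!r}, column {col!r}")
    if orientation == "cells_by_genes" or (
        orientation == "auto" and _looks_like_barcodes(frame.index) and not _looks_like_barcodes(frame.columns)
    ):
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    frame = _collapse_duplicate_genes(frame)
    return ExpressionMatrix(frame.to_numpy(float), frame.index.to_numpy(object),
                            frame.columns.to_numpy(object), layer_hint)


def _read_mtx_triplet(d: Path, layer_hint: str) -> ExpressionMatrix:
    mtx = d / "matrix.mtx"
    barcodes = d / "barcodes.tsv"
    features = d / "features.tsv"
    if not features.exists():
        features = d / "genes.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise MatrixFormatError(f"MTX triplet incomplete: {f} not found")
    values = scipy.io.mmread(mtx)
    if scipy.sparse.issparse(values):
        values = values.toarray()
    values = np.asarray(values, dtype=float)
    bc = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    ft = pd.read_csv(features, sep="\t", header=None)
    # 10x features files carry (id, symbol[, type]); use the symbol column when present
    genes = ft[1 if ft.shape[1] > 1 else 0].astype(str).tolist()
    if values.shape != (len(genes), len(bc)):
        raise MatrixFormatError(
            f"{d}: matrix is {values.shape} but features/barcodes give "
            f"({len(genes)}, {len(bc)})"
        )
    frame = _collapse_duplicate_genes(pd.DataFrame(values, index=genes, columns=bc))
    return ExpressionMatrix(frame.to_numpy(float), frame.index.to_numpy(object),
                            frame.columns.to_numpy(object), layer_hint)


def write_matrix(m: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> Path:
    """Write a matrix as dense TSV/CSV or as a 10x-style MTX triplet directory."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sp = scipy.sparse.coo_matrix(m.values)
        is_int = np.allclose(m.values, np.round(m.values))
        scipy.io.mmwrite(path / "matrix.mtx", sp, field="integer" if is_int else "real")
        pd.Series(list(m.cell_ids)).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        feat = pd.DataFrame({"id": list(m.gene_ids), "symbol": list(m.gene_ids)})
        feat.to_csv(path / "features.tsv", sep="\t", index=False, header=False)
        return path
    sep = "," if fmt == "csv" else "\t"
    m.to_frame().to_csv(path, sep=sep)
    return path


# --------------------------------------------------------------------------
# normalization / scaling / aggregation
# --------------------------------------------------------------------------


def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize and log-transform counts.

    value[g, c] = ln(1 + count[g, c] / total[c] * scale_factor).  The result
    is invariant to multiplying any single cell's counts by a positive
    constant.  Cells with zero total count are dropped with a warning.
    """
    if m.layer != "counts":
        raise ValidationError(f"log_normalize expects a counts layer, got {m.layer!r}")
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = m.values.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [c for c, k in zip(m.cell_ids, keep) if not k]
        log.warning("log_normalize: dropping %d zero-total cells: %s",
                    len(dropped), dropped[:5])
    vals = m.values[:, keep]
    out = np.log1p(vals / totals[keep] * scale_factor)
    return ExpressionMatrix(out, m.gene_ids.copy(), m.cell_ids[keep].copy(), "lognorm")


def z_scale_genes(m: ExpressionMatrix, clip: float = 10.0) -> ExpressionMatrix:
    """Standardize each gene to mean 0 / sd 1 across cells (sample sd, ddof=1).

    Zero-variance genes become all-zero rows; values are clipped to ±clip.
    """
    if m.layer != "lognorm":
        raise ValidationError(f"z_scale_genes expects a lognorm layer, got {m.layer!r}")
    mean = m.values.mean(axis=1, keepdims=True)
    if m.n_cells > 1:
        sd = m.values.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros((m.n_genes, 1))
    out = np.zeros_like(m.values)
    nz = sd[:, 0] > 0
    out[nz] = (m.values[nz] - mean[nz]) / sd[nz]
    np.clip(out, -clip, clip, out=out)
    return ExpressionMatrix(out, m.gene_ids.copy(), m.cell_ids.copy(), "scaled")


def aggregate_by_cluster(m: ExpressionMatrix, meta: CellMeta) -> ExpressionMatrix:
    """Average member-cell profiles per cluster; columns = sorted cluster labels."""
    meta = meta.aligned_to(m)
    clusters = meta.table["cluster"]
    if clusters.isna().any():
        missing = meta.table.loc[clusters.isna(), "cell_id"].tolist()
        raise ValidationError(f"cells without cluster labels: {missing[:5]} "
                              f"({len(missing)} total)")
    labels = sorted(clusters.astype(str).unique())
    cols = np.column_stack(
        [m.values[:, (clusters.astype(str) == lab).to_numpy()].mean(axis=1) for lab in labels]
    )
    return ExpressionMatrix(cols, m.gene_ids.copy(), np.array(labels, dtype=object), m.layer)
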