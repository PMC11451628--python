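"""Data model and readers/writers for segmented-cell tables, count matrices,
pathology images and affine matrices, plus per-cell QC.

Conventions
-----------
* Tissue coordinates are micrometres, origin top-left, y increasing downward
  (imaging convention); image coordinates are pixels with the same
  orientation.
* Polygons are stored as open rings (last vertex != first) with
  counter-clockwise winding in the y-down frame; a duplicated closing vertex
  is stripped on read.
* Counts are kept sparse (CSR) internally; dense views are materialized on
  demand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import shapely
import shapely.wkt
import tifffile

from .errors import (
    DimensionMismatchError,
    DuplicateCellIdError,
    MalformedPolygonError,
    NonIntegerCountError,
)
from .registration import AffineTransform2D

GENOTYPES = ("non_tg", "tg")
SEXES = ("M", "F")
REGIONS = ("cortex", "hippocampus", "other")
PSYN_STATUSES = ("positive", "negative", "unknown")
PANELS = ("base", "custom", "negative_probe")
SPECIES_TAGS = ("mouse", "human", "control")

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# CellRecord
# ---------------------------------------------------------------------------

def _canonical_polygon(vertices: np.ndarray) -> np.ndarray:
    """Strip a duplicated closing vertex and normalize winding to CCW.

    CCW is defined by positive signed area in the y-down frame (shoelace on
    the raw coordinates).
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise MalformedPolygonError(f"vertex array must be (n, 2), got {v.shape}")
    if len(v) >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise MalformedPolygonError(f"polygon needs >=3 vertices, got {len(v)}")
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if abs(signed) < 1e-12:
        raise MalformedPolygonError("polygon has zero area")
    if signed < 0:
        v = v[::-1]
    return v


@dataclass
class CellRecord:
    """One segmented cell: geometry plus sample/typing/pathology metadata."""

    cell_id: str
    sample_id: str
    genotype: str
    sex: str
    region: str
    nucleus_centroid: tuple[float, float]
    polygon: np.ndarray
    cell_type: str = UNASSIGNED
    psyn_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.psyn_status not in PSYN_STATUSES:
            raise ValueError(f"psyn_status must be one of {PSYN_STATUSES}")
        self.polygon = _canonical_polygon(self.polygon)
        poly = self.shapely_polygon
        if not poly.is_valid:
            raise MalformedPolygonError(f"cell {self.cell_id}: self-intersecting polygon")
        cx, cy = self.nucleus_centroid
        if not poly.covers(shapely.Point(cx, cy)):
            raise MalformedPolygonError(
                f"cell {self.cell_id}: nucleus centroid outside polygon")

    @property
    def shapely_polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.polygon)

    @property
    def area(self) -> float:
        return self.shapely_polygon.area


def validate_cells(cells: Sequence[CellRecord], *, check_overlap: bool = False,
                   overlap_tol: float = 1e-6) -> None:
    """Check cross-cell invariants: unique ids per sample and, optionally,
    pairwise polygon non-overlap beyond ``overlap_tol`` um^2 within a sample.
    """
    seen: set[tuple[str, str]] = set()
    for c in cells:
        key = (c.sample_id, c.cell_id)
        if key in seen:
            raise DuplicateCellIdError(f"duplicate cell_id {c.cell_id!r} in sample {c.sample_id!r}")
        seen.add(key)
    if not check_overlap:
        return
    by_sample: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_sample.setdefault(c.sample_id, []).append(c)
    for sample_id, group in by_sample.items():
        polys = np.array([c.shapely_polygon for c in group], dtype=object)
        tree = shapely.STRtree(polys)
        left, right = tree.query(polys, predicate="intersects")
        for i, j in zip(left, right):
            if i >= j:
                continue
            inter = shapely.intersection(polys[i], polys[j])
            if inter.area > overlap_tol:
                raise MalformedPolygonError(
                    f"sample {sample_id}: cells {group[i].cell_id} and "
                    f"{group[j].cell_id} overlap by {inter.area:.3g} um^2")


def cells_to_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Flat metadata view (geometry reduced to the nucleus centroid)."""
    return pd.DataFrame({
        "cell_id": [c.cell_id for c in cells],
        "sample_id": [c.sample_id for c in cells],
        "genotype": [c.genotype for c in cells],
        "sex": [c.sex for c in cells],
        "region": [c.region for c in cells],
        "x": [c.nucleus_centroid[0] for c in cells],
        "y": [c.nucleus_centroid[1] for c in cells],
        "cell_type": [c.cell_type for c in cells],
        "psyn_status": [c.psyn_status for c in cells],
    })


# ---------------------------------------------------------------------------
# Cell table file formats
# ---------------------------------------------------------------------------

_CSV_COLS = ["cell_id", "sample_id", "genotype", "sex", "region", "x", "y",
             "cell_type", "psyn_status", "polygon_wkt"]


def _record_from_row(row, vertices) -> CellRecord:
    return CellRecord(
        cell_id=str(row["cell_id"]),
        sample_id=str(row["sample_id"]),
        genotype=str(row["genotype"]),
        sex=str(row["sex"]),
        region=str(row["region"]),
        nucleus_centroid=(float(row["x"]), float(row["y"])),
        polygon=vertices,
        cell_type=str(row.get("cell_type", UNASSIGNED)),
        psyn_status=str(row.get("psyn_status", "unknown")),
    )


def read_cells(path, format: str = "csv_wkt", *, check_overlap: bool = False) -> list[CellRecord]:
    """Read a segmented-cell table.

    ``csv_wkt``: one row per cell with a WKT POLYGON column.
    ``vertex_table``: one row per vertex (long form), ordered by
    ``vertex_index`` within each cell.
    """
    path = Path(path)
    if format == "csv_wkt":
        df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
        cells = []
        for _, row in df.iterrows():
            try:
                geom = shapely.wkt.loads(row["polygon_wkt"])
            except shapely.errors.ShapelyError as exc:
                raise MalformedPolygonError(f"cell {row['cell_id']}: bad WKT ({exc})") from exc
            if geom.geom_type != "Polygon":
                raise MalformedPolygonError(
                    f"cell {row['cell_id']}: expected POLYGON, got {geom.geom_type}")
            cells.append(_record_from_row(row, np.asarray(geom.exterior.coords)))
    elif format == "vertex_table":
        df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
        cells = []
        for (_, _), grp in df.groupby(["sample_id", "cell_id"], sort=False):
            grp = grp.sort_values("vertex_index")
            verts = grp[["vertex_x", "vertex_y"]].to_numpy(dtype=float)
            cells.append(_record_from_row(grp.iloc[0], verts))
    else:
        raise ValueError(f"unknown cell table format {format!r}")
    validate_cells(cells, check_overlap=check_overlap)
    return cells


def write_cells(cells: Sequence[CellRecord], path, format: str = "csv_wkt") -> None:
    path = Path(path)
    if format == "csv_wkt":
        rows = []
        for c in cells:
            closed = np.vstack([c.polygon, c.polygon[:1]])
            wkt = "POLYGON ((" + ", ".join(f"{float(x)!r} {float(y)!r}" for x, y in closed) + "))"
            rows.append({
                "cell_id": c.cell_id, "sample_id": c.sample_id,
                "genotype": c.genotype, "sex": c.sex, "region": c.region,
                "x": repr(float(c.nucleus_centroid[0])), "y": repr(float(c.nucleus_centroid[1])),
                "cell_type": c.cell_type, "psyn_status": c.psyn_status,
                "polygon_wkt": wkt,
            })
        pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)
    elif format == "vertex_table":
        rows = []
        for c in cells:
            for k, (vx, vy) in enumerate(c.polygon):
                rows.append({
                    "cell_id": c.cell_id, "sample_id": c.sample_id,
                    "genotype": c.genotype, "sex": c.sex, "region": c.region,
                    "x": repr(float(c.nucleus_centroid[0])), "y": repr(float(c.nucleus_centroid[1])),
                    "cell_type": c.cell_type, "psyn_status": c.psyn_status,
                    "vertex_index": k, "vertex_x": repr(float(vx)), "vertex_y": repr(float(vy)),
                })
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown cell table format {format!r}")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x genes integer counts with per-gene panel/species annotation.

    ``panel`` distinguishes ``base``/``custom`` probes from
    ``negative_probe`` controls; negative probes are excluded from
    normalization and differential expression throughout the package.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    panel: np.ndarray
    species_tag: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DimensionMismatchError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise NonIntegerCountError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise NonIntegerCountError("count matrix contains negative entries")
        self.panel = np.asarray(self.panel, dtype=object)
        self.species_tag = np.asarray(self.species_tag, dtype=object)
        if len(self.panel) != len(self.gene_ids) or len(self.species_tag) != len(self.gene_ids):
            raise DimensionMismatchError("panel/species annotations must be per-gene")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DuplicateCellIdError("duplicate cell ids in count matrix")

    # -- views ---------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def negative_probe_mask(self) -> np.ndarray:
        return self.panel == "negative_probe"

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def subset_cells(self, indices) -> "CountMatrix":
        indices = np.asarray(indices)
        return CountMatrix(
            cell_ids=[self.cell_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            counts=self.counts[indices],
            panel=self.panel,
            species_tag=self.species_tag,
        )

    def subset_genes(self, gene_mask) -> "CountMatrix":
        gene_mask = np.asarray(gene_mask)
        idx = np.flatnonzero(gene_mask) if gene_mask.dtype == bool else gene_mask
        return CountMatrix(
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            counts=self.counts[:, idx],
            panel=self.panel[idx],
            species_tag=self.species_tag[idx],
        )


def read_counts(mtx_path, features_path, barcodes_path) -> CountMatrix:
    """Read a MatrixMarket triplet (cells x genes) with TSV sidecars.

    Features sidecar: three headerless columns gene_id, panel, species_tag.
    Barcodes sidecar: one cell id per line.
    """
    mtx_path = Path(mtx_path)
    with open(mtx_path) as fh:
        header = fh.readline()
    if "coordinate" not in header:
        raise NonIntegerCountError(f"expected coordinate MTX, header: {header.strip()}")
    if "integer" not in header:
        raise NonIntegerCountError(f"MTX header does not declare integer field: {header.strip()}")
    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    features = pd.read_csv(features_path, sep="\t", header=None,
                           names=["gene_id", "panel", "species_tag"], dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, names=["cell_id"], dtype=str)
    if mat.shape[0] != len(barcodes):
        raise DimensionMismatchError(
            f"MTX declares {mat.shape[0]} cells but barcodes file has {len(barcodes)}")
    if mat.shape[1] != len(features):
        raise DimensionMismatchError(
            f"MTX declares {mat.shape[1]} genes but features file has {len(features)}")
    bad_panel = set(features["panel"]) - set(PANELS)
    if bad_panel:
        raise ValueError(f"unknown panel values {bad_panel}")
    return CountMatrix(
        cell_ids=barcodes["cell_id"].tolist(),
        gene_ids=features["gene_id"].tolist(),
        counts=mat,
        panel=features["panel"].to_numpy(dtype=object),
        species_tag=features["species_tag"].to_numpy(dtype=object),
    )


def write_counts(cm: CountMatrix, mtx_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), cm.counts.tocoo(), field="integer")
    pd.DataFrame({
        "gene_id": cm.gene_ids, "panel": cm.panel, "species_tag": cm.species_tag,
    }).to_csv(features_path, sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(barcodes_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_and_filter(counts: CountMatrix) -> tuple[pd.DataFrame, CountMatrix]:
    """Per-cell QC summary plus a filtered matrix.

    The summary covers every input cell (total transcripts over all probes,
    number of detected non-control genes, negative-probe rate).  The returned
    matrix keeps exactly the cells with at least one detected gene; retained
    counts are untouched (filtering is row subsetting only).
    """
    dense_total = np.asarray(counts.counts.sum(axis=1)).ravel()
    neg = counts.negative_probe_mask
    neg_total = np.asarray(counts.counts[:, np.flatnonzero(neg)].sum(axis=1)).ravel()
    real = counts.counts[:, np.flatnonzero(~neg)]
    unique_genes = np.asarray((real > 0).sum(axis=1)).ravel()
    qc = pd.DataFrame({
        "cell_id": counts.cell_ids,
        "total_transcripts": dense_total.astype(int),
        "unique_genes": unique_genes.astype(int),
        "negative_probe_rate": neg_total / np.maximum(dense_total, 1),
    })
    keep = np.flatnonzero(unique_genes >= 1)
    return qc, counts.subset_cells(keep)


# ---------------------------------------------------------------------------
# Affine matrix files
# ---------------------------------------------------------------------------

def read_affine(path, *, source_space: str = "image_px", target_space: str = "tissue_um",
                pixel_size_um: float = 1.0) -> AffineTransform2D:
    """Read a 3x3 plain-text affine matrix (row-major, whitespace or commas).

    An optional header line ``# source=... target=... pixel_size_um=...``
    overrides the keyword defaults, pinning the direction of the exported
    matrix in the file itself.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    if "=" in token:
                        key, val = token.split("=", 1)
                        if key == "source":
                            source_space = val
                        elif key == "target":
                            target_space = val
                        elif key == "pixel_size_um":
                            pixel_size_um = float(val)
                continue
            values.extend(float(tok) for tok in line.replace(",", " ").split())
    if len(values) != 9:
        raise ValueError(f"affine file must contain 9 numbers, found {len(values)}")
    return AffineTransform2D(np.array(values).reshape(3, 3),
                             source_space, target_space, pixel_size_um)


def write_affine(t: AffineTransform2D, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# source={t.source_space} target={t.target_space} "
                 f"pixel_size_um={float(t.pixel_size_um)!r}\n")
        for row in t.matrix:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Single-channel 8- or 16-bit TIFF as a 2-D array (row = y, col = x)."""
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ValueError(f"expected single-channel 2-D image, got shape {img.shape}")
    return img


def write_image(img: np.ndarray, path) -> None:
    if img.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"image dtype must be uint8 or uint16, got {img.dtype}")
    tifffile.imwrite(str(path), img)
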