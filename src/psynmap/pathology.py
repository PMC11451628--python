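"""Per-cell pathology calling from a thresholded IF channel.

The pSyn channel is thresholded (strictly greater than a single intensity
used across samples), connected components above a minimum area become
inclusions, and each inclusion's unweighted pixel centroid is mapped into
tissue micrometres through the registration affine.  A cell is pSyn-positive
iff at least one inclusion centroid falls inside its polygon (boundary points
count as inside; a centroid on a shared boundary goes to the cell with the
lexicographically smallest cell_id, so no centroid is double-counted).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
import skimage.measure

from .io import CellRecord
from .registration import AffineTransform2D, apply_affine


@dataclass
class InclusionSet:
    """Thresholded pathology objects.

    ``table`` has one row per inclusion: centroid_x/centroid_y (tissue um),
    area_px, peak_intensity.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)


def threshold_mask(image: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of pixels strictly above ``threshold``."""
    info_max = np.iinfo(image.dtype).max if np.issubdtype(image.dtype, np.integer) else None
    if info_max is not None and not (0 <= threshold <= info_max):
        raise ValueError(f"threshold {threshold} outside dtype range [0, {info_max}]")
    return image > threshold


def find_inclusions(mask: np.ndarray, affine: AffineTransform2D, *,
                    min_area: int = 4, connectivity: int = 8,
                    intensity_image: np.ndarray | None = None) -> InclusionSet:
    """Connected components of the mask, filtered by area, as inclusions.

    Centroids are unweighted means of member pixel centers (pixel center at
    its integer index), converted to tissue micrometres via ``affine``
    (which must map image_px -> tissue_um).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if affine.source_space != "image_px" or affine.target_space != "tissue_um":
        raise ValueError("find_inclusions needs an image_px -> tissue_um affine")
    labels = skimage.measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    props = skimage.measure.regionprops(labels, intensity_image=intensity_image)
    rows = []
    for p in props:
        if p.area < min_area:
            continue
        cy, cx = p.centroid  # (row, col) = (y, x)
        (tx, ty), = apply_affine([(cx, cy)], affine)
        rows.append({
            "centroid_x": tx,
            "centroid_y": ty,
            "area_px": int(p.area),
            "peak_intensity": float(p.intensity_max) if intensity_image is not None else np.nan,
        })
    table = pd.DataFrame(rows, columns=["centroid_x", "centroid_y", "area_px", "peak_intensity"])
    return InclusionSet(table)


# ---------------------------------------------------------------------------
# Point-in-polygon (even-odd rule, boundary-inclusive)
# ---------------------------------------------------------------------------

# squared distance below which a point counts as lying on an edge (1e-9 um)
_BOUNDARY_D2 = 1e-18


def _on_boundary(px: float, py: float, verts: np.ndarray) -> bool:
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    seg_len2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
    # distance from point to the supporting line, squared
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = cross ** 2 / np.where(seg_len2 > 0, seg_len2, 1.0)
    dot = (px - x1) * (x2 - x1) + (py - y1) * (y2 - y1)
    within = (dot >= 0.0) & (dot <= seg_len2)
    on_segment = np.any((d2 <= _BOUNDARY_D2) & within)
    at_vertex = np.any((px - x1) ** 2 + (py - y1) ** 2 <= _BOUNDARY_D2)
    return bool(on_segment or at_vertex)


def point_in_polygon(point, polygon) -> bool:
    """Even-odd (ray-casting) containment test; boundary points are inside.

    ``polygon`` is an (n, 2) open ring (closing vertex optional).
    """
    verts = np.asarray(polygon, dtype=float)
    if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    px, py = float(point[0]), float(point[1])
    if _on_boundary(px, py, verts):
        return True
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    # horizontal ray to +x; half-open rule on y avoids double-counting vertices
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_at = x1 + (py - y1) * (x2 - x1) / np.where(y2 != y1, y2 - y1, 1.0)
    crossings = np.count_nonzero(straddles & (x_at > px))
    return crossings % 2 == 1


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Vectorized even-odd test for many points against one polygon.

    Matches :func:`point_in_polygon` except that boundary handling uses the
    same ray-parity rule without the explicit edge test (callers exclude
    edge-adjacent points, or use the scalar form where the boundary rule
    matters).
    """
    verts = np.asarray(polygon, dtype=float)
    if len(verts) >= 2 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    pts = np.asarray(points, dtype=float)
    px, py = pts[:, 0:1], pts[:, 1:2]
    x1, y1 = verts[None, :, 0], verts[None, :, 1]
    x2, y2 = np.roll(verts[:, 0], -1)[None, :], np.roll(verts[:, 1], -1)[None, :]
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_at = x1 + (py - y1) * (x2 - x1) / np.where(y2 != y1, y2 - y1, 1.0)
    crossings = np.count_nonzero(straddles & (x_at > px), axis=1)
    return crossings % 2 == 1


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_pathology(cells: list[CellRecord], inclusions: InclusionSet,
                     ) -> tuple[list[CellRecord], pd.DataFrame]:
    """Label each cell positive/negative by inclusion-centroid containment.

    Returns the relabelled cells (new records; inputs are not mutated) and a
    per-inclusion assignment table with the assigned ``cell_id`` or the
    marker ``orphan`` for centroids contained in no cell.  Each inclusion is
    assigned to at most one cell; a centroid on a shared boundary goes to the
    lexicographically smallest cell_id.
    """
    centroids = inclusions.centroids
    assigned = np.full(len(centroids), None, dtype=object)
    positive: set[int] = set()
    if len(cells) and len(centroids):
        polys = np.array([c.shapely_polygon for c in cells], dtype=object)
        tree = shapely.STRtree(polys)
        pts = shapely.points(centroids[:, 0], centroids[:, 1])
        # STRtree prefilter on bounding boxes; exact even-odd test decides.
        cand_pt, cand_cell = tree.query(pts)
        for k in range(len(centroids)):
            hits = cand_cell[cand_pt == k]
            containing = [i for i in hits
                          if point_in_polygon(centroids[k], cells[i].polygon)]
            if containing:
                winner = min(containing, key=lambda i: cells[i].cell_id)
                assigned[k] = cells[winner].cell_id
                positive.add(winner)
    out = [replace(c, psyn_status="positive" if i in positive else "negative")
           for i, c in enumerate(cells)]
    assignment = inclusions.table.copy()
    assignment["cell_id"] = [a if a is not None else "orphan" for a in assigned]
    return out, assignment


def call_pathology(cells: list[CellRecord], image: np.ndarray,
                   affine: AffineTransform2D, *, threshold: float | None = None,
                   threshold_frac: float = 0.25, min_area: int = 4,
                   connectivity: int = 8) -> tuple[list[CellRecord], InclusionSet, pd.DataFrame]:
    """Threshold -> find inclusions -> assign, in one call.

    ``threshold`` defaults to ``threshold_frac`` of the image dtype maximum
    (the absolute IF threshold is a free parameter of the assay; one value
    is used across samples).
    """
    if threshold is None:
        threshold = threshold_frac * np.iinfo(image.dtype).max
    mask = threshold_mask(image, threshold)
    incl = find_inclusions(mask, affine, min_area=min_area, connectivity=connectivity,
                           intensity_image=image)
    called, assignment = assign_pathology(cells, incl)
    return called, incl, assignment
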