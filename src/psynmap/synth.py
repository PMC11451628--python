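"""Synthetic imaging-spatial-transcriptomics study generator.

Produces a complete in-silico experiment with the structure the downstream
analysis assumes: layer-banded cortical cell types segmented by nuclear
expansion, negative-binomial marker/driver expression with per-cell library
size factors, a non-cross-reacting human SNCA transgene with genotype and
sex effects, a logistic per-cell pathology model driven by realized hSNCA
and Plk2 expression, a rendered pathology IF image offset by a known affine
transform, and negative control probes — together with the ground truth
needed to score recovery.

Geometry emulates 5-um nuclear-expansion segmentation: nuclei are placed by
dart-throwing with a minimum spacing, and each cell polygon is the nucleus
disk dilated by the expansion distance, clipped to the nucleus' Voronoi
region so neighboring polygons never overlap.

Every stochastic step draws from a single :class:`numpy.random.Generator`
in a fixed order, so a fixed seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .errors import BlobOutOfBoundsError, DensityInfeasibleError
from .expression import ReferenceProfiles, _zscore_columns
from .io import (CellRecord, CountMatrix, write_affine, write_cells,
                 write_counts, write_image)
from .registration import AffineTransform2D, apply_affine, invert_affine

DEFAULT_TYPES = ("L2/3 IT", "L4/5 IT", "L5 ET", "L5 NP", "L6 CT", "InN")

HSNCA, MSNCA, PLK2 = "hSNCA", "mSnca", "Plk2"


def _default_layout() -> list[tuple[str, tuple[float, float], float]]:
    # (cell_type, depth band as fraction of cortical depth, density cells/mm^2)
    return [
        ("L2/3 IT", (0.00, 0.35), 1400.0),
        ("L4/5 IT", (0.35, 0.55), 1400.0),
        ("L5 ET", (0.55, 0.75), 800.0),
        ("L5 NP", (0.55, 0.75), 500.0),
        ("L6 CT", (0.75, 1.00), 1200.0),
        ("InN", (0.00, 1.00), 300.0),
    ]


def build_expression_table(types, plk2_means=None, *, marker_mean: float = 6.0,
                           marker_background: float = 0.3, n_targets: int = 20,
                           n_housekeeping: int = 12) -> pd.DataFrame:
    """Per-type NB mean counts per cell (library factor 1).

    Three high/low markers per type, endogenous mouse Snca, a per-type Plk2
    gradient (the candidate vulnerability driver), a block of DE-target
    genes, and housekeeping genes.  hSNCA and negative probes are appended
    at draw time, not here.
    """
    types = list(types)
    genes: dict[str, np.ndarray] = {}
    for t in types:
        tag = t.replace("/", "").replace(" ", "_")
        for k in range(1, 4):
            col = np.full(len(types), marker_background)
            col[types.index(t)] = marker_mean
            genes[f"{tag}_mk{k}"] = col
    genes[MSNCA] = np.full(len(types), 3.0)
    if plk2_means is None:
        plk2_means = np.full(len(types), 2.0)
    genes[PLK2] = np.asarray(plk2_means, dtype=float)
    for k in range(1, n_targets + 1):
        genes[f"target{k:02d}"] = np.full(len(types), 2.0)
    for k in range(1, n_housekeeping + 1):
        genes[f"hk{k:02d}"] = np.full(len(types), 4.0)
    return pd.DataFrame(genes, index=types)


def _default_expression() -> pd.DataFrame:
    # Plk2 gradient across types drives the default vulnerability ordering
    return build_expression_table(DEFAULT_TYPES,
                                  plk2_means=[2.0, 4.0, 8.0, 1.0, 0.5, 0.1])


@dataclass
class GenerativeParams:
    """All knobs of the synthetic study; defaults emulate the source assay.

    Expression means are counts per cell at library factor 1; the pathology
    logit acts on realized log-normalized expression (scale factor 1e4).
    """

    n_samples_per_genotype: int = 4
    sex_ratio: float = 0.5  # fraction of male animals per genotype
    tissue_width_um: float = 800.0
    tissue_depth_um: float = 1200.0
    region: str = "cortex"
    region_layout: list = field(default_factory=_default_layout)
    nucleus_radius_um: float = 3.0
    expansion_um: float = 5.0
    min_spacing_um: float = 8.0
    type_mean_expression: pd.DataFrame = field(default_factory=_default_expression)
    nb_dispersion: float = 0.1
    libsize_lognormal: tuple[float, float] = (0.0, 0.25)
    # hSNCA transgene: per-type tg mean, male multiplier, non-tg leak mean
    hsnca_tg_mean: dict = field(default_factory=lambda: {
        t: (5.0 if t == "InN" else 10.0) for t in DEFAULT_TYPES})
    hsnca_male_multiplier: float = 1.3
    hsnca_leak_mean: float = 0.0
    negative_probe_mean: float = 0.05
    n_negative_probes: int = 5
    # logistic pathology model on log-normalized expression
    beta0_type: dict = field(default_factory=lambda: {t: -8.3 for t in DEFAULT_TYPES})
    beta_hsnca: float = 0.4
    beta_plk2: float = 0.9
    male_pathology_offset: float = 0.0  # no sex effect on pathology by default
    # pSyn-status expression effects (log2FC applied to pSyn+ tg cells)
    psyn_log2fc: dict = field(default_factory=dict)
    # rendering
    inclusion_radius_px: int = 3
    inclusion_intensity: float = 30000.0
    background_noise_sd: float = 0.0
    image_margin_px: int = 20
    pixel_size_um: float = 1.0
    true_affine: AffineTransform2D | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_affine is None:
            # image px -> tissue um: unit scale, 20 um offset so the canvas
            # covers the tissue with a margin
            m = np.array([[1.0, 0.0, -20.0], [0.0, 1.0, -20.0], [0.0, 0.0, 1.0]])
            self.true_affine = AffineTransform2D(m, "image_px", "tissue_um",
                                                 self.pixel_size_um)
        for t, (lo, hi), d in self.region_layout:
            if not (0 <= lo < hi <= 1) or d <= 0:
                raise ValueError(f"bad layout entry {(t, (lo, hi), d)}")
        if (self.type_mean_expression.to_numpy() < 0).any():
            raise ValueError("NB means must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return list(self.type_mean_expression.index)

    @property
    def gene_ids(self) -> list[str]:
        genes = list(self.type_mean_expression.columns) + [HSNCA]
        genes += [f"NegControl{k}" for k in range(1, self.n_negative_probes + 1)]
        return genes


@dataclass
class SyntheticTruth:
    """Ground truth for scoring: per-cell type/pathology and inclusion sites."""

    cells: pd.DataFrame       # cell_id, sample_id, true_type, true_psyn, true_hsnca_rate
    inclusions: pd.DataFrame  # cell_id, sample_id, x, y (tissue um)
    params: GenerativeParams


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _dart_throw(rng: np.random.Generator, accepted: list, grid: dict,
                bounds: tuple[float, float, float, float], n_target: int,
                spacing: float, max_tries: int) -> list[int]:
    """Greedy minimum-distance sampling into a shared spatial hash grid."""
    x0, y0, x1, y1 = bounds
    cell = spacing
    placed = 0
    out = []
    tries = 0
    while placed < n_target and tries < max_tries:
        tries += 1
        px = rng.uniform(x0, x1)
        py = rng.uniform(y0, y1)
        gx, gy = int(px // cell), int(py // cell)
        ok = True
        for ix in range(gx - 1, gx + 2):
            for iy in range(gy - 1, gy + 2):
                for j in grid.get((ix, iy), ()):
                    qx, qy = accepted[j]
                    if (px - qx) ** 2 + (py - qy) ** 2 < spacing ** 2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            j = len(accepted)
            accepted.append((px, py))
            grid.setdefault((gx, gy), []).append(j)
            out.append(j)
            placed += 1
    if placed < n_target:
        raise DensityInfeasibleError(
            f"placed {placed}/{n_target} nuclei at spacing {spacing} um in {bounds}")
    return out


def _voronoi_clipped_disks(pts: np.ndarray, radius: float) -> list[np.ndarray]:
    """Polygon per nucleus: disk(radius) clipped to the nucleus' Voronoi region."""
    if len(pts) == 1:  # no neighbors: the polygon is the full expansion disk
        disk = shapely.Point(pts[0]).buffer(radius, quad_segs=8)
        return [np.asarray(disk.exterior.coords)[:-1]]
    mp = shapely.MultiPoint(pts)
    envelope = shapely.box(pts[:, 0].min() - 4 * radius, pts[:, 1].min() - 4 * radius,
                           pts[:, 0].max() + 4 * radius, pts[:, 1].max() + 4 * radius)
    regions = np.array(list(shapely.voronoi_polygons(mp, extend_to=envelope).geoms),
                       dtype=object)
    tree = shapely.STRtree(regions)
    pt_geoms = shapely.points(pts[:, 0], pts[:, 1])
    pi, ri = tree.query(pt_geoms, predicate="within")
    region_of = dict(zip(pi.tolist(), ri.tolist()))
    if len(region_of) != len(pts):
        # points on region edges (degenerate); fall back to nearest region
        for k in range(len(pts)):
            if k not in region_of:
                region_of[k] = int(tree.nearest(pt_geoms[k]))
    disks = shapely.buffer(pt_geoms, radius, quad_segs=8)
    polys = []
    for k in range(len(pts)):
        poly = shapely.intersection(disks[k], regions[region_of[k]])
        if poly.geom_type != "Polygon" or poly.is_empty:  # pragma: no cover
            poly = disks[k]
        polys.append(np.asarray(poly.exterior.coords)[:-1])
    return polys


def generate_cells(params: GenerativeParams, sample_id: str, genotype: str,
                   sex: str, rng: np.random.Generator,
                   ) -> tuple[list[CellRecord], np.ndarray]:
    """Segmented cells for one sample; returns (records, true type labels)."""
    accepted: list[tuple[float, float]] = []
    grid: dict = {}
    type_of: list[str] = []
    w, d = params.tissue_width_um, params.tissue_depth_um
    for t, (lo, hi), dens in params.region_layout:
        area_mm2 = (w * (hi - lo) * d) / 1e6
        n_target = int(round(dens * area_mm2))
        idx = _dart_throw(rng, accepted, grid, (0.0, lo * d, w, hi * d),
                          n_target, params.min_spacing_um, max_tries=300 * max(n_target, 1))
        type_of.extend([t] * len(idx))
    pts = np.asarray(accepted)
    order = np.argsort(pts[:, 1] * w * 10 + pts[:, 0], kind="stable")
    pts = pts[order]
    types = np.asarray(type_of, dtype=object)[order]
    polys = _voronoi_clipped_disks(pts, params.nucleus_radius_um + params.expansion_um)
    cells = []
    for k, (p, verts) in enumerate(zip(pts, polys)):
        cells.append(CellRecord(
            cell_id=f"{sample_id}_c{k:05d}",
            sample_id=sample_id,
            genotype=genotype,
            sex=sex,
            region=params.region,
            nucleus_centroid=(float(p[0]), float(p[1])),
            polygon=verts,
        ))
    return cells, types


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson mixture; variance mean + alpha * mean^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = np.where(mean > 0, rng.gamma(shape, 1.0, size=mean.shape) * mean * alpha, 0.0)
    return rng.poisson(lam)


def generate_counts(cells: list[CellRecord], types: np.ndarray,
                    params: GenerativeParams, rng: np.random.Generator,
                    true_psyn: np.ndarray | None = None,
                    ) -> tuple[CountMatrix, np.ndarray]:
    """NB counts for one sample's cells; returns (matrix, hSNCA mean rates).

    hSNCA is drawn only for tg cells (plus any leak), with the male
    multiplier applied to the mean; negative probes have a low fixed mean
    independent of cell type.  When ``true_psyn`` is given, the configured
    pSyn log2 fold changes are applied to positive cells' means (used by the
    two-pass pathology coupling in :func:`generate_study`).
    """
    n = len(cells)
    type_idx = pd.Index(params.type_mean_expression.index).get_indexer(types)
    if (type_idx < 0).any():
        raise ValueError("cell type missing from type_mean_expression")
    meanlog, sdlog = params.libsize_lognormal
    L = rng.lognormal(meanlog, sdlog, size=n)
    base_mean = params.type_mean_expression.to_numpy()[type_idx]  # n x genes
    base_mean = base_mean * L[:, None]
    genotype = np.array([c.genotype for c in cells], dtype=object)
    sex = np.array([c.sex for c in cells], dtype=object)
    hs_mean = np.array([params.hsnca_tg_mean[t] for t in types], dtype=float)
    hs_rate = np.where(genotype == "tg", hs_mean, params.hsnca_leak_mean)
    hs_rate = hs_rate * np.where(sex == "M", params.hsnca_male_multiplier, 1.0) * L
    if true_psyn is not None and params.psyn_log2fc:
        genes = list(params.type_mean_expression.columns)
        fc = np.ones(len(genes))
        for g, lfc in params.psyn_log2fc.items():
            fc[genes.index(g)] = 2.0 ** lfc
        base_mean = np.where(true_psyn[:, None], base_mean * fc[None, :], base_mean)
    counts_main = _nb_draw(rng, base_mean, params.nb_dispersion)
    counts_hs = _nb_draw(rng, hs_rate[:, None], params.nb_dispersion)
    neg_mean = np.full((n, params.n_negative_probes), params.negative_probe_mean) * L[:, None]
    counts_neg = _nb_draw(rng, neg_mean, 0.0)
    mat = np.hstack([counts_main, counts_hs, counts_neg]).astype(np.int64)
    genes = params.gene_ids
    panel = np.array(
        ["custom" if g in (PLK2, HSNCA) or g.startswith("target") else
         "negative_probe" if g.startswith("NegControl") else "base" for g in genes],
        dtype=object)
    species = np.array(
        ["human" if g == HSNCA else
         "control" if g.startswith("NegControl") else "mouse" for g in genes],
        dtype=object)
    cm = CountMatrix(
        cell_ids=[c.cell_id for c in cells],
        gene_ids=genes,
        counts=mat,
        panel=panel,
        species_tag=species,
    )
    return cm, hs_rate


# ---------------------------------------------------------------------------
# Pathology truth
# ---------------------------------------------------------------------------

def _lognorm_gene(counts: CountMatrix, gene: str, scale_factor: float = 1e4) -> np.ndarray:
    keep = ~counts.negative_probe_mask
    lib = np.asarray(counts.counts[:, np.flatnonzero(keep)].sum(axis=1), float).ravel()
    col = np.asarray(counts.counts[:, counts.gene_index(gene)].todense(), float).ravel()
    return np.log1p(col * scale_factor / np.maximum(lib, 1.0))


def assign_true_pathology(cells: list[CellRecord], types: np.ndarray,
                          counts: CountMatrix, params: GenerativeParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Bernoulli pSyn truth from the logistic model on realized expression.

    P(pSyn+) = logistic(beta0_type + beta_hsnca * x_hSNCA + beta_plk2 * x_Plk2
    [+ male offset]); non-tg cells are forced negative.
    """
    x_h = _lognorm_gene(counts, HSNCA)
    x_p = _lognorm_gene(counts, PLK2)
    beta0 = np.array([params.beta0_type[t] for t in types], dtype=float)
    sex = np.array([c.sex for c in cells], dtype=object)
    logit = (beta0 + params.beta_hsnca * x_h + params.beta_plk2 * x_p
             + np.where(sex == "M", params.male_pathology_offset, 0.0))
    prob = 1.0 / (1.0 + np.exp(-logit))
    genotype = np.array([c.genotype for c in cells], dtype=object)
    prob = np.where(genotype == "tg", prob, 0.0)
    return rng.random(len(cells)) < prob


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_pathology_image(cells: list[CellRecord], true_psyn: np.ndarray,
                           params: GenerativeParams, rng: np.random.Generator,
                           ) -> tuple[np.ndarray, AffineTransform2D]:
    """Render one blob per pSyn+ cell at its nucleus, plus background noise.

    Returns the uint16 image and the affine mapping image px -> tissue um.
    """
    aff = params.true_affine
    inv = invert_affine(aff)
    corners_um = [(0, 0), (params.tissue_width_um, 0),
                  (0, params.tissue_depth_um),
                  (params.tissue_width_um, params.tissue_depth_um)]
    corners_px = apply_affine(corners_um, inv)
    if corners_px.min() < 0:
        raise BlobOutOfBoundsError("affine maps tissue off the pixel canvas")
    m = params.image_margin_px
    shape = (int(np.ceil(corners_px[:, 1].max())) + m,
             int(np.ceil(corners_px[:, 0].max())) + m)
    img = np.zeros(shape, dtype=float)
    pos = [c for c, p in zip(cells, true_psyn) if p]
    if pos:
        centers = apply_affine([c.nucleus_centroid for c in pos], inv)
        r = params.inclusion_radius_px
        for cx, cy in centers:
            if not (0 <= cx < shape[1] and 0 <= cy < shape[0]):
                raise BlobOutOfBoundsError(f"inclusion center ({cx:.1f}, {cy:.1f}) px off canvas")
            # sub-pixel placement: light up pixel centers within r of the
            # continuous blob center, so the object centroid tracks the nucleus
            y0, y1 = max(int(cy) - r - 1, 0), min(int(cy) + r + 2, shape[0])
            x0, x1 = max(int(cx) - r - 1, 0), min(int(cx) + r + 2, shape[1])
            yy, xx = np.mgrid[y0:y1, x0:x1]
            sub = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
            img[y0:y1, x0:x1] = np.where(sub, params.inclusion_intensity, img[y0:y1, x0:x1])
    if params.background_noise_sd > 0:
        img += rng.normal(0.0, params.background_noise_sd, size=shape)
    return np.clip(img, 0, 65535).astype(np.uint16), aff


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one run of the generator produces."""

    cells: list[CellRecord]
    cell_types_true: np.ndarray
    counts: CountMatrix
    truth: SyntheticTruth
    images: dict  # sample_id -> (uint16 image, AffineTransform2D)
    sample_table: pd.DataFrame  # sample_id, genotype, sex

    @property
    def tg_sample_ids(self) -> list[str]:
        return self.sample_table.loc[self.sample_table.genotype == "tg",
                                     "sample_id"].tolist()


def _sample_plan(params: GenerativeParams) -> pd.DataFrame:
    rows = []
    n = params.n_samples_per_genotype
    n_male = int(round(params.sex_ratio * n))
    for genotype in ("tg", "non_tg"):
        short = "tg" if genotype == "tg" else "nontg"
        for k in range(n):
            rows.append({"sample_id": f"{short}{k + 1}",
                         "genotype": genotype,
                         "sex": "M" if k < n_male else "F"})
    return pd.DataFrame(rows)


def generate_study(params: GenerativeParams, seed: int | None = None,
                   render: bool = True) -> SyntheticStudy:
    """Generate all samples of the study under one seeded RNG stream.

    ``render=False`` skips the pathology image rendering (useful when only
    the expression/pathology truth is needed); ``images`` is then empty.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    plan = _sample_plan(params)
    all_cells: list[CellRecord] = []
    all_types: list[np.ndarray] = []
    mats: list[CountMatrix] = []
    hs_rates: list[np.ndarray] = []
    psyn: list[np.ndarray] = []
    images: dict = {}
    for _, row in plan.iterrows():
        cells, types = generate_cells(params, row.sample_id, row.genotype, row.sex, rng)
        cm, hs_rate = generate_counts(cells, types, params, rng)
        truth_psyn = assign_true_pathology(cells, types, cm, params, rng)
        if params.psyn_log2fc and truth_psyn.any():
            # redraw counts with status-dependent means, pathology held fixed
            cm, hs_rate = generate_counts(cells, types, params, rng,
                                          true_psyn=truth_psyn)
        if render:
            img, aff = render_pathology_image(cells, truth_psyn, params, rng)
            images[row.sample_id] = (img, aff)
        all_cells.extend(cells)
        all_types.append(types)
        mats.append(cm)
        hs_rates.append(hs_rate)
        psyn.append(truth_psyn)
    types_arr = np.concatenate(all_types)
    psyn_arr = np.concatenate(psyn)
    counts = CountMatrix(
        cell_ids=[c.cell_id for c in all_cells],
        gene_ids=mats[0].gene_ids,
        counts=np.vstack([m.to_dense() for m in mats]),
        panel=mats[0].panel,
        species_tag=mats[0].species_tag,
    )
    truth_cells = pd.DataFrame({
        "cell_id": [c.cell_id for c in all_cells],
        "sample_id": [c.sample_id for c in all_cells],
        "true_type": types_arr,
        "true_psyn": psyn_arr,
        "true_hsnca_rate": np.concatenate(hs_rates),
    })
    incl = truth_cells.loc[truth_cells.true_psyn, ["cell_id", "sample_id"]].copy()
    coords = {c.cell_id: c.nucleus_centroid for c in all_cells}
    incl["x"] = [coords[c][0] for c in incl.cell_id]
    incl["y"] = [coords[c][1] for c in incl.cell_id]
    truth = SyntheticTruth(truth_cells.reset_index(drop=True),
                           incl.reset_index(drop=True), params)
    return SyntheticStudy(all_cells, types_arr, counts, truth, images, plan)


def programmed_rate_params(rates: dict[str, float], cells_per_type: int = 2000,
                           **overrides) -> GenerativeParams:
    """Study condition with exact per-type pathology rates.

    The logistic slopes are zeroed and each type's intercept set to
    logit(rate), so the marginal pSyn+ probability of every tg cell of a
    type equals the programmed rate; the tissue is laid out in equal bands
    sized to hold ``cells_per_type`` cells of each type per sample.
    """
    types = list(rates)
    k = len(types)
    width, depth = 1200.0, 400.0 * k
    band_area_mm2 = width * (depth / k) / 1e6
    layout = [(t, (i / k, (i + 1) / k), cells_per_type / band_area_mm2)
              for i, t in enumerate(types)]
    eps = 1e-12
    beta0 = {t: float(np.log((r + eps) / (1 - r + eps))) for t, r in rates.items()}
    return GenerativeParams(
        tissue_width_um=width, tissue_depth_um=depth,
        region_layout=layout,
        type_mean_expression=build_expression_table(types, n_targets=10,
                                                    n_housekeeping=8),
        hsnca_tg_mean={t: 10.0 for t in types},
        beta0_type=beta0, beta_hsnca=0.0, beta_plk2=0.0,
        **overrides)


def cortex10_params(cells_per_type: int = 500, **overrides) -> GenerativeParams:
    """A richer cortical layout with ten annotated types.

    Emulates the type diversity of an annotated cortical section (IT/ET/NP/CT
    excitatory subclasses across depth plus interneurons) with a Plk2
    expression gradient across types; used for vulnerability-screen recovery
    studies where the across-type regression needs realistic type counts.
    """
    types = ["L2/3 IT", "L4 IT", "L4/5 IT", "L5 IT", "L5 ET",
             "L5 NP", "L6 IT", "L6 CT", "L6b", "InN"]
    plk2 = [2.0, 3.0, 4.0, 5.0, 8.0, 0.5, 1.5, 1.0, 0.7, 0.1]
    k = len(types)
    width, depth = 1000.0, 160.0 * k
    band_area_mm2 = width * (depth / k) / 1e6
    layout = [(t, (i / k, (i + 1) / k), cells_per_type / band_area_mm2)
              for i, t in enumerate(types)]
    return GenerativeParams(
        tissue_width_um=width, tissue_depth_um=depth,
        region_layout=layout,
        type_mean_expression=build_expression_table(types, plk2_means=plk2),
        hsnca_tg_mean={t: (5.0 if t == "InN" else 10.0) for t in types},
        beta0_type={t: -8.3 for t in types},
        **overrides)


def reference_profiles_from_params(params: GenerativeParams,
                                   scale_factor: float = 1e4) -> ReferenceProfiles:
    """Expected non-tg log-normalized profile per type, z-scored across types.

    Serves as the miniature annotation reference for correlation-based cell
    typing (the transgene and negative probes are excluded).
    """
    mu = params.type_mean_expression.to_numpy(dtype=float)
    lib = mu.sum(axis=1, keepdims=True)
    vals = np.log1p(mu * scale_factor / lib)
    scaled = _zscore_columns(vals)
    return ReferenceProfiles(list(params.type_mean_expression.index),
                             list(params.type_mean_expression.columns), scaled)


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write the study in the package's on-disk formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "mtx": outdir / "counts.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "truth": outdir / "truth.csv",
        "reference": outdir / "reference.tsv",
        "samples": outdir / "samples.csv",
    }
    write_cells(study.cells, paths["cells"])
    write_counts(study.counts, paths["mtx"], paths["features"], paths["barcodes"])
    truth = study.truth.cells.copy()
    truth.to_csv(paths["truth"], index=False)
    ref = reference_profiles_from_params(study.truth.params)
    ref.to_frame().T.to_csv(paths["reference"], sep="\t")  # gene rows, type cols
    study.sample_table.to_csv(paths["samples"], index=False)
    for sample_id, (img, aff) in study.images.items():
        ipath = outdir / f"psyn_{sample_id}.tif"
        apath = outdir / f"affine_{sample_id}.txt"
        write_image(img, ipath)
        write_affine(aff, apath)
        paths[f"image_{sample_id}"] = ipath
        paths[f"affine_{sample_id}"] = apath
    return paths
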