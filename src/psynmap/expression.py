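"""Expression normalization, scaling, reference-profile cell typing,
cross-modality comparison and cortical depth profiling.

Normalization follows the library-size convention:
``value_ij = ln(1 + c_ij * SF / L_i)`` where ``L_i`` is the total count of
cell *i* over non-negative-probe genes and SF is the scale factor (1e4 by
default for the spatial data; 1e6 mimics reference-atlas processing).
Negative control probes contribute neither to the library size nor to the
normalized gene set.

"Scaled" expression means per-gene z-scores across cells (n-1 denominator,
no clipping), optionally after regressing out a per-cell covariate such as
total read count.  Group-average expression is reported on the
``expm1(log-normalized)`` scale, the convention used for per-type expression
summaries in imaging spatial transcriptomics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import EmptyGroupError, NoSharedGenesError, ZeroLibrarySizeError
from .io import CellRecord, CountMatrix, UNASSIGNED

DEFAULT_SCALE_FACTOR = 1e4


@dataclass
class NormalizedMatrix:
    """Log-normalized cells x genes expression (negative probes removed)."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # dense cells x genes, float
    scale_factor: float
    library_size: np.ndarray  # per-cell totals over non-negative-probe genes

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class ReferenceProfiles:
    """Per-type expression profiles z-scored across types within each gene."""

    cell_types: list[str]
    genes: list[str]
    scaled_mean: np.ndarray  # types x genes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scaled_mean, index=self.cell_types, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceProfiles":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def lognormalize(counts: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR,
                 ) -> NormalizedMatrix:
    """Library-size normalize and log1p-transform, dropping negative probes."""
    keep = ~counts.negative_probe_mask
    sub = counts.counts[:, np.flatnonzero(keep)]
    lib = np.asarray(sub.sum(axis=1), dtype=float).ravel()
    if np.any(lib == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(lib == 0)[:5]]
        raise ZeroLibrarySizeError(f"cells with zero library size, e.g. {bad}")
    dense = np.asarray(sub.todense(), dtype=float)
    values = np.log1p(dense * scale_factor / lib[:, None])
    return NormalizedMatrix(
        cell_ids=list(counts.cell_ids),
        gene_ids=[g for g, k in zip(counts.gene_ids, keep) if k],
        values=values,
        scale_factor=scale_factor,
        library_size=lib,
    )


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = np.zeros_like(values, dtype=float)
    # columns constant up to floating-point residue map to all zeros
    ok = sd > 1e-10 * (np.abs(values).max(axis=0) + 1.0)
    out[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
    return out


def scale_genes(norm: NormalizedMatrix, covariate: np.ndarray | None = None) -> np.ndarray:
    """Per-gene z-scores, optionally after regressing out a per-cell covariate.

    With a covariate, each gene is replaced by the residuals of an OLS fit of
    its normalized values on the covariate (with intercept), then z-scored.
    Constant genes map to all zeros.
    """
    if norm.n_cells < 2:
        raise ValueError("scaling needs at least 2 cells")
    values = norm.values
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.shape != (norm.n_cells,):
            raise ValueError("covariate must be one value per cell")
        X = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        values = values - X @ beta
    return _zscore_columns(values)


def average_expression(norm: NormalizedMatrix, groups) -> pd.DataFrame:
    """Group x gene matrix of mean expm1(log-normalized) expression."""
    groups = np.asarray(groups)
    if groups.shape != (norm.n_cells,):
        raise ValueError("groups must be one label per cell")
    expm1 = np.expm1(norm.values)
    labels = pd.unique(groups)
    rows = []
    for lab in labels:
        mask = groups == lab
        if not mask.any():
            raise EmptyGroupError(f"group {lab!r} has no cells")
        rows.append(expm1[mask].mean(axis=0))
    return pd.DataFrame(rows, index=pd.Index(labels, name="group"), columns=norm.gene_ids)


def make_reference_profiles(norm: NormalizedMatrix, labels) -> ReferenceProfiles:
    """Build reference profiles from labelled cells: average per type, then
    z-score each gene across types."""
    avg = average_expression(norm, labels)
    scaled = _zscore_columns(avg.to_numpy(dtype=float))
    return ReferenceProfiles(list(avg.index), list(avg.columns), scaled)


def _pearson_rows(mat: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``mat`` and each row of ``profiles``."""
    a = mat - mat.mean(axis=1, keepdims=True)
    b = profiles - profiles.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a @ b.T) / np.outer(na, nb)
    return np.nan_to_num(r, nan=-np.inf)


def assign_cell_types(norm: NormalizedMatrix, reference: ReferenceProfiles,
                      min_r: float = 0.1) -> np.ndarray:
    """Assign each cell the reference type whose profile it best correlates with.

    The per-cell vector is the gene-scaled (z-scored across cells) expression
    over the genes shared with the reference; Pearson r is computed against
    each reference row and the argmax wins.  Cells whose best r falls below
    ``min_r`` are left unassigned.  Ties break to the first type in reference
    order.
    """
    query_genes = set(norm.gene_ids)
    # genes constant across reference types have an all-zero scaled profile
    # and carry no type information; drop them before correlating
    informative = np.any(reference.scaled_mean != 0, axis=0)
    shared = [g for g, keep in zip(reference.genes, informative)
              if keep and g in query_genes]
    if len(shared) < 3:
        raise NoSharedGenesError(
            f"only {len(shared)} informative genes shared with the reference (need >=3)")
    scaled = _zscore_columns(norm.values)
    qidx = [norm.gene_ids.index(g) for g in shared]
    ridx = [reference.genes.index(g) for g in shared]
    r = _pearson_rows(scaled[:, qidx], reference.scaled_mean[:, ridx])
    best = np.argmax(r, axis=1)
    best_r = r[np.arange(len(best)), best]
    labels = np.array([reference.cell_types[i] for i in best], dtype=object)
    labels[best_r < min_r] = UNASSIGNED
    return labels


def profile_similarity(a: ReferenceProfiles, b: ReferenceProfiles) -> pd.DataFrame:
    """Type x type Pearson similarity over the shared gene set."""
    shared = [g for g in a.genes if g in set(b.genes)]
    if len(shared) < 3:
        raise NoSharedGenesError(f"only {len(shared)} shared genes (need >=3)")
    ai = [a.genes.index(g) for g in shared]
    bi = [b.genes.index(g) for g in shared]
    r = _pearson_rows(a.scaled_mean[:, ai], b.scaled_mean[:, bi])
    return pd.DataFrame(r, index=a.cell_types, columns=b.cell_types)


def per_gene_cross_modality_regression(scaled_a: pd.DataFrame, scaled_b: pd.DataFrame,
                                       ) -> pd.DataFrame:
    """Per-gene OLS of modality b on modality a across shared cell types.

    Both inputs are type x gene scaled-expression frames with identical type
    index.  Genes constant in ``a`` get NaN slope and ``degenerate=True``.
    """
    if list(scaled_a.index) != list(scaled_b.index):
        raise ValueError("both matrices must cover the same cell types in order")
    if len(scaled_a.index) < 3:
        raise ValueError("need >=3 cell types for per-gene regression")
    shared = [g for g in scaled_a.columns if g in set(scaled_b.columns)]
    rows = []
    for g in shared:
        x = scaled_a[g].to_numpy(dtype=float)
        y = scaled_b[g].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"gene": g, "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "p": np.nan, "degenerate": True})
            continue
        res = scipy.stats.linregress(x, y)
        rows.append({"gene": g, "slope": res.slope, "intercept": res.intercept,
                     "r2": res.rvalue ** 2, "p": res.pvalue, "degenerate": False})
    return pd.DataFrame(rows).set_index("gene")


def depth_profile(cells: list[CellRecord], depth_axis: tuple[tuple[float, float], tuple[float, float]],
                  n_bins: int = 10, labels=None) -> pd.DataFrame:
    """Per-type distribution of cells along a depth axis.

    ``depth_axis`` is (origin, unit direction).  Each cell's nucleus is
    projected onto the axis; projections are rescaled to [0, 1] over the
    cells supplied; per type the histogram over ``n_bins`` equal bins is
    normalized to sum to 1.
    """
    origin, direction = np.asarray(depth_axis[0], float), np.asarray(depth_axis[1], float)
    if not np.isclose(np.linalg.norm(direction), 1.0):
        raise ValueError("direction must be a unit vector")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if labels is None:
        labels = np.array([c.cell_type for c in cells], dtype=object)
    else:
        labels = np.asarray(labels, dtype=object)
    pts = np.array([c.nucleus_centroid for c in cells], dtype=float)
    proj = (pts - origin) @ direction
    lo, hi = proj.min(), proj.max()
    frac = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    types = pd.unique(labels)
    rows = []
    for t in types:
        h, _ = np.histogram(np.clip(frac[labels == t], 0, 1), bins=edges)
        total = h.sum()
        rows.append(h / total if total else h.astype(float))
    cols = [f"bin_{i}" for i in range(n_bins)]
    return pd.DataFrame(rows, index=pd.Index(types, name="cell_type"), columns=cols)
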