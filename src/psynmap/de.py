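"""Pseudo-bulk negative-binomial differential expression and per-cell GLMs.

Counts are aggregated into (cell type, sample, pSyn group) units by exact
integer summation; units are normalized with median-of-ratios size factors;
each gene is tested with a log-link negative-binomial GLM Wald test between
a reference and a contrast group (gene-wise dispersion by profile maximum
likelihood with a moment fallback, floored at 1e-8).  Benjamini-Hochberg
correction is applied per contrast over the testable genes.

The two-group model with unit size factor :math:`s_u` is

.. math:: y_{ug} \\sim \\mathrm{NB}(\\mu_{ug},\\ \\alpha_g), \\qquad
          \\mu_{ug} = s_u\\,\\lambda_{c(u),g},

so the Wald statistic is :math:`\\hat\\beta/\\mathrm{SE}` with
:math:`\\hat\\beta = \\ln\\hat\\lambda_1 - \\ln\\hat\\lambda_0` and the SE
from per-group Fisher information; log2FC = :math:`\\hat\\beta/\\ln 2`.

A separate per-cell GLM regresses raw counts of individual genes on
normalized hSNCA expression (log link, log library-size offset) within a
cell type, restricted to transgenic cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import AllZeroUnitError
from .expression import NormalizedMatrix
from .io import CountMatrix

MIN_DISPERSION = 1e-8

CONTRASTS = ("nontg_vs_psynPos", "nontg_vs_psynNeg", "psynPos_vs_psynNeg")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkMatrix:
    """Units x genes integer count sums with per-unit metadata.

    ``meta`` carries the grouping columns plus ``n_cells``; rows align with
    ``counts``.
    """

    meta: pd.DataFrame
    counts: np.ndarray  # units x genes, int64
    gene_ids: list[str]

    @property
    def n_units(self) -> int:
        return len(self.meta)

    def select_units(self, mask) -> "PseudobulkMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return PseudobulkMatrix(self.meta.iloc[idx].reset_index(drop=True),
                                self.counts[idx], list(self.gene_ids))


def aggregate_pseudobulk(counts: CountMatrix, cells: pd.DataFrame,
                         grouping=("cell_type", "sample_id", "psyn_group"),
                         min_cells: int = 10) -> PseudobulkMatrix:
    """Sum raw counts over cells within each grouping unit.

    ``cells`` is a per-cell frame aligned to ``counts.cell_ids`` (matched on
    the ``cell_id`` column) containing the grouping columns.  Units with
    fewer than ``min_cells`` member cells are dropped with a warning.
    Negative-probe genes are excluded.
    """
    grouping = list(grouping)
    cells = cells.set_index("cell_id").loc[counts.cell_ids].reset_index()
    keep_genes = np.flatnonzero(~counts.negative_probe_mask)
    gene_ids = [counts.gene_ids[i] for i in keep_genes]
    mat = counts.counts[:, keep_genes]
    metas, sums = [], []
    for key, grp in cells.groupby(grouping, sort=True, observed=True):
        idx = grp.index.to_numpy()
        if len(idx) < min_cells:
            warnings.warn(
                f"pseudo-bulk unit {key} dropped: {len(idx)} cells < min_cells={min_cells}")
            continue
        metas.append(dict(zip(grouping, key if isinstance(key, tuple) else (key,)),
                          n_cells=len(idx)))
        sums.append(np.asarray(mat[idx].sum(axis=0)).ravel())
    meta = pd.DataFrame(metas, columns=grouping + ["n_cells"])
    cmat = (np.vstack(sums).astype(np.int64) if sums
            else np.zeros((0, len(gene_ids)), dtype=np.int64))
    return PseudobulkMatrix(meta, cmat, gene_ids)


def size_factors(pb: PseudobulkMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Ratios are taken against the per-gene geometric mean over genes nonzero
    in every unit; when no such gene exists the factors fall back to library
    sizes.  Units with zero total counts are rejected.
    """
    y = pb.counts.astype(float)
    if y.shape[0] < 2:
        raise ValueError("size factors need >=2 units")
    totals = y.sum(axis=1)
    if np.any(totals == 0):
        raise AllZeroUnitError("pseudo-bulk unit with zero total counts")
    all_nonzero = np.all(y > 0, axis=0)
    if all_nonzero.any():
        logs = np.log(y[:, all_nonzero])
        log_geomean = logs.mean(axis=0)
        s = np.exp(np.median(logs - log_geomean, axis=1))
    else:
        s = totals
    s = s / np.exp(np.mean(np.log(s)))
    return s


# ---------------------------------------------------------------------------
# Two-group NB Wald test (vectorized across genes)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over units; Poisson limit at tiny alpha."""
    mu = np.maximum(mu, 1e-300)
    if alpha < 1e-7:
        ll = y * np.log(mu) - mu - scipy.special.gammaln(y + 1)
    else:
        r = 1.0 / alpha
        ll = (scipy.special.gammaln(y + r) - scipy.special.gammaln(r)
              - scipy.special.gammaln(y + 1)
              + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=0)


def _group_rate(y: np.ndarray, s: np.ndarray, alpha: float, n_iter: int = 25) -> np.ndarray:
    """MLE of the per-gene group rate lambda with offsets s and dispersion alpha.

    Solves the score equation by a damped fixed-point iteration started at
    the Poisson solution sum(y)/sum(s) (exact when alpha -> 0).
    """
    ysum = y.sum(axis=0)
    lam = ysum / s.sum()
    if alpha < 1e-7:
        return lam
    pos = lam > 0
    lam_p = lam[pos]
    yp = y[:, pos]
    for _ in range(n_iter):
        denom = (s[:, None] * (1.0 + alpha * yp) / (1.0 + alpha * lam_p[None, :] * s[:, None])
                 ).sum(axis=0)
        new = ysum[pos] / denom
        if np.allclose(new, lam_p, rtol=1e-10):
            lam_p = new
            break
        lam_p = new
    lam[pos] = lam_p
    return lam


_ALPHA_GRID = np.concatenate([[MIN_DISPERSION], np.geomspace(1e-4, 10.0, 28)])


def _profile_dispersion(y0, s0, y1, s1) -> np.ndarray:
    """Per-gene dispersion by Cox-Reid adjusted profile likelihood.

    The group rates are re-maximized at each candidate alpha on a log-spaced
    grid; the adjustment term -0.5 * ln det(X'WX) (here the product of the
    two per-group Fisher informations) counters the downward bias of the
    plain MLE at small unit counts.
    """
    n_genes = y0.shape[1]
    best_ll = np.full(n_genes, -np.inf)
    best_alpha = np.full(n_genes, MIN_DISPERSION)
    for alpha in _ALPHA_GRID:
        lam0 = _group_rate(y0, s0, alpha)
        lam1 = _group_rate(y1, s1, alpha)
        mu0 = lam0[None, :] * s0[:, None]
        mu1 = lam1[None, :] * s1[:, None]
        info0 = (mu0 / (1.0 + alpha * mu0)).sum(axis=0)
        info1 = (mu1 / (1.0 + alpha * mu1)).sum(axis=0)
        ll = (_nb_loglik(y0, mu0, alpha) + _nb_loglik(y1, mu1, alpha)
              - 0.5 * np.log(np.maximum(info0, 1e-300))
              - 0.5 * np.log(np.maximum(info1, 1e-300)))
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best_alpha = np.where(better, alpha, best_alpha)
    return best_alpha


def _moment_dispersion(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Method-of-moments fallback on size-factor-normalized counts."""
    norm = y / s[:, None]
    m = norm.mean(axis=0)
    v = norm.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (v - m) / m ** 2
    return np.clip(np.nan_to_num(alpha, nan=MIN_DISPERSION), MIN_DISPERSION, None)


@dataclass
class DEResult:
    """Per-gene Wald test results for one contrast."""

    table: pd.DataFrame
    contrast: str = ""
    cell_type: str = ""


def nb_wald_de(pb: PseudobulkMatrix, group_labels, reference: str, contrast: str,
               *, alpha_fdr: float = 0.05, contrast_name: str = "",
               cell_type: str = "") -> DEResult:
    """Negative-binomial Wald differential expression between two unit groups.

    ``group_labels`` assigns each pseudo-bulk unit to a group; units labelled
    ``reference`` form the baseline and units labelled ``contrast`` the
    comparison (log2FC > 0 means higher in ``contrast``).  Genes all-zero in
    one group are reported with a 0.5 pseudo-count log2FC and flagged as
    separated; their Wald p is NaN and they are excluded from BH.
    """
    labels = np.asarray(group_labels)
    i0, i1 = np.flatnonzero(labels == reference), np.flatnonzero(labels == contrast)
    if len(i0) < 2 or len(i1) < 2:
        raise ValueError(f"need >=2 units per group, got {len(i0)} vs {len(i1)}")
    s = size_factors(pb.select_units(np.concatenate([i0, i1])))
    s0, s1 = s[:len(i0)], s[len(i0):]
    y0 = pb.counts[i0].astype(float)
    y1 = pb.counts[i1].astype(float)

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        alpha = _profile_dispersion(y0, s0, y1, s1)
        bad = ~np.isfinite(alpha)
        if bad.any():
            alpha[bad] = _moment_dispersion(np.vstack([y0, y1]),
                                            np.concatenate([s0, s1]))[bad]
        n_genes = y0.shape[1]
        lam0 = np.empty(n_genes)
        lam1 = np.empty(n_genes)
        info0 = np.empty(n_genes)
        info1 = np.empty(n_genes)
        for a in np.unique(alpha):
            sel = alpha == a
            l0 = _group_rate(y0[:, sel], s0, a)
            l1 = _group_rate(y1[:, sel], s1, a)
            lam0[sel], lam1[sel] = l0, l1
            mu0 = l0[None, :] * s0[:, None]
            mu1 = l1[None, :] * s1[:, None]
            info0[sel] = (mu0 / (1.0 + a * mu0)).sum(axis=0)
            info1[sel] = (mu1 / (1.0 + a * mu1)).sum(axis=0)

        separated = (lam0 == 0) | (lam1 == 0)
        beta = np.where(separated, np.nan, np.log(np.maximum(lam1, 1e-300))
                        - np.log(np.maximum(lam0, 1e-300)))
        se = np.where(separated, np.nan, np.sqrt(1.0 / np.maximum(info0, 1e-300)
                                                 + 1.0 / np.maximum(info1, 1e-300)))
        wald = beta / se
        # small-sample reference: t with residual df rather than normal,
        # since the dispersion is estimated from very few units
        df_resid = len(i0) + len(i1) - 2
        p = 2.0 * scipy.stats.t.sf(np.abs(wald), df_resid)
        # pseudo-count log2FC for separated genes (reporting only)
        m0 = y0.mean(axis=0) / s0.mean()
        m1 = y1.mean(axis=0) / s1.mean()
        log2fc = np.where(separated,
                          np.log2((m1 + 0.5) / (m0 + 0.5)),
                          beta / np.log(2.0))

    table = pd.DataFrame({
        "gene": pb.gene_ids,
        "log2FC": log2fc,
        "SE": se / np.log(2.0),
        "wald_stat": wald,
        "p_raw": p,
        "dispersion": alpha,
        "separated": separated,
    }).set_index("gene")
    table["fdr"] = np.nan
    testable = ~table["p_raw"].isna()
    if testable.any():
        table.loc[testable, "fdr"] = multipletests(table.loc[testable, "p_raw"],
                                                   method="fdr_bh")[1]
    table["significant"] = table["fdr"] < alpha_fdr
    return DEResult(table, contrast=contrast_name or f"{reference}_vs_{contrast}",
                    cell_type=cell_type)


# ---------------------------------------------------------------------------
# Percentile-matched subsetting and consensus
# ---------------------------------------------------------------------------

def percentile_matched_subset(cell_ids, psyn_status, hsnca_norm,
                              hi_pct: float = 75.0, lo_pct: float = 25.0):
    """Decouple pathology status from driver-gene expression by subsetting.

    Over the supplied cells of one type (tg only), computes the hSNCA
    expression percentiles (linear interpolation) and returns
    ``(neg_high_ids, pos_low_ids)``: pSyn- cells strictly above the
    ``hi_pct`` percentile and pSyn+ cells strictly below the ``lo_pct``
    percentile.  Either set may be empty.
    """
    status = np.asarray(psyn_status)
    x = np.asarray(hsnca_norm, dtype=float)
    ids = np.asarray(cell_ids)
    hi = np.percentile(x, hi_pct)
    lo = np.percentile(x, lo_pct)
    neg_high = ids[(status == "negative") & (x > hi)]
    pos_low = ids[(status == "positive") & (x < lo)]
    return list(neg_high), list(pos_low)


def consensus_degs(results: list[DEResult], min_types: int = 2,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Genes significant in the same direction in >= ``min_types`` cell types.

    Takes one DEResult per cell type (same contrast); a gene significant
    upward in one type and downward in another is excluded.
    """
    if len(results) < 2:
        raise ValueError("consensus needs results from >=2 cell types")
    rows = []
    genes = results[0].table.index
    for g in genes:
        up, down = [], []
        for res in results:
            if g not in res.table.index:
                continue
            rec = res.table.loc[g]
            if rec["fdr"] < alpha and not rec["separated"]:
                (up if rec["log2FC"] > 0 else down).append(res.cell_type)
        if len(up) >= min_types and not down:
            rows.append({"gene": g, "direction": "up", "n_types": len(up),
                         "cell_types": ";".join(up)})
        elif len(down) >= min_types and not up:
            rows.append({"gene": g, "direction": "down", "n_types": len(down),
                         "cell_types": ";".join(down)})
    return pd.DataFrame(rows, columns=["gene", "direction", "n_types", "cell_types"])


# ---------------------------------------------------------------------------
# Per-cell GLM of gene expression against hSNCA
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Per-gene slopes of GEx ~ hSNCA within one cell type."""

    table: pd.DataFrame
    cell_type: str = ""


def sc_glm_vs_hsnca(counts: CountMatrix, norm: NormalizedMatrix, cell_mask,
                    genes, *, cell_type: str = "", alpha_fdr: float = 0.05,
                    hsnca_gene: str = "hSNCA", family: str = "nb") -> GLMResult:
    """Regress single-cell raw counts of each gene on normalized hSNCA.

    Log-link GLM with a log library-size offset over the cells selected by
    ``cell_mask`` (intended: tg cells of one type; >=20 required).  Family
    ``"nb"`` estimates a per-gene dispersion from a Poisson fit and refits a
    negative-binomial GLM; on failure (or ``family="quasipoisson"``) a
    quasi-Poisson fit with Pearson-scaled standard errors is used and the
    gene is flagged.  BH q-values are computed across the tested genes.
    """
    idx = np.flatnonzero(np.asarray(cell_mask))
    if len(idx) < 20:
        raise ValueError(f"need >=20 cells for the per-cell GLM, got {len(idx)}")
    x = norm.gene(hsnca_gene)[idx]
    offset = np.log(norm.library_size[idx])
    X = sm.add_constant(x)
    rows = []
    for g in genes:
        y = np.asarray(counts.counts[idx, counts.gene_index(g)].todense()).ravel().astype(float)
        if y.sum() == 0:
            rows.append({"gene": g, "slope": np.nan, "se": np.nan, "p_raw": np.nan,
                         "family": "none", "converged": False})
            continue
        slope = se = p = np.nan
        used = "nb"
        converged = False
        try:
            if family == "nb":
                pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                mu = pois.fittedvalues
                a_hat = _mle_alpha_given_mu(y, mu)
                fam = (sm.families.NegativeBinomial(alpha=a_hat)
                       if a_hat > MIN_DISPERSION * 10 else sm.families.Poisson())
                fit = sm.GLM(y, X, family=fam, offset=offset).fit()
                slope, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
                converged = bool(fit.converged)
            if family == "quasipoisson" or not converged:
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(scale="X2")
                slope, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
                converged = bool(fit.converged)
                used = "quasipoisson"
        except Exception:
            used = "failed"
        rows.append({"gene": g, "slope": slope, "se": se, "p_raw": p,
                     "family": used, "converged": converged})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = np.nan
    ok = ~table["p_raw"].isna()
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p_raw"], method="fdr_bh")[1]
    table["significant"] = table["q"] < alpha_fdr
    return GLMResult(table, cell_type=cell_type)


def _mle_alpha_given_mu(y: np.ndarray, mu: np.ndarray) -> float:
    """Scalar NB dispersion MLE holding the fitted means fixed."""
    def nll(log_alpha):
        return -_nb_loglik(y[:, None], mu[:, None], float(np.exp(log_alpha)))[0]
    opt = scipy.optimize.minimize_scalar(
        nll, bounds=(np.log(1e-8), np.log(50.0)), method="bounded",
        options={"xatol": 1e-3})
    if not opt.success:
        v = y.var(ddof=1)
        m = y.mean()
        return float(max((v - m) / m ** 2, MIN_DISPERSION)) if m > 0 else MIN_DISPERSION
    return float(np.exp(opt.x))
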