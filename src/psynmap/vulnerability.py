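"""Cell-type vulnerability to pSyn pathology and its relation to expression.

Vulnerability of a cell type in a sample is the percentage of its cells
carrying at least one pSyn inclusion.  Types are compared by one-way ANOVA
on per-sample percentages with Tukey HSD, and vulnerability is screened
against per-type mean gene expression by simple linear regression with
Benjamini-Hochberg correction across genes.  Percentage-on-expression and
expression-on-percentage parameterizations give identical r2 and slope
p-values in simple OLS; the package standardizes on percent pSyn+ as the
response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicatesError
from .io import CellRecord, UNASSIGNED, cells_to_frame


def vulnerability_table(cells: list[CellRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per (sample_id, cell_type) pathology counts and percentage.

    Requires every cell to have a called psyn_status; unassigned cells are
    excluded.  Sample x type combinations with no cells are omitted rather
    than reported as 0%.
    """
    df = cells_to_frame(cells) if not isinstance(cells, pd.DataFrame) else cells.copy()
    if (df["psyn_status"] == "unknown").any():
        raise ValueError("all cells must have a called psyn_status")
    df = df[df["cell_type"] != UNASSIGNED]
    grouped = df.groupby(["sample_id", "cell_type"], sort=True, observed=True)
    out = grouped.agg(
        n_cells=("cell_id", "size"),
        n_psyn_pos=("psyn_status", lambda s: int((s == "positive").sum())),
    ).reset_index()
    out["pct_psyn"] = 100.0 * out["n_psyn_pos"] / out["n_cells"]
    return out


def compare_vulnerability(table: pd.DataFrame, alpha: float = 0.05):
    """One-way ANOVA across cell types on per-sample percentages, plus Tukey HSD.

    Returns ``(F, p, tukey_frame)`` where the Tukey frame has one row per
    type pair with the adjusted p-value.  Requires >=2 types with >=2
    sample-level replicates each.
    """
    groups = {t: g["pct_psyn"].to_numpy(dtype=float)
              for t, g in table.groupby("cell_type", observed=True)}
    usable = {t: v for t, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise InsufficientReplicatesError(
            "need >=2 cell types with >=2 per-sample replicates each")
    values = list(usable.values())
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        f_stat, p = 0.0, 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat, p = scipy.stats.f_oneway(*values)
        if np.isnan(f_stat):  # zero within-group variance with distinct means
            f_stat, p = np.inf, 0.0
    labels = np.concatenate([[t] * len(v) for t, v in usable.items()])
    data = np.concatenate(values)
    tukey = pairwise_tukeyhsd(data, labels, alpha=alpha)
    tukey_frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return float(f_stat), float(p), tukey_frame


def vulnerability_expression_regression(pct_by_type: pd.Series,
                                        expression_by_type: pd.DataFrame,
                                        genes=None, alpha: float = 0.05) -> pd.DataFrame:
    """Screen genes whose per-type expression tracks per-type vulnerability.

    ``pct_by_type``: mean percent pSyn+ per cell type (tg samples).
    ``expression_by_type``: type x gene mean expression, typically from the
    genotype of interest (non-tg for vulnerability screening, tg for the
    transgene itself).  Per gene, OLS of pct on expression across types;
    BH correction across the non-degenerate genes.
    """
    types = [t for t in pct_by_type.index if t in expression_by_type.index]
    if len(types) < 3:
        raise ValueError("need >=3 cell types shared between pct and expression tables")
    y = pct_by_type.loc[types].to_numpy(dtype=float)
    gene_list = list(expression_by_type.columns) if genes is None else list(genes)
    rows = []
    for g in gene_list:
        x = expression_by_type.loc[types, g].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"gene": g, "slope": np.nan, "intercept": np.nan, "r2": np.nan,
                         "p_raw": np.nan, "degenerate": True})
            continue
        res = scipy.stats.linregress(x, y)
        rows.append({"gene": g, "slope": res.slope, "intercept": res.intercept,
                     "r2": res.rvalue ** 2, "p_raw": res.pvalue, "degenerate": False})
    out = pd.DataFrame(rows).set_index("gene")
    out["fdr"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < alpha
    return out


def stratify_by_sex(cells: list[CellRecord] | pd.DataFrame):
    """Split cells by sex for independent downstream tabulation.

    Returns ``{"M": frame, "F": frame}``; a missing sex yields an empty frame
    with the same columns.
    """
    df = cells_to_frame(cells) if not isinstance(cells, pd.DataFrame) else cells
    return {sex: df[df["sex"] == sex].reset_index(drop=True) for sex in ("M", "F")}
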