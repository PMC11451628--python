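"""End-to-end orchestration: simulate -> QC -> annotate -> register ->
call pathology -> vulnerability -> DE/GLM, with a machine-readable run report.

Every stage is a pure function of its inputs; the report records the seed,
all resolved parameters and per-stage counts so a run can be audited and
reproduced exactly.  Stage failures propagate wrapped in
:class:`PipelineStageError` with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import expression as expr_mod
from . import pathology as path_mod
from . import synth as synth_mod
from . import vulnerability as vuln_mod
from .errors import PipelineStageError
from .io import UNASSIGNED, cells_to_frame, qc_and_filter


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (all defaults documented)."""

    outdir: str = "psynmap_run"
    seed: int = 0
    # pathology calling
    threshold_frac: float = 0.25   # IF threshold as fraction of dtype max
    min_area_px: int = 4
    connectivity: int = 8
    # expression
    scale_factor: float = 1e4
    min_r: float = 0.1
    # DE / GLM
    hi_pct: float = 75.0
    lo_pct: float = 25.0
    min_cells: int = 10
    fdr_alpha: float = 0.05
    excitatory_only_de: bool = True  # restrict DE/GLM to excitatory neuron types
    # generator overrides (field name -> value), applied over GenerativeParams defaults
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def make_params(self) -> synth_mod.GenerativeParams:
        return synth_mod.GenerativeParams(seed=self.seed, **self.sim)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run the full analysis on a fresh synthetic study; returns the report.

    With ``write_outputs`` the simulated inputs, intermediate tables and the
    JSON report are written under ``config.outdir``; stages never mutate an
    upstream artifact on disk.
    """
    outdir = Path(config.outdir)
    report: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()},
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    params = config.make_params()
    study = _stage("simulate")(synth_mod.generate_study)(params)
    if write_outputs:
        synth_mod.write_study(study, outdir / "sim")
    report["stages"]["simulate"] = {
        "n_cells": len(study.cells),
        "n_genes": study.counts.n_genes,
        "n_samples": int(len(study.sample_table)),
        "true_psyn_positive": int(study.truth.cells.true_psyn.sum()),
    }

    # --- qc -----------------------------------------------------------------
    qc, counts = _stage("qc")(qc_and_filter)(study.counts)
    kept = set(counts.cell_ids)
    cells = [c for c in study.cells if c.cell_id in kept]
    report["stages"]["qc"] = {
        "cells_in": int(len(qc)),
        "cells_out": counts.n_cells,
        "median_negative_probe_rate": float(qc.negative_probe_rate.median()),
    }

    # --- normalize + annotate ----------------------------------------------
    norm = _stage("normalize")(expr_mod.lognormalize)(counts, config.scale_factor)
    reference = synth_mod.reference_profiles_from_params(params, config.scale_factor)
    labels = _stage("annotate")(expr_mod.assign_cell_types)(norm, reference, config.min_r)
    for c, lab in zip(cells, labels):
        c.cell_type = str(lab)
    truth_type = study.truth.cells.set_index("cell_id").true_type
    agree = np.mean([c.cell_type == truth_type[c.cell_id] for c in cells])
    report["stages"]["annotate"] = {
        "n_unassigned": int(np.sum(labels == UNASSIGNED)),
        "agreement_with_truth": round(float(agree), 6),
    }

    # --- register + call pathology ------------------------------------------
    @_stage("callpath")
    def _call_all():
        by_sample: dict[str, list] = {}
        for c in cells:
            by_sample.setdefault(c.sample_id, []).append(c)
        called_all, n_incl, n_orphan = [], 0, 0
        for sample_id, sample_cells in by_sample.items():
            img, aff = study.images[sample_id]
            called, incl, assignment = path_mod.call_pathology(
                sample_cells, img, aff,
                threshold_frac=config.threshold_frac,
                min_area=config.min_area_px, connectivity=config.connectivity)
            called_all.extend(called)
            n_incl += len(incl)
            n_orphan += int((assignment["cell_id"] == "orphan").sum())
        return called_all, n_incl, n_orphan

    cells, n_inclusions, n_orphans = _call_all()
    cells_df = cells_to_frame(cells)
    id_to_idx = {cid: i for i, cid in enumerate(counts.cell_ids)}
    truth_psyn = study.truth.cells.set_index("cell_id").true_psyn
    called_pos = cells_df.psyn_status == "positive"
    acc = float(np.mean(called_pos.to_numpy()
                        == truth_psyn.loc[cells_df.cell_id].to_numpy()))
    report["stages"]["callpath"] = {
        "n_inclusions": n_inclusions,
        "n_orphans": n_orphans,
        "n_psyn_positive": int(called_pos.sum()),
        "accuracy_vs_truth": round(acc, 6),
    }

    # --- vulnerability -------------------------------------------------------
    @_stage("vulnerability")
    def _vuln():
        tg = cells_df[cells_df.genotype == "tg"]
        table = vuln_mod.vulnerability_table(tg)
        f_stat, p_anova, tukey = vuln_mod.compare_vulnerability(table, config.fdr_alpha)
        pct_by_type = table.groupby("cell_type", observed=True).pct_psyn.mean()
        nontg_mask = np.array([g == "non_tg" for g in
                               (cells_df.set_index("cell_id").loc[counts.cell_ids].genotype)])
        assigned = cells_df.set_index("cell_id").loc[counts.cell_ids].cell_type.to_numpy()
        use = nontg_mask & (assigned != UNASSIGNED)
        avg_nontg = expr_mod.average_expression(
            expr_mod.NormalizedMatrix(
                [cid for cid, u in zip(counts.cell_ids, use) if u],
                norm.gene_ids, norm.values[use], norm.scale_factor,
                norm.library_size[use]),
            assigned[use])
        screen = vuln_mod.vulnerability_expression_regression(
            pct_by_type, avg_nontg, alpha=config.fdr_alpha)
        return table, f_stat, p_anova, tukey, pct_by_type, screen

    vuln_table, f_stat, p_anova, tukey, pct_by_type, screen = _vuln()
    report["stages"]["vulnerability"] = {
        "anova_F": round(float(f_stat), 6),
        "anova_p": float(p_anova),
        "pct_psyn_by_type": {t: round(float(v), 4) for t, v in
                             pct_by_type.sort_values(ascending=False).items()},
        "screen_significant_genes": sorted(screen.index[screen.significant].tolist()),
    }

    # --- pseudo-bulk DE ------------------------------------------------------
    @_stage("de")
    def _de():
        merged = cells_df.copy()
        merged["psyn_group"] = np.where(
            merged.genotype == "non_tg", "nontg",
            np.where(merged.psyn_status == "positive", "psynPos", "psynNeg"))
        de_types = [t for t in pd.unique(merged.cell_type)
                    if t != UNASSIGNED and not (config.excitatory_only_de and t == "InN")]
        contrasts = {
            "nontg_vs_psynPos": ("nontg", "psynPos"),
            "nontg_vs_psynNeg": ("nontg", "psynNeg"),
            "psynPos_vs_psynNeg": ("psynNeg", "psynPos"),
        }
        results: dict[str, list] = {k: [] for k in contrasts}
        for t in sorted(de_types):
            sub = merged[merged.cell_type == t]
            pb = de_mod.aggregate_pseudobulk(
                counts.subset_cells([id_to_idx[c] for c in sub.cell_id]),
                sub, grouping=("sample_id", "psyn_group"), min_cells=config.min_cells)
            for name, (ref, con) in contrasts.items():
                grp = pb.meta.psyn_group.to_numpy()
                if (grp == ref).sum() < 2 or (grp == con).sum() < 2:
                    continue
                res = de_mod.nb_wald_de(pb, grp, ref, con, alpha_fdr=config.fdr_alpha,
                                        contrast_name=name, cell_type=t)
                results[name].append(res)
        consensus = {}
        for name, lst in results.items():
            if len(lst) >= 2:
                consensus[name] = de_mod.consensus_degs(lst, alpha=config.fdr_alpha)
        return results, consensus, sorted(de_types)

    de_results, consensus, de_types = _de()
    report["stages"]["de"] = {
        name: {
            "n_celltypes_tested": len(lst),
            "n_significant": int(sum(r.table.significant.sum() for r in lst)),
            "consensus_genes": consensus.get(name, pd.DataFrame()).to_dict("records")
            if name in consensus else [],
        }
        for name, lst in de_results.items()
    }

    # --- matched-percentile DE ----------------------------------------------
    @_stage("matched_percentile")
    def _matched():
        merged = cells_df.set_index("cell_id")
        out = {}
        for t in de_types:
            sub = merged[(merged.cell_type == t) & (merged.genotype == "tg")]
            if len(sub) < 4 * config.min_cells:
                continue
            hs = pd.Series(norm.gene(synth_mod.HSNCA), index=counts.cell_ids)
            neg_high, pos_low = de_mod.percentile_matched_subset(
                sub.index.to_numpy(), sub.psyn_status.to_numpy(),
                hs.loc[sub.index].to_numpy(), config.hi_pct, config.lo_pct)
            chosen = list(neg_high) + list(pos_low)
            if not neg_high or not pos_low:
                continue
            sel = merged.loc[chosen].reset_index()
            sel["psyn_group"] = np.where(sel.psyn_status == "positive",
                                         "psynPos_low", "psynNeg_high")
            pb = de_mod.aggregate_pseudobulk(
                counts.subset_cells([id_to_idx[c] for c in sel.cell_id]),
                sel, grouping=("sample_id", "psyn_group"),
                min_cells=max(2, config.min_cells // 2))
            grp = pb.meta.psyn_group.to_numpy()
            if (grp == "psynNeg_high").sum() < 2 or (grp == "psynPos_low").sum() < 2:
                continue
            out[t] = de_mod.nb_wald_de(pb, grp, "psynNeg_high", "psynPos_low",
                                       alpha_fdr=config.fdr_alpha,
                                       contrast_name="matched_percentile", cell_type=t)
        return out

    matched = _matched()
    report["stages"]["matched_percentile"] = {
        t: {
            "hSNCA_log2FC": round(float(r.table.loc[synth_mod.HSNCA, "log2FC"]), 4),
            "hSNCA_fdr": float(r.table.loc[synth_mod.HSNCA, "fdr"]),
            "n_significant": int(r.table.significant.sum()),
        }
        for t, r in matched.items()
    }

    # --- per-cell GLM --------------------------------------------------------
    @_stage("glm")
    def _glm():
        merged = cells_df.set_index("cell_id").loc[counts.cell_ids]
        out = {}
        for t in de_types:
            degs = sorted(set().union(*[
                set(r.table.index[r.table.significant])
                for lst in de_results.values() for r in lst if r.cell_type == t
            ])) if any(r.cell_type == t for lst in de_results.values() for r in lst) else []
            degs = [g for g in degs if g != synth_mod.HSNCA]
            if not degs:
                continue
            mask = ((merged.cell_type == t) & (merged.genotype == "tg")).to_numpy()
            if mask.sum() < 20:
                continue
            out[t] = de_mod.sc_glm_vs_hsnca(counts, norm, mask, degs,
                                            cell_type=t, alpha_fdr=config.fdr_alpha)
        return out

    glm_results = _glm()
    report["stages"]["glm"] = {
        t: {"n_genes_tested": int(len(r.table)),
            "n_significant": int(r.table.significant.sum())}
        for t, r in glm_results.items()
    }

    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        vuln_table.to_csv(outdir / "vulnerability.csv", index=False)
        tukey.to_csv(outdir / "tukey.csv", index=False)
        screen.to_csv(outdir / "vulnerability_screen.csv")
        for name, lst in de_results.items():
            for r in lst:
                safe = r.cell_type.replace("/", "").replace(" ", "_")
                r.table.to_csv(outdir / f"de_{name}_{safe}.csv")
        for t, r in matched.items():
            safe = t.replace("/", "").replace(" ", "_")
            r.table.to_csv(outdir / f"de_matched_{safe}.csv")
        for t, r in glm_results.items():
            safe = t.replace("/", "").replace(" ", "_")
            r.table.to_csv(outdir / f"glm_{safe}.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        with open(outdir / "resolved_config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True,
                      default=str)
    return report
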