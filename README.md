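# psynmap

Pathology-aware analysis of imaging spatial transcriptomics (IST).

In synucleinopathy mouse models, phosphorylated α-synuclein (pSyn, Ser129)
pathology forms in some cortical neurons but not others. `psynmap` implements
the analysis that connects a pathology immunofluorescence (IF) channel to
segmented, in-situ single-cell expression data and asks *which cell types are
vulnerable and why*:

1. **Co-registration** — an affine matrix maps the IF image (pixels) onto the
   tissue coordinates (µm) of the segmented cells.
2. **Per-cell pathology calling** — the pSyn channel is thresholded, connected
   components become inclusions, and a cell is pSyn⁺ iff an inclusion centroid
   falls inside its polygon (boundary-inclusive even-odd test; ties go to the
   lexicographically smallest cell id).
3. **Cell typing** — library-size log-normalization
   `x_ij = ln(1 + c_ij·SF/L_i)`, then per-cell Pearson correlation against
   z-scored reference expression profiles.
4. **Vulnerability statistics** — per sample × type, % pSyn⁺ cells; one-way
   ANOVA with Tukey HSD across types; per-gene OLS screen
   `% pSyn⁺ ~ mean expression` across types with Benjamini–Hochberg (BH)
   correction.
5. **Pseudo-bulk differential expression** — counts summed over
   (type, sample, pSyn group) units, median-of-ratios size factors, and a
   per-gene negative-binomial Wald test
   `y_ug ~ NB(s_u·λ_{c(u),g}, α_g)` with Cox–Reid-adjusted gene-wise
   dispersion, run for the three contrasts non-tg vs pSyn⁺, non-tg vs pSyn⁻,
   and pSyn⁺ vs pSyn⁻, plus a ≥2-type same-direction consensus rule and a
   percentile-matched design (pSyn⁻/hSNCA-high vs pSyn⁺/hSNCA-low) that
   decouples pathology from driver-gene expression.
6. **Per-cell GLM** — `GEx ~ hSNCA`: NB log-link regression of a gene's raw
   counts on normalized hSNCA with a log library-size offset, in transgenic
   cells of one type, BH-corrected per type.

Because the original animal dataset is not required, the package ships a
first-class **synthetic study generator**: layer-banded cortical cell types
with marker genes, nuclear-expansion-style segmentation (dart-thrown nuclei,
Voronoi-clipped 8 µm disks — polygons never overlap), NB counts with per-cell
library factors, a human-SNCA transgene with genotype and sex effects,
negative control probes, a logistic pathology model
`P(pSyn⁺) = σ(β₀(type) + β_hSNCA·x_hSNCA + β_Plk2·x_Plk2)` on realized
expression, and a rendered pathology image offset by a known affine — all with
ground truth, so every stage of the pipeline can be scored against what was
simulated.

## Worked example

```bash
psynmap run-all --seed 1 --outdir run1
```

runs simulate → QC → annotate → register → call pathology → vulnerability →
DE/GLM and prints the stage report. On the default study (8 samples, 12,520
cells, 58-gene panel) it prints, among other entries:

```
"annotate":  { "agreement_with_truth": 0.973163, "n_unassigned": 12 }
"callpath":  { "n_inclusions": 1274, "n_orphans": 0, "accuracy_vs_truth": 1.0 }
"vulnerability": {
  "anova_F": 146.875256,
  "pct_psyn_by_type": { "L5 ET": 47.6959, "L4/5 IT": 35.0759, "L2/3 IT": 21.2632,
                        "L5 NP": 16.2061, "L6 CT": 7.097, "InN": 1.334 },
  "screen_significant_genes": [ "Plk2", ... ] }
"matched_percentile": { "L2/3 IT": { "hSNCA_log2FC": -1.8274, ... } }
```

Reading this: cell typing recovered 97% of true identities; every rendered
inclusion was assigned to the correct cell; the recovered vulnerability
ranking follows the generator's programmed Plk2 gradient (L5 ET most
vulnerable, interneurons nearly spared, as in the tissue this emulates); the
expression screen flags *Plk2* as tracking vulnerability across types; and in
the percentile-matched contrast the pSyn⁺/hSNCA-low cells show, by
construction, significantly lower *hSNCA* than their pSyn⁻/hSNCA-high
comparators. Per-type DE tables, the consensus DEG list, GLM results and a
`report.json` with every parameter and seed are written under `run1/`.

The same stages are available piecewise (`psynmap simulate`, `qc`, `annotate`,
`register`, `callpath`, `vuln`, `de`, `glm`) over the plain-text interchange
formats: cells CSV with WKT polygons, MatrixMarket counts with TSV sidecars,
3×3 affine text files, and single-channel TIFF.

## Layout

```
src/psynmap/
  io.py            cell tables, counts (MTX), affine files, images, QC
  registration.py  tagged 2-D affine transforms (apply / invert / compose)
  pathology.py     thresholding, inclusions, point-in-polygon, assignment
  expression.py    log-normalization, scaling, typing, depth profiles
  vulnerability.py vulnerability tables, ANOVA/Tukey, expression screen
  de.py            pseudo-bulk NB Wald DE, consensus, percentile matching, GLM
  synth.py         synthetic study generator + ground truth
  pipeline.py      run_pipeline / RunConfig
  cli.py           `psynmap` command-line interface
docs/methods.md    model and design notes
```
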