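# Methods

## Coordinate model and registration

Tissue space is micrometres with the imaging convention (origin top-left, y
down); image space is pixels in the same orientation. An
`AffineTransform2D` is a 3×3 homogeneous matrix acting on µm coordinates,
tagged with source and target spaces; when an endpoint is `image_px` the
pixel pitch (`pixel_size_um`) converts on the way in or out. Inclusion
*centroids* are transformed from image into tissue space rather than
resampling the image: for point-in-polygon containment the two are
mathematically equivalent, and transforming points avoids interpolation
artifacts. Matrix files are 3×3 plain text; an optional header line
(`# source=image_px target=tissue_um pixel_size_um=1.0`) pins the direction
of the exported matrix, since alignment tools do not always state it.

## Pathology calling

The pSyn channel is thresholded strictly (`> t`, one `t` across samples; the
default is 0.25 of the dtype maximum and is a free parameter — the absolute
IF threshold depends on staining and acquisition and is not knowable a
priori). Connected components (default 8-connectivity, minimum area 4 px —
both configurable, both unknowable a priori) become inclusions whose
centroid is the unweighted mean of member pixel centers, i.e. the geometry of
the binary object, not intensity-weighted. Containment is the even-odd
(ray-casting) rule with boundary points counted inside; a centroid on a
shared boundary is assigned to the cell with the lexicographically smallest
id, so each inclusion contributes to at most one cell and results are
reproducible regardless of cell ordering. Note one subtlety: raising the
threshold cannot create positives for spatially separated inclusions, but
when two objects merge at a low threshold their single centroid can land in
fewer cells than the two separate centroids would — the monotonicity
property is therefore guaranteed only for separated objects.

## Expression model

Normalization is `x_ij = ln(1 + c_ij · SF / L_i)` with `L_i` the total count
of cell *i* over non-negative-probe genes; negative control probes are
excluded from both the library and the normalized gene set, and from all
downstream testing. `SF` defaults to 1e4 for the spatial data and 1e6 when
mimicking reference-atlas processing. "Scaling" is a per-gene z-score
(n−1 denominator, unclipped), optionally after regressing out a per-cell
covariate (total post-filter reads) by OLS. Group averages are reported as
`mean(expm1(x))`, the convention for per-type expression summaries.

Cell typing correlates each cell's gene-scaled vector with z-scored
reference profiles (Pearson, argmax, unassigned below `min_r`). Genes whose
scaled reference profile is identically zero (constant across types) carry
no type information and are dropped before correlating. `min_r` defaults to
0.1: on a compact (~60-gene) panel the correct-match correlation
concentrates well above this while mismatches sit near zero; a stricter 0.2
rejects a meaningful fraction of shallow cells without improving accuracy.
Reference-profile similarity between two datasets and the per-gene
cross-modality regression both operate on the shared gene set of two
type × gene scaled matrices.

## Vulnerability statistics

Vulnerability is `100 · n_pSyn+ / n_cells` per (sample, type); empty
combinations are omitted rather than reported as 0%. Types are compared by
one-way ANOVA on per-sample percentages (each sample is the replicate, as in
per-animal designs) with Tukey HSD. The expression screen regresses per-type
mean vulnerability on per-type mean expression (OLS per gene, BH across
non-degenerate genes). The two phrasings `GEx ~ %pSyn+` and `%pSyn+ ~ GEx`
have identical r² and slope p-value in simple OLS; the package standardizes
on percent as the response. The default operates on per-type means pooled
across samples; a per-sample-point variant can be had by passing per-sample
rows.

## Pseudo-bulk differential expression

Counts are summed exactly over (cell type, sample, pSyn group) units; units
under `min_cells` (default 10) are dropped with a warning. Size factors are
DESeq-style median-of-ratios over genes nonzero in every unit (library-size
fallback), rescaled to geometric mean 1. Each gene is tested between two
unit groups under `y_ug ~ NB(s_u λ_g, α_g)` with a log link:

* group rates by fixed-point solution of the score equation (exact Poisson
  solution as the α→0 limit);
* gene-wise dispersion by **Cox–Reid adjusted** profile likelihood on a
  log-spaced grid (floor 1e-8), with a method-of-moments fallback. The CR
  adjustment (−½ ln of the product of per-group Fisher informations)
  counters the strong downward bias of the plain MLE at 4-vs-4 units;
  no empirical-Bayes shrinkage across genes is applied;
* Wald statistic `β̂/SE` with `SE² = 1/I₀ + 1/I₁` referred to a
  **t(n_units − 2)** distribution — the small-sample reference matters: with
  a normal reference the 4-vs-4 null tail is inflated several-fold;
* `log2FC = β̂/ln 2`; genes all-zero in one group are reported with a
  0.5-pseudo-count fold change, flagged `separated`, p = NaN, and excluded
  from BH;
* BH across testable genes per contrast per cell type; consensus keeps genes
  significant in the same direction in ≥2 types.

Two structural facts found while validating: (1) the per-group Fisher
information is bounded by `n_units/α`, so at dispersion 0.1 and 4v4 units no
sequencing depth yields 80% power for a 2-fold change — power targets are
only meaningful at pseudo-bulk-realistic dispersions (α ≈ 0.01–0.05 for
aggregates of ≥100 cells), which is what the recovery simulations use while
null calibration is checked at α = 0.1; (2) simulating a fold change on all
genes of a unit is absorbed by the size factors (compositional), so recovery
simulations perturb a balanced 10% subset of genes.

Percentile-matched subsetting takes, within the tg cells of one type, pSyn⁻
cells strictly above the 75th percentile of normalized hSNCA and pSyn⁺ cells
strictly below the 25th (linear-interpolation percentiles; ties fall
outside). The design formula deliberately contains only the group factor
(no sample covariate), matching per-unit aggregation; treating units from
the same animal as independent is a pseudo-replication caveat inherited from
the design.

## Per-cell GLM (GEx ~ hSNCA)

Within the tg cells of one type (≥20 cells), each candidate gene's raw
counts are regressed on normalized hSNCA with a log link and log
library-size offset: a Poisson fit supplies fitted means, a scalar NB
dispersion is maximized given those means, and the NB GLM is refit; on
non-convergence a quasi-Poisson fit (Pearson-scaled SEs) is used and
flagged. Candidate genes are restricted to pseudo-bulk DEGs. BH q-values are
computed per type. One known limitation of the total-count normalization
convention: the tested gene's own counts sit inside the library that
normalizes both the offset and the hSNCA regressor, which induces a small
negative compositional coupling (order gene-share of the library, <1% here).
The coverage simulations therefore define the generative truth on a
normalization excluding the tested genes, which the two-argument API
(`counts` vs `norm`) supports directly.

## Synthetic study

The generator is the package's study design, not a fixture. Defaults:

* 4 samples per genotype (tg / non-tg), half male; one tissue block of
  800 × 1200 µm per sample.
* Six cortical types in depth bands (L2/3 IT, L4/5 IT, L5 ET, L5 NP, L6 CT
  at laminar positions; InN spread across depth) at 300–1400 cells/mm²,
  ~1565 cells per sample. Nuclei are dart-thrown with 8 µm minimum spacing
  (nucleus radius 3 µm); polygons are the nucleus disk dilated 5 µm and
  clipped to the nucleus' Voronoi cell, emulating nuclear-expansion
  segmentation — polygons are pairwise disjoint by construction.
* Panel of 58 genes: 3 markers per type (mean 6 in-type vs 0.3 out),
  mSnca, a Plk2 gradient across types (8 → 0.1 mean counts), 20 DE-target
  genes, 12 housekeeping genes, hSNCA, and 5 negative probes (mean 0.05).
* Counts are gamma-Poisson: `c_ij ~ NB(µ_{type,j}·L_i, α)` with α = 0.1 and
  `L_i ~ lognormal(0, 0.25)`. hSNCA is drawn only in tg cells (configurable
  leak, default 0 — the probe sets do not cross-react), ×1.3 in males
  (an expression effect only; the male pathology offset defaults to 0, as
  higher male expression was not observed to translate into higher pathology
  rates).
* Pathology: `P(pSyn⁺) = σ(−8.3 + 0.4·x_hSNCA + 0.9·x_Plk2)` on realized
  log-normalized expression; non-tg forced negative. With the default Plk2
  gradient this yields per-type rates from ~50% (L5 ET) down to ~1% (InN).
* Rendering: one disk blob (radius 3 px, intensity 30000 on uint16) per
  pSyn⁺ cell at its nucleus, placed at sub-pixel precision; optional
  Gaussian background noise (default off — calling is also validated at
  noise = 10% of blob intensity); the true affine (default: 20 px margin
  translation at 1 µm/px) is returned and written alongside the image.
* Determinism: one `numpy.random.Generator` seeded once drives every draw in
  a fixed order; fixed seed ⇒ byte-identical outputs.

Two packaged study conditions support recovery analyses:
`programmed_rate_params(rates, cells_per_type)` zeroes the logistic slopes
and sets per-type intercepts to `logit(rate)` so marginal rates are exact,
with bands sized for a target count per type; `cortex10_params()` provides a
ten-type cortical layout (IT/ET/NP/CT subclasses plus InN) with a Plk2
gradient — the across-type vulnerability screen needs the type diversity of
an annotated cortex for its regression to have useful degrees of freedom.

What the generator does **not** emulate: transcript-level spot positions and
optical crowding, segmentation errors, hippocampal anatomy, rostro-caudal
gradients, batch effects, or cytoplasmic/axonal (non-nuclear) inclusion
morphologies. Tests passing on this generator show the pipeline recovers
truth under its assumptions (correct segmentation, nuclear pathology,
NB counts); they do not certify performance on real tissue.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale versions of each
analysis: 2+2-sample studies (~6,300 cells) for call-accuracy and
determinism checks, 20 seeds × 1 tg sample × 8,000 cells for rate recovery,
20 seeds × (2+2) × ~5,000 cells for the screen, 500 replicates of 4v4 × 200
genes for DE null calibration, and 100 simulations of 2,000 cells for GLM
coverage — sizes chosen so the full pipeline stays interactive on one CPU
while keeping binomial/regression noise well inside the asserted margins.
Ties, degenerate inputs and zero cases follow the documented conventions:
constant genes z-score to zero and are excluded from BH; empty percentile
subsets and empty DE contrasts are reported, not errors; ANOVA with zero
within-group variance reports F = +inf (distinct means) or F = 0, p = 1
(identical data).
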