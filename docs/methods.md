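# Methods

This note documents the models implemented in `leukodeconv`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the package's known limitations.

## Mixture model and ν-SVR deconvolution

A bulk expression profile is modelled as a linear combination of cell-type
reference profiles: m = f·B, with m the mixture vector over genes, B the
signature matrix (genes × cell types) and f the unknown cell-type fractions.
The model assumes (i) expression is on the linear scale (mixing is additive
in transcript abundance, not in log space), (ii) the reference profiles are
representative of the cell states present in the sample, and (iii) every
abundant cell type is represented in B — mass from unmodelled cell types is
absorbed into the modelled fractions because the output is renormalised to
the unit simplex.

Estimation (`svr.fit_sample`):

1. Genes are intersected between m and B. B is z-scored **globally** (one
   mean and one standard deviation for the whole matrix, preserving
   between-column structure); m is z-scored over the shared genes. Whether
   the reference implementation standardises B globally or per column is not
   documented; global is the default here and the per-column alternative can
   be obtained by pre-scaling B. Standardisation makes the fractions
   invariant to positive rescaling of the mixture.
2. For each ν in {0.25, 0.5, 0.75} a linear-kernel ν-SVR of m* on the
   columns of B* is fitted (scikit-learn `NuSVR`, C = 1, the conventional
   defaults for this algorithm; both ν grid and C are arguments). ν bounds
   the fraction of support vectors, i.e. how many genes effectively
   constrain the fit.
3. Model selection: the ν whose reconstruction B*·w (raw primal
   coefficients, no intercept) has the lowest RMSE against m* wins. The raw
   — not clipped — coefficients are used for reconstruction, matching the
   convention of the algorithm this module reimplements; the reported
   `pearson_r` is computed on the same reconstruction.
4. The winning coefficients are clipped at zero (fractions are physical
   proportions) and renormalised to sum to one, so every output column lies
   on the unit simplex within 1e-9.

Degenerate inputs fail loudly rather than silently: fewer than two shared
genes, a constant mixture, or a mixture anti-correlated with every signature
(all coefficients non-positive) raise errors; `svr.deconvolve` records
per-sample failures in its QC table and continues. Linear ν-SVR on fixed
input is deterministic, so this stage takes no seed. On noiseless synthetic
mixtures from a full-column-rank toy matrix the estimates agree with a
non-negative least-squares solution of the same standardised system to well
under 0.05 mean absolute error per fraction (tested).

No quantile normalisation is applied to mixtures, and no permutation
p-values are computed for deconvolution significance; both are deliberate
omissions to keep the pipeline minimal and explicit.

## ssGSEA scoring, calibration, spillover

`ssgsea.ssgsea_es` scores one gene set in one sample. Genes are ranked by
descending expression; ties are broken by the stable input gene order and
flagged with a warning when more than 10% of values tie (microarray
intensities rarely tie; determinism matters more than tie elegance). With G
genes and k signature genes, position i (top = 1) carries rank weight
(G−i+1)^α with α = 0.25 by default; the running sum gains the normalised hit
weight at signature positions and loses 1/(G−k) elsewhere, and the ES is the
**integral** of the running sum over all positions (not the maximum
deviation) — the single-sample convention. When the signature is the whole
universe the miss term vanishes and the score is the fixed value forced by
the normalised hit weights. Only ranks enter, so any strictly monotone
per-sample transform of expression leaves scores unchanged (property-tested).

Cell-type raw scores are the mean ES over that cell type's gene sets
(`score_cell_types`); cell types with no usable signature in the expression
universe are dropped with a warning. `calibrate` shifts each cell type's
panel minimum to zero and applies an optional monotone power law
(max(0, x−shift)^exponent / scale); the default is the identity because no
platform calibration constants are bundled — real calibration parameters can
be supplied as a per-cell-type dict. Calibration never changes sample
ranking within a cell type.

Spillover compensation addresses the main failure mode of signature scoring:
transcriptionally related cell types (naive vs memory T cells, monocytes vs
macrophages) share signature genes and therefore leak score into each other.
Given a spillover matrix K (unit diagonal, off-diagonal in [0, 1]), the
compensated score is max(0, tᵢ − α·Σⱼ≠ᵢ Kᵢⱼ·tⱼ) with α = 0.5 by default
(configurable; α = 0 disables compensation). `derive_spillover` estimates K
from synthetic pure-type samples: marker genes up-regulated 8-fold over a
lognormal background, n = 10 replicates per type; K is the mean raw score of
type i on pure-j samples, clipped at zero and row-scaled to unit diagonal.
Unrelated cell types get near-zero off-diagonals; types sharing half their
signature genes spill at K ≈ 0.5–0.7, and an off-diagonal ≥ 0.95 is flagged
as near-singular (the two types are not separable). Numeric parity with any
particular published scoring package is a non-goal: those scores depend on
that package's internal calibration fixtures.

## Flow-cytometry concordance

`validation.validate` joins score and flow vectors by sample id per mapped
pair, computes Spearman's rank correlation (average ranks for ties; two-sided
p from the t approximation, or exact permutation enumeration for n ≤ 9 on
request), adjusts p across exactly the tested pairs, and classifies:

- r ≤ 0 → none (a negative correlation is never evidence the signature
  works, whatever its FDR);
- else FDR > 0.1 → none;
- else r > 0.5 → strong; r > 0.3 → moderate; otherwise weak.

The published rule leaves r = 0.5 and r = 0.3 unassigned; this package reads
the inequalities strictly, so r = 0.5 → moderate and r = 0.3 → weak. Pairs
that cannot be tested (unmapped id, < 4 matched samples, constant vector)
are reported with a reason, never silently dropped, and excluded from the
adjustment family. BH FDR is the default adjustment; Bonferroni is provided
for small confirmatory panels. Pearson correlation is available in the
underlying scipy call path but is not part of the assessment scheme.

The bundled concordance fixtures carry the published per-pair statistics for
a 255-sample whole-blood cohort (14 regression-method pairs, 25
enrichment-method pairs); feeding them through the classifier reproduces the
published category counts (7/4/3 and 17/2/6), which is what
`scripts/acceptance.py` recomputes. Two values in the source's prose differ
from its tables (monocyte r 0.604 vs 0.259; basophil 0.148 vs 0.016); the
tables are treated as authoritative. The 26-pair clinical-cohort mapping was
published only as counts plus examples; the bundled
`mapping_clarity_reconstructed.tsv` is a documented synthetic reconstruction
honouring those counts (9 + 17 pairs onto 9 phenotypes) and examples.

## Treatment-effect stage

Cohort tables carry arm (placebo / low_dose / high_dose), age, gender and
one score column per signature. Signatures whose zero fraction exceeds 0.99
(strictly) are removed first: a score that is almost always zero means the
method does not detect that cell type in blood, and modelling it would only
spend multiplicity. For each contrast (low, high, or both doses pooled, each
vs placebo) and signature, two OLS models are fitted: score ~ treated + age
+ gender_M (F is the reference level) and score ~ treated. Reported per row:
the treated coefficient and p from the covariate model, that model's overall
F-test p, and the treated p from the simple model. P-values are adjusted
across signatures separately per contrast and per p-type; the adjustment
family is the post-filter signature set. The published account does not name
the adjustment method ("adjusted p-values"); BH is the default here,
Bonferroni selectable. Significance is the dual rule, strictly: adjusted
treated p < 0.1 AND adjusted F-test p < 0.1 — so a treatment signal that is
explained away by age or gender imbalance fails the rule (the confounded
scenario is constructed and tested). The threshold appears both as "< 0.1"
and "≤ 0.1" in the source; strict < is implemented. Null calibration is
simulation-tested: at n = 60/arm over 200 null replicates the unadjusted
treated p falls below 0.1 in 10% ± 5% of cases.

## Synthetic-data generators

- `make_signature_matrix`: per-type marker-gene blocks (lognormal amplitude
  ~ 10× a lognormal background at level 50, amplitude drawn once per gene
  and shared across the cell types carrying that marker — shared markers of
  related cell types are similarly expressed, which is exactly what makes
  such types confusable). `overlap` controls the shared fraction of adjacent
  blocks; the matrix has full column rank below overlap 0.5.
- `make_mixtures`: f ~ Dirichlet(α) per sample, m = B·f with multiplicative
  lognormal noise (scale-dependent error, the realistic microarray regime).
- `make_flow`: percentages 100·f with multiplicative Gaussian noise of
  coefficient of variation `cv`, clipped to [0, 100].
- `make_cohort`: default arm sizes (57, 62, 70) match the clinical subset
  this pipeline targets, and the default female fraction 0.886 matches the
  validation cohort's demographics; injected effects are per-signature mean
  shifts in noise-sd units on the contrast's treated arms, with optional age
  slopes, gender shifts and arm-wise age offsets for constructing
  confounded designs.

All generators are deterministic under a fixed seed, which is recorded in
the returned ground truth. Problem sizes used in the test suite — 50–400
genes, 4–8 cell types, 20–50 mixture samples, 57–70 patients per arm, 200
null replicates — were chosen as the smallest sizes at which the statistical
properties under test are stable.

What the generators do **not** emulate: probe-level array artefacts, batch
structure and normalisation differences, cross-subject variability in the
reference profiles, rare cell types near the detection floor, compositional
correlations between flow percentages, and longitudinal repopulation
kinetics. Passing tests therefore demonstrate correctness of the algorithms
under the stated mixture model, not field performance on any particular
array cohort.

## Known limitations

- Fractions are relative; absolute abundance (cells/µL) is out of scope, and
  unmodelled cell types bias the modelled fractions upward.
- Enrichment scores are arbitrary-unit; only rank comparisons across samples
  within a cell type are meaningful without platform calibration constants.
- The reconstructed clinical-cohort mapping is a stand-in, suitable for
  exercising the machinery but not for reproducing the original per-pair
  numbers.
- The treatment stage models a single timepoint with OLS; longitudinal or
  mixed-effects modelling is a non-goal.
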