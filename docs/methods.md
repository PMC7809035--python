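# Methods

`micronet` re-implements, as a tested pipeline, the analysis chain that links
cortical gene co-expression modules to microglia and to Alzheimer's-related
traits: signature enrichment, covariate-adjusted trait association, a sparse
partial-correlation network, attenuation-based mediation ordering, and two
orthogonal validations of an "activated microglia" expression program
(cell morphometry and single-nucleus proportions). This note records the
models, the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical decisions.

## Bulk preprocessing and module meta-features

Expression enters as a gene x sample FPKM matrix. The association-facing
route is:

1. **Quantile normalization.** Every sample is forced onto the mean
   quantile profile. Ties within a sample receive the mean of the reference
   values across their tied ranks, which makes the operation idempotent.
2. **Expression floor.** Genes with mean FPKM strictly greater than 1 are
   retained; the retained set is also the enrichment background.
3. **log2(FPKM + 1).** The +1 offset keeps zeros finite; at the expression
   levels that pass the floor it is a near-affine change that the
   meta-feature (being per-gene standardized) is insensitive to.
4. **Batch adjustment.** Per gene, each batch (study) is re-centered and
   re-scaled to the pooled mean and SD. This is the location/scale core of
   ComBat without the empirical-Bayes shrinkage of batch parameters; with
   tens of samples per batch the shrinkage matters little, and the
   simplification is exact on the synthetic data where batch effects are
   location shifts.
5. **Residualization.** Per gene, OLS residuals against a covariate design
   (intercept always included; categorical covariates expanded to
   indicators with a first-level reference). The default covariate set for
   the association route is **technical only (RIN, PMI)**: the pipeline
   reports module associations *with* sex and age, which would be destroyed
   if those biological covariates were regressed out of the expression
   first. The full covariate set remains available through the config for
   module-discovery-style cleaning.
6. **Meta-feature.** A module's per-sample activity is the unweighted mean
   of its genes' z-scores (ddof = 1). Zero-variance genes are excluded with
   a warning. The meta-feature is invariant to per-gene affine rescaling
   and has mean zero by construction.

## Cell-type signatures and enrichment

A gene is **cell-type enriched** when its mean FPKM in the sorted-cell
profile is at least `fold` (default 4) times its mean in *every* comparator
profile and strictly exceeds `min_expr` (default 1). The inclusive `>=` at
exactly fourfold is a documented convention choice. One comparator (bulk
tissue) reproduces the aged-microglia signature rule; several comparators
reproduce the microglia/astrocyte/neuron cross-profiles.

Module enrichment is an upper-tail hypergeometric test
`p = P(X >= k)` with `X ~ HG(N, K, n)`, accumulated in log space via
`logsumexp` of log-pmf terms so that extreme enrichments (p ~ 1e-150)
remain finite. Both module and gene set are intersected with the explicit
background before counting; the reported K is the post-intersection count.
The multi-module screen applies Bonferroni at `alpha / #modules`
(0.05/47 ~ 0.0011 at the cortical module catalog's scale).

Ternary coordinates place a gene on the microglia/astrocyte/neuron simplex
by dividing each cell-type mean by their sum; all-zero genes are undefined
and dropped with a warning.

GWAS proximity flags a gene when some probe on the same chromosome has
`p < 0.05` (strict) within `[start - 50 kb, end + 50 kb]` (both boundaries
inclusive; intervals are 1-based inclusive in this tool's dialect).
Inconsistent chromosome naming between the two tables ("chr1" vs "1") is
detected and reported rather than silently producing an empty overlap.

## Trait association

Associations are OLS with intercept: `trait ~ meta-feature + age + sex +
study + RIN + PMI`, two-sided p-values. The cell-type-adjusted variant adds
other module meta-features (neuronal, astrocytic, oligodendrocyte,
endothelial) as extra covariates. Cohort-subset analyses (one study only,
cognitively non-impaired) are row filters, not separate code paths.
Multiplicity is handled by Bonferroni (`p < alpha/m`) or Benjamini-Hochberg
step-up; the BH "threshold" reported is the largest rejected raw p, which
is the data-dependent number such tables typically quote.

**Cognitive decline slopes.** Annual global cognition is modeled as a
linear mixed model with fixed effects (time, age, sex, education) and a
correlated random intercept + slope per subject (REML). Time is centered
internally — the slope is invariant to the year origin and the optimizer is
much better conditioned. Each subject's slope is the fixed time effect
plus the conditional mode of their random slope, computed directly as
`b_i = G Z_i' (Z_i G Z_i' + s^2 I)^{-1} r_i`; this formula stays defined
when the estimated slope variance collapses to zero (everyone declining at
the same rate). When the within-subject residual variance is numerically
zero the mixed likelihood is singular and per-subject OLS slopes — the
exact noiseless limit of the conditional modes — are returned instead.
Subjects with fewer than two visits receive a missing slope.

**Mediated fraction.** How much of an exposure's (e.g. sex's) trait effect
a module accounts for is reported under two labeled definitions, since the
phrase "variance explained by the exposure" is ambiguous:
*attenuation* `1 - beta_adj/beta_unadj`, and *variance ratio*
`1 - dR2_with/dR2_without` where dR2 is the exposure's incremental R^2.
Both are flagged undefined when the unadjusted exposure effect is
indistinguishable from zero (|t| < 1).

## Partial-correlation network

Module meta-features, traits, and technical covariates are standardized
and treated as jointly Gaussian. The graphical lasso maximizes
`log det(Omega) - tr(S Omega) - lambda * sum_{i != j} |Omega_ij|` (diagonal
unpenalized); partial correlations are
`rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)`, and an edge is any nonzero
off-diagonal rho among visible nodes. RIN and PMI participate in the
estimation but are suppressed from the reported edges.

The penalty is tuned by repeated 10-fold cross-validation (10 repeats) over
25 log-spaced grid values in [0.01, 1.0] on the correlation scale, scoring
held-out Gaussian log-likelihood `log det(Omega) - tr(S_test Omega)` with
test data standardized by training-fold parameters. The winner is chosen
by the one-standard-error rule toward larger lambda (sparser); exact ties
also break sparser. Leave-one-out (folds = n) is allowed as a degenerate
configuration; otherwise at least 2 x folds samples are required.

Numerics: the solver is penalized coordinate descent
(scikit-learn's `graphical_lasso`). The final fit runs to a duality-gap
tolerance of 1e-4 within 500 sweeps; CV scoring fits, which only need to
*rank* penalties, use 1e-3 within 100 sweeps — this keeps the 2,500-fit CV
sweep fast without measurably moving the selected penalty. `lambda = 0`
returns the plain inverse; a penalty above the largest off-diagonal |S|
returns a diagonal precision. Duplicated or collinear nodes make S
singular and are reported by name.

## Mediation ordering

The decision rule is deliberately simple regression attenuation: with
covariates (always including RIN and PMI), if A's coefficient on B has
p < 0.05 alone but p >= 0.05 once C enters the model, A-B is *mediated*
through C; p >= 0.05 alone is *no association*; anything else is
*not mediated*. alpha = 0.05 is the default and exposed in config.

`order_triple` runs the rule for all six directed orderings of a triple.
An ordering U -> M -> D is **supported** when U-D is mediated by M while
U-M and M-D each remain significant given the third variable. The
supported set may be empty or contain several orderings — ties are
reported, never resolved by an invented fit statistic. Outputs are labeled
"ordering consistent with the data": cross-sectional attenuation cannot
establish causality, and no counterfactual estimator (product of
coefficients, bootstrap indirect effect) is computed.

Note one structural symmetry: if X -> Z -> Y truly holds, the mirrored
ordering Y -> Z -> X is typically also supported (attenuation is symmetric
in the endpoints); what the data *can* exclude is the wrong mediator, e.g.
X -> Y -> Z. Recovery checks therefore assert the true ordering present
and the wrong-mediator ordering absent.

## Morphology

Cells are 8-connected components of a binary mask; components under
`min_area` (default 5 px) are discarded and counted. **Compactness** is
the population variance of the pixels' Euclidean distances to the centroid
divided by the pixel count: a 3x3 square scores 0.020227, a filled disk
~0.0177 regardless of radius, and a one-pixel-wide line of length L scores
~L/12 — so ramified cells score high. Population (not sample) variance is
a documented convention choice. The statistic is invariant to translation
and 90-degree rotation; coordinates are pixel centers, 0-based.

Marker positivity uses a global Otsu threshold per channel per image; a
cell is positive when at least `positive_fraction` (default 10%) of its
pixels exceed the threshold, and double-positivity is the conjunction of
per-channel flags. Both the thresholding rule and the fraction are config
because the original "default thresholding"/"overlap of positive signals"
procedure is underdetermined; raising the fraction can only remove
positives (monotonicity is tested).

Group comparison fits `compactness ~ group` with a random intercept per
subject (REML); compactness is z-scored first so the group coefficient is
in SD units. A single subject degenerates to OLS with a warning. The
per-subject positive fraction is related to ordinal stage scores (Braak
etc.) by OLS with the stage treated as numeric; at fewer than 4 staged
subjects the regression is refused.

## Single-nucleus validation

Counts are normalized to CPM per cell (zero-total cells dropped with a
logged count). A cell's module score is the unweighted mean CPM over the
module's *detected* genes — unlike the bulk meta-feature there is no
per-gene z-scoring, because per-gene standardization is dominated by
dropout noise at single-cell depth. Per-subject composition is the
proportion of each of the four microglial clusters relative to their sum
(clustering itself is an input; no clustering algorithm is implemented).
One cluster's proportion is related to a pathology trait by a Huber
M-estimated linear model (tuning constant 1.345, 95% Gaussian efficiency)
with sex and PMI as covariates — with ~50 subjects a single outlying
composition can otherwise dominate an OLS fit.

## Synthetic cohort generator

The generator produces every input with known ground truth, all randomness
flowing from one root seed through named child streams (one per output),
so adding an output never perturbs existing ones. Streams use the
counter-based Philox generator keyed by (seed, stream hash): during
development, PCG64 streams under this keying scheme showed excess,
seed-clustered correlation between specific draw blocks — enough to
distort null calibration on small seed ranges — and Philox removed it.

**Causal structure.** Subject-level latents follow two chains:
`sex -> m114 -> amyloid -> decline` and `m5 -> tau -> decline`, plus
`m113 -> amyloid` and `age -> m116`, with standardized path coefficients
(defaults: sex->m114 0.30, m114->amyloid 0.30, m113->amyloid 0.25,
m5->tau 0.35, amyloid->decline 0.25, age->m116 0.30, and tau->decline
0.50 — the tau-cognition coupling is deliberately the strongest path,
matching its dominant role in cognitive aging, and it gives the mediation
ordering check adequate power at n = 400). Residual SDs are set so every
latent has unit variance. Sex is coded 0 = male, 1 = female and enters the
structural equations as a +/-1 contrast; tests compare magnitudes and the
generator's documented directions, not any external sign convention.

**Defaults.** 400 subjects; 12 modules of 25 genes each (five immune, four
cell-type, three background) plus 100 unassigned genes; gene log2-noise SD
0.5. Pathology is Gaussian on the square-root scale (clipped at zero; the
raw scale is the square), with ordinal stages cut from pathology
quantiles. Expression is built on the log2 scale — baseline + loading x
module activity + RIN/PMI gradients + a study-batch shift + noise — and
exponentiated, so FPKM is strictly positive. Decline slope is
`-0.05 - 0.10 x` the decline latent (per-year units; SD 0.10 across
subjects, the realistic order for annual global cognition).

**Other outputs.** Reference profiles plant each signature at 6x bulk with
5% log-normal replicate noise, so the fourfold rule recovers the planted
sets exactly with margin on both sides. Longitudinal cognition has
per-subject intercepts, the shared decline slope, age/sex/education level
effects, and i.i.d. visit noise (default 8 visits, SD 0.25). Cell images
place disk-plus-arms blobs on a 40 px grid (guaranteeing disjoint,
connected cells); arm length grows with a per-cell ramification latent
that the marker-positive group shifts by the configured effect (default
-0.3), and the positive fraction rises with the subject's tau stage.
Single-nucleus counts are Poisson-lognormal around four cluster profiles,
with cluster 1's m5 genes doubled and the per-subject cluster-1 weight
`exp(0.8 x tau_z)`. The GWAS table spaces genes 250 kb apart and plants
one sub-0.05 probe inside the +/-50 kb window of each designated gene.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level sampling, library-size and GC/length
artifacts, isoform structure, correlated module activities beyond the
specified chains, non-Gaussian pathology tails, LD structure among GWAS
probes, empirical-Bayes-scale batch heterogeneity, spatial tissue
organization, ambient RNA and doublets. Recovery results demonstrate that
the estimators find the planted structure at realistic effect sizes and
sample sizes; they are not evidence about any particular cohort.

## Problem sizes used by the test suite and acceptance script

Chosen to finish comfortably on one CPU: recovery checks run 20 seeds at
n = 400; null calibration pools 20 seeds for uniformity and 100 seeds for
the BH false-discovery check (the proportion estimate at 20 seeds is too
noisy to be meaningful); morphology uses 6 subjects x 600 cells for effect
recovery and 6 x 150 for the null battery; the single-nucleus check uses
48 subjects and 2,000 nuclei; oracle comparisons (hypergeometric
enumeration at N <= 20, proximal-gradient graphical-lasso objective at
5 x 5) are exact-scale.

## Known limitations

- The mediation verdicts are threshold-based attenuation statements, with
  all the fragility that implies near p = 0.05; they order hypotheses, not
  causes.
- The selected network is a function of the CV fold randomness; only
  edge-level conclusions stable across seeds should be trusted (the edge
  set itself is not a deterministic function of the data alone).
- Batch adjustment is location/scale only; strongly outlying small batches
  would benefit from empirical-Bayes shrinkage that is not implemented.
- The double-positivity rule (10% of pixels over Otsu) is a stand-in for
  an underdetermined original procedure; conclusions sensitive to the
  fraction should be checked across config values.
- Real-data mode expects the documented TSV/CSV schemas; module discovery,
  alignment and quantification are out of scope and consumed as inputs.
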