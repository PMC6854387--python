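# Methods

This note records the statistical model behind `picrisk`, the conventions
the implementation commits to where the method leaves a choice open, and
what the synthetic-data generator does and does not emulate.

## Effect sizes

A branch sample is one experimental branch with an ant treatment arm
(control / excluded), an optional bird stratum (access / excluded), a
foliage area in m², and a count per herbivore species. Counts are pooled
across branches and years within each arm before any ratio is formed:
density = Σ counts / Σ areas, and LRR = ln(control density / exclusion
density). Pooling first is deliberate — most species are too rare for
branch-level ratios — and it makes the estimate a ratio of two Poisson-like
totals, which is consistent but biased at small totals. No small-sample
bias correction is applied: the correction requires a per-species LRR
variance, which a single pooled ratio does not have. A species with a
zero-count arm gets a missing effect (with a logged warning), never an
imputed continuity-corrected one.

Supplemental-year samples (2016-style, all bird-excluded) enter LRR pooling
but are excluded from the abundance metric and from body length, which use
the core years only; this is implemented as a year mask per metric
(`effects.CORE_YEARS`).

Species filters preserve the asymmetric thresholds of the assays exactly:
the main analysis set requires strictly more than 10 records; per-stratum
effect estimates require at least 5 records in that stratum; the
behavioral-response metric requires ≥ 5 assay records while the fleeing
metric requires > 5. The abundance metric is the natural log of the record
count; the base is configurable and immaterial after standardization.

## Trees, phylodiversity, contrasts

Trees are rooted, tips uniquely labeled. Polytomies are never resolved
silently: the original analysis resolved them by expert opinion, so
`Phylogeny.resolve_polytomies` takes an explicit tip-priority order and the
comparative operations refuse multifurcating input. Two branch-length
schemes are supported for undated trees: all branches = 1.0, and Grafen's
heights, node height = ((tips below − 1)/(N − 1))^ρ with tips at height 0
(root height 1, ρ = 1 by default, exposed in the configuration).

Host phylodiversity is the summed branch length of the minimal subtree
spanning a species' hosts up to their most recent common ancestor. Whether
the path from that ancestor to the tree root should count is a genuine
convention fork (root-inclusive Faith's PD vs. MRCA-rooted PD); the default
is MRCA-only — so a one-host specialist scores 0 — with `include_root`
available and recorded in every output. The undated oak split of the host
tree is dated by the midpoint rule (equidistant between the dated parent
node and the tips), provided as `date_undated_node`.

Contrasts follow Felsenstein's pruning recursion with the standard
adjusted-branch-length update v + v_i v_j/(v_i + v_j). Contrast signs are
arbitrary in the method; the implementation fixes them deterministically
(the child whose smallest descendant tip label sorts first is the minuend)
so repeated runs and different traits share a sign convention. Correctness
is anchored two independent ways in the tests: against dendropy's contrast
implementation, and against the exact theorem that the through-origin
regression slope on standardized contrasts equals the GLS slope under the
explicit Brownian tip covariance (checked to 10⁻¹⁰ relative tolerance on
random trees of up to 8 tips).

## Multimodel inference

Regressions on contrasts are constrained through the origin. The
information-criterion bookkeeping uses conventions that were validated as a
chain against a published eight-model comparison table: the Gaussian
log-likelihood is evaluated at the ML residual variance RSS/n; the
parameter count is k = slopes + 1 (the residual variance counts, so the
null model has k = 1); n is the number of contrasts (19 for a 20-species
tree). Under exactly these conventions the published AICc values are
reproduced from the published log-likelihoods to within rounding (±0.02),
which is how ties among rival conventions (REML vs ML variance, k with or
without σ²) were broken.

Predictor contrast vectors are standardized to mean 0, SD 1 (ddof = 1)
before model fitting; the response contrasts are not (the source analysis
describes standardizing the predictors only; a flag enables standardizing
the response too). Stage 1 fits all 2⁵ = 32 subsets and ranks predictors by
RVI, explicitly by rank and not by an RVI cutoff; RVI ties are broken by
predictor name with a loud warning. Stage 2 refits the 2³ = 8 subsets of
the top three.

Model-averaged slopes are conditional averages over the models containing
the predictor, with weights renormalized, matching the "averaged across all
models in which each parameter appeared" convention; a full-set shrinkage
average (absent models contribute 0) is available behind
`conditional=False`. The unconditional standard error is Buckland's
SE = Σ w′ᵢ √(var(βᵢ) + (βᵢ − β̄)²), and intervals use the normal 1.96
multiplier. Within-model slope variances use the unbiased residual variance
RSS/(n − p) — the GLM convention — while the likelihood uses the ML
plug-in; the two roles are distinct and both are fixed here.

Two conventions deserve flags rather than guesses. Uncentered R² is
1 − RSS/Σy² with adjustment factor n/(n − p); for the null model this is
defined as identically 0, although published null-model adjusted R² values
of about −.03 imply some other (unstated) convention — the discrepancy is
documented rather than reverse-engineered, and nothing downstream consumes
the null model's R².

## Treatment contingency

Per-stratum contrasts are computed independently on the tree pruned to each
stratum's qualifying species, then stacked. The ANCOVA design has no
intercept — [x, 1{group A}, 1{group B}, x·1{group B}] — so the treatment
term carries 2 df; terms are tested with sequential (type-I) sums of
squares in the order predictor, treatment, interaction, residual df
n − 4. This layout is pinned down by the published df pattern
(1 / 2, 24 / 1 with 28 stacked contrasts) and is verified by the exact
decomposition Σ term SS + residual SS = uncentered total SS. The
interaction F is invariant to which group indexes the slope offset (tested).
Predictor contrasts enter the ANCOVA and the per-stratum regressions
unstandardized: per-stratum z-scoring would distort the interaction test,
and the reported statistics (F, adjusted R², p) are invariant to any common
rescaling anyway.

Contrast–contrast association uses the ordinary Pearson correlation with
df = n − 2, matching the published degrees of freedom (17 for 19
contrasts), rather than a through-origin correlation sometimes advocated
for contrasts.

## Synthetic data

The generator emulates the study's structure at its scale: 20 species on a
random Yule (or balanced) tree; five traits evolving under correlated
Brownian motion (unit variances, +0.5 correlation between diet breadth and
behavioral response, root state 0); two bird strata × two ant arms × 280
branches each (≈ 560 branches per arm overall); foliage areas ~
N(1.5, 0.5²) m² truncated at 0.1; baseline density 0.05/m². Counts are
Poisson: exclusion mean λ_s·area, control mean λ_s·area·exp(β·z_s), so a
species' true LRR is exactly β·z_s on the standardized trait scale; the
default β = (+0.39, +0.41, 0, 0, −0.42) mirrors the magnitude and signs of
the effects the method targets. Species baseline densities λ_s vary with
the latent abundance trait (spread 0.8 on the log scale), which reproduces
the ~25-fold range of record counts seen in real samples and prevents the
observed abundance (ln record count) from being a mechanical copy of the
estimated LRR. Observable traits are monotone maps of the latent ones
(phylodiversity affine into a 0–250 my range, proportions via a logistic
squash, length affine in mm), so fixtures respect the real columns' bounds
while preserving rank information.

What the generator does **not** emulate: site/block spatial structure
affects only labels (counts are exchangeable across branches);
overdispersion beyond Poisson; measurement error in the behavioral assays;
and topology uncertainty beyond a single nearest-neighbor-interchange
variant. Passing recovery tests therefore demonstrate correctness of the
inference chain under its own sampling assumptions, not robustness to the
field data's unmodeled structure.

Calibration studies that need contrast-level truth bypass the tree layer:
`simulate_contrast_regression` draws predictor contrasts i.i.d. N(0,1) and
the response as Xβ + N(0, σ²) with σ = 0.5, chosen so a slope of 0.5 gives
a single-predictor R² near 0.5 — the middle of the fit-quality range the
method encounters in practice. Under these conditions (19 contrasts,
β = {0.5, 0}, 2,000 replicates) the model-averaged 95% interval for the
real slope covers the truth ≈ 94% of the time and the real predictor
outranks the null one by RVI in ≈ 99% of replicates.

## Numerical choices and problem sizes

Invariant checks use 10⁻¹⁰ relative tolerance throughout. Exact-fit
degenerate regressions (RSS = 0) report infinite log-likelihood rather than
erroring. All simulation-based tests fix seeds; the test suite's larger
studies use 1,000 Brownian replicates for the contrast-distribution check
and 2,000 replicates for interval calibration, sizes at which the checked
quantities are stable to well inside their test tolerances while the whole
suite stays fast. Known limitations: no phylogenetic GLS with estimated
branch-length transformations (contrasts only, by design), no mixed-effects
structure for site/block/year, and no interaction terms among continuous
predictors.
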