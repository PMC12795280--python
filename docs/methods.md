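# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Dietary scores

**Diversity and variety.** Scores are computed from a participant × item
intake table (g/day) and a two-level taxonomy (42 fine food groups
refining 22 coarse groups, with beverage and liquid flags). Count scores
tally units (groups for *diversity*, items for *variety*) with positive
consumption; the Simpson (Berry) form is `1 − Σ pᵢ²` over the gram shares
of the units in scope, ranging 0 (one unit consumed) to `1 − 1/R` (equal
shares over R units). Shares are computed on grams, not energy. A
participant with zero intake in a scope is assigned 0 (minimal diversity)
with a warning rather than an error, because beverage-excluding scopes can
legitimately be empty. Two beverage exclusions are exposed: `beverages`
drops items flagged as beverages; the stricter `liquids` additionally
drops milk-type items.

**HFD and the 0–100 composite.** The healthy-food-diversity column is the
full-diet Berry index times a health-value-weighted share sum, with health
values (per food group, in [0, 1]) supplied by configuration — published
health-value vectors vary by food-composition source, so they are an input
rather than a constant. The composite score is
`50·(groups consumed / #groups) + 50·(items consumed / #items)`, an
equal-weight min–max normalisation of the two count scores.

**Diet quality (AHEI/DASH style).** Both indices are config-driven
component scorers rather than hard-coded tables: an AHEI-style component
interpolates linearly from its minimum (0 points) to its maximum
(10 points), reversed for adverse components; a DASH-style component
scores the cohort consumption quintile 1–5, reversed for adverse
components. Default rule sets with the canonical 11 (AHEI) and 8 (DASH)
components ship with the package, with thresholds chosen for the
synthetic generator's variables; real-cohort users supply their own
thresholds. Alcohol is scored beneficial-linear to a moderate ceiling
rather than J-shaped — a simplification documented here deliberately.

**aDII.** Each weighted item's intake is regressed on total energy across
the cohort (Willett residual method), the residuals are z-standardised,
multiplied by a literature pro(+)/anti(−) inflammatory weight and summed.
The regression and standardisation are fitted on plausible reporters
only; participants flagged by the Harris–Benedict band (energy < 0.5·BMR
or > 3.5·BMR, classic 1919 coefficients) receive NA. Consequences of the
construction, used as test oracles: the cohort mean is 0, the score is
invariant to adding a constant to an item's intake, and equivariant under
weight scaling.

## QASD

Tertile cut points are the nearest-rank empirical 33.33/66.67 percentiles,
computed with integer arithmetic (`ceil(n/3)`, `ceil(2n/3)`) so exact
thirds never suffer float rounding. Values tied with a cut point go to the
lower tertile (conservative; configurable by supplying external cut
points, which also supports calibrating score categories against a
reference cohort). Current smokers score 0; former, passive and
non-smokers score 1 — passive smokers are not active smokers under the
binary recoding, and the mapping is overridable. Any missing component
makes the total NA rather than a partial sum.

## Metagenome processing

Rarefaction draws exactly `depth` reads per sample *without replacement*
(multivariate hypergeometric), with an independent RNG sub-stream per
(sample, replicate) so results do not depend on evaluation order.
Gene richness (GMGR) is the mean over replicates of the number of genes
hit at least once; samples shallower than the target depth are NA.
Frequency normalisation divides counts by gene length and scales rows to
sum to one. An MGS's abundance is the mean frequency of its 50 marker
genes when strictly more than 10% of them (≥ 6 of 50) have frequency > 0,
else 0; "positive signal" means frequency > 0 with no floor. Cell-count
correction multiplies each sample row by `count / mean(count)`. The
rank-based inverse-normal transform uses `Φ⁻¹(rank/(n+1))` with average
ranks for ties; a Blom offset is available via `offset="blom"`.

## Association screening and deconfounding

Partial Spearman correlation ranks both variables, residualises the ranks
on the covariates by OLS (categoricals one-hot), and tests the Pearson
correlation of the residuals on `n − #cov − 2` degrees of freedom.
Cliff's delta is computed from joint ranks (equivalently `2·AUC − 1`);
its CI uses the consistent-variance normal approximation combining row,
column and overall dominance variances.

The deconfounding machine takes a two-level exposure contrast, filters
features to ≥ 20% prevalence, runs a naive rank-sum screen with BH-FDR
(default threshold 0.1), then refits the rank-transformed feature on
covariates plus recruitment-center dummies with and without the exposure.
Status: `NS` (naive screen fails), `OK_nc` (no covariate associates with
the feature, so no confounding candidate exists), `OK_sd` (exposure adds
explanatory power, LRT p < 0.05, and the Cliff's delta CI excludes zero),
`confounded` otherwise. Recruitment center enters as fixed-effect dummies
— a deliberate modelling choice over a random intercept; the LRT then
compares two OLS fits via `n·log(RSS₀/RSS₁)` against χ². Type-I control
is verified on null panels (mean OK_sd fraction ≤ 0.15 over 20 seeds).

Type-III ANOVA uses sum-to-zero factor coding; marginal means evaluate
the fit at covariate means; pairwise level contrasts are adjusted with
the studentized-range (Tukey) distribution.

## Mediation

`LinearMediation(outcome, mediator, exposure, covariates).fit()` fits the
two OLS regressions, reports ACME = a·b, ADE = c′, total = a·b + c′ (an
exact identity in the linear no-interaction model, asserted to 1e-8),
and simulates uncertainty by drawing coefficient vectors from the
asymptotic normal distributions of the two fits (quasi-Bayesian, default
1000 draws; a nonparametric bootstrap is available by flag). CIs are
percentile 2.5/97.5; p-values are `2·min(P(draw ≤ 0), P(draw ≥ 0))`. The
proportion mediated is the point ratio ACME/total (it can exceed [0, 1]
when the paths oppose; the raw value is kept and only clipped for impact
tiering: high > 20%, medium 10–20%, low < 10%). The estimator is
cross-checked in the tests against an independent generic mediation
implementation.

The bidirectional enumeration first screens all MGS × metabolite pairs by
covariate-adjusted linear association with BH-FDR < 0.05 (MGS abundances
are expected rank-normal-transformed upstream), then runs each surviving
pair in both directions (1: exposure → MGS → metabolite; 2: exposure →
metabolite → MGS) for each QASD contrast (high vs low, high vs medium,
medium vs low). BH-FDR runs separately per (direction × contrast × effect
type) — the most conservative family choice consistent with requiring
FDR < 0.05 on ACME, ADE and total simultaneously. Significant mediations
are classified shared (both directions) or direction-specific. A
phenotype filter retains results whose mediator and outcome are each
associated with a clinical phenotype (e.g. HOMA-IR) at FDR < 0.05 under
the same adjustment.

Note an identifiability caveat: in the linear Gaussian model a
sufficiently strong chain is typically significant in *both* directions
(the reverse model has nonzero population ACME and ADE), so
direction-specificity is an empirical classification, not proof of causal
direction. The test suite constructs genuinely direction-specific panels
(a = c′, b = 1, equal noise, making the reverse direct effect zero in
population) to exercise the classifier.

## Community analyses

Bray–Curtis is `Σ|xᵢ − xⱼ| / Σ(xᵢ + xⱼ)`. PCoA Gower-centers `−D²/2` and
eigendecomposes; negative eigenvalues (non-Euclidean distances) are
dropped, not corrected, and reported so users can see the lost inertia.
PERMANOVA partitions `tr(H·G)` sequentially over design terms
(McArdle–Anderson), with pseudo-F against the full-model residual mean
square and p-values by free permutation of sample identities; permutation
p-values are `(1 + #{perm ≥ obs}) / (1 + permutations)` so they are never
zero. The PERMANOVA-based mediation statistic is a joint-significance
construction: component 1 is the exposure term's PERMANOVA F (after
covariates); component 2 is the F of the leading ordination axes entering
after exposure and covariates in an OLS on the outcome, with a
Freedman–Lane residual-permutation p; the mediation p is the maximum of
the two. This reproduces the two reported F-terms but is one specific
combination rule among several in the distance-mediation literature,
isolated behind a single function.

dbRDA regresses the positive-axis PCoA coordinates on predictors;
R² is the constrained share of positive inertia, adjusted by the Ezekiel
formula `1 − (1−R²)(n−1)/(n−p−1)`. Forward selection greedily adds the
candidate with the largest adjusted-R² gain while its permutation p is
below alpha; the collinearity pre-filter removes, from any pair with
|Spearman ρ| > 0.9, the member with the larger mean absolute correlation
to the rest. envfit fits a covariate on the first k axes and scales the
unit coefficient vector by √R².

## Synthetic cohorts

A latent standard-normal "healthiness" per participant drives every
lifestyle-linked quantity: nutrient columns load on it (beneficial
positive, adverse negative), dietary evenness scales the Dirichlet
concentration over the 42 food groups by `exp(h/2)`, MET-h/week and
smoking status follow it (smoking by quantile), clinical variables (BMI,
HbA1c, log-normal HOMA-IR, medication propensity) decline with it, and
the fraction of carried species grows with `richness_slope·h` so that the
gene matrix yields a richness gradient. Genes are "detected" when their
expected read count at a nominal 20,000-read depth reaches 1 — a
desk-scale construction that produces the gradient without simulating
reads. Mediation panels plant `M = a·X + β(c₁+c₂) + N(0, σ_m)`,
`Y = b·M + c′·X + β(c₁+c₂) + N(0, σ_y)` with mild confounding β = 0.2 by
default (0 gives the pure chain); feature panels plant direction-1 chains
on the diagonal of an otherwise-noise MGS × metabolite grid. All draws
come from named RNG sub-streams of one master seed, so cohorts are
reproducible and extensions do not shift existing draws.

What the generator does **not** emulate: compositionality and
zero-inflation of real MGS abundances, FFQ portion-size and reporting
error structure, batch/center technical effects, non-linear
exposure–outcome relationships, and unmeasured confounding beyond the
planted covariates. Passing tests therefore demonstrate statistical
correctness of the machinery (calibration, recovery, invariants) — not
that sequential ignorability or linearity hold in any real cohort.

## Problem sizes and defaults

Default analysis thresholds: association FDR 0.05, deconfounding FDR 0.1
with |Cliff's delta| ≥ 0.1, mediation FDR 0.05 on all three effects,
10 rarefaction replicates, 1000 mediation draws, 999 permutations. The
test and acceptance workloads use desk-scale sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: mediation recovery
at n = 2000 averaged over four panels (SE ≈ 1 percentage point on the
mediated proportion), CI coverage over 200 replicates at n = 500, null
calibration over 20 enumeration seeds and 200 PERMANOVA seeds with 99
permutations each.

## Interfaces

The library functions and `scripts/acceptance.py` are the interface; no
console entry point is shipped. Model-style estimation follows the
model/results convention (`LinearMediation(...).fit()` returns a
`MediationResults` with estimates, intervals, p-values and `summary()`);
pipeline stages are pure functions over pandas containers, and all file
I/O is confined to the `io` module (TSV with "NA" missing values,
participant/sample id in the first column).
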