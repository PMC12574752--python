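# Methods notes

## The AWAG framework

The package analyzes survey data in which each respondent answers, for each
of 12 eHealth service items, whether they have heard of it (awareness),
whether they intend to use it (want), and whether they have used it —
independently or with family help (adoption). Items are grouped into three
functional categories (information-based, treatment-intermediary, treatment
services). A respondent engages with a *category* if they engage with at
least one of its items (any-item rule); a category-level field is missing
only when every constituent item is missing for that field.

The **adoption gap ratio** is
`100·(min(A, W) − U)/min(A, W)` on the category counts A, W, U over a
common denominator n. Because n cancels, the ratio is computed on raw
counts and is invariant to scaling all counts by a common factor. If the
any-item rule produces U > min(A, W) (impossible in nested data, possible
in principle elsewhere) the gap is clipped to 0 with a warning rather than
reported negative, preserving the statistic's [0, 100] range.

The **segmentation matrix** cuts both rate axes at the cumulative
technology-adoption-lifecycle breakpoints 15/50/85%, with tiers
`[0,15) / [15,50) / [50,85) / [85,100]` — closed on the upper boundary, so
a rate of exactly 85 falls in the extreme tier and exactly 50 counts as
"high". This convention is forced by the data the framework was designed
around: an awareness rate of 85.3 must land in the extreme tier while a
want rate of 78.4 must not, to produce the opened/want-bias cell.
Groups come from the 50-cut (opened / desire deficiency / perception
deficiency / closed). Within each group an axis is either in its moderate
tier or its extreme tier (≥85 in the high half, <15 in the low half);
**strong** = both extreme, **generic** = both moderate, **want-bias** =
awareness extreme only, **awareness-bias** = want extreme only. Only the
opened-group cells are exercised by real published data; the other
quadrants mirror the opened logic structurally, which is the package's own
design choice — the framework's verbal descriptions do not pin down
subregions outside the opened group.

Reported rates are rounded half-away-from-zero to 1 decimal at
presentation only; classification and gap computation always use unrounded
values (1204/1322 → 91.1, 333/1037 → 32.1).

## Scoring conventions

- Stage coding: awareness = heard code 2; want = intention code 2;
  adoption = use code 2 (family-assisted) or 3 (independent). Want is
  coded from the recorded intention regardless of prior awareness (in the
  field procedure, unaware respondents receive an explanation before the
  intention question; that is a survey procedure, not a computation).
- Likert sums: eHEALS 8 items (8–40), perceived usefulness and perceived
  ease of use 4 items each (4–20). Missing items make the score missing
  under the default strict policy; person-mean rescaling is available but
  off by default, since the source summaries imply complete instruments
  and prescribe no imputation rule.
- Self-rated health: 5 levels collapsed to negative {1,2} / fair {3} /
  positive {4,5}.
- Income: lowest < 40% of the reference per-capita disposable income;
  middle = 40–100% inclusive (both boundary points middle, matching the
  "between 40% and 100%" phrasing); highest above. The reference income is
  a city statistic that must be supplied in configuration — it is never
  defaulted, because a wrong silent default would misclassify every
  respondent.

## Sample-size calculator

`n = ceil(z² p(1−p)/δ²)` with `z = z_{1−α*/2}` at the Bonferroni-adjusted
level `α* = α/k`. The adjusted level is rounded to 4 decimals before the
quantile (configurable via `alpha_precision`), matching the convention of
carrying the adjusted α at reporting precision: 0.05/3 → .0167 → z=2.3932
→ n=895 at p=0.5, δ=0.04. With the unrounded level the quantile is 2.3940
and the ceiling lands at 896; the printed design value is reproducible
only under the rounded convention, which is therefore the default.
Nonresponse inflation is `ceil(n/(1−rate))` (895 at 30% → 1279).

## Cluster-robust regression

Respondents are sampled within hospitals (3 clusters in the reference
design), so the nine logistic models (3 outcomes × 3 categories) use a
cluster-level sandwich covariance: bread = inverse observed information,
meat = sum over clusters of outer products of within-cluster score sums,
scaled by the CR1 factor G/(G−1). Confidence intervals and p-values use
t(G−1) critical values, the standard few-cluster correction; with G=3 any
cluster-robust flavor is fragile, and users should treat the interval
widths as indicative. With fewer than 2 clusters the estimator falls back
to the classical covariance with a warning. statsmodels supplies the
maximum-likelihood fit; the sandwich is computed in-package because the
statsmodels cluster covariance applies an additional (n−1)/(n−k) degrees-
of-freedom factor that is not part of the CR1 definition used here.

Covariate sets follow the published battery: awareness models use sex,
age, marital status, residence, education, income tier, SRH, chronic
disease and eHealth literacy; want and adoption models add perceived
usefulness and ease of use. Continuous covariates enter untransformed
(per-unit odds ratios). Each model is complete-case (listwise deletion,
logged). Whether the published want models conditioned on awareness is not
stated; the battery includes all respondents, consistent with the want
question being asked of everyone. Separation is flagged via diverging
coefficients (|β| > 15) and non-convergence of Newton/IRLS (tolerance
1e-8, 100 iterations; BFGS fallback when the Hessian is singular); flagged
models are reported, never silently dropped.

## Synthetic respondent generator

The generator emulates the reference survey's conditions and is the
package's test bed; its defaults are fixed study conditions, not tuning
knobs.

**Covariates.** Hospital assignment is multinomial with probabilities
proportional to the three reference hospital samples (587/207/484), with a
small per-hospital intercept shift (±0.15) so cluster-robust errors are
non-degenerate. Age is drawn by inverse-CDF interpolation through quantile
knots fitted to the published summaries (median 53, IQR 40–60, minimum at
the inclusion age 15, left-skewed); a parametric skew-normal could not
match this quantile profile. Education is a discrete distribution over
schooling milestones with median 9 and IQR 6–13. Sex, marital status,
residence, income tier, SRH and chronic disease are categorical draws at
the published frequencies. A latent digital-affinity trait (loading −0.55
on standardized age, +0.35 on education) drives the three Likert
instruments: each item is the trait-shared latent plus item noise,
discretized to 1–5, giving sums near the published medians (eHEALS ≈26,
PU ≈16, PEOU ≈14) and realistic age/education confounding of literacy.

**Response mechanism.** Per item, the three stages are Bernoulli with
logistic probabilities; linear predictors use the *same raw-scale feature
columns as the regression design matrix* (so true coefficients are
directly comparable to fitted ones), plus a respondent-level engagement
factor shared across all items (sd 3.4), a per-category factor (sd 0.8),
a fixed per-item intercept offset (±0.25 within category), and the
hospital shift. Want receives a carryover from the item's awareness
(γ=1.0) and adoption from want (γ=1.0); adoption is forced to 0 for
unaware items by default (hierarchy constraint). Adopters are
family-assisted with probability 0.2 (unreported in the source;
configurable). Default coefficient signs follow the published pattern:
negative age, rural and better-SRH effects; positive education, income,
literacy, usefulness, ease-of-use effects.

The strong shared factor is what reproduces the near-nested structure of
real multi-item surveys, where the overall any-of-12 rate (91.1%) sits
barely above the largest category rate (89.4%): with items independent
given covariates the overall rate overshoots by 6+ points. Its size was
chosen, with the stage/category intercepts, in a one-off calibration
(bisection at n=60000) against the published category rates; the
calibrated intercepts are frozen defaults. At n=20000 the generator
reproduces all twelve category-stage rates within ~1.5 percentage points.

**What the generator does not emulate:** the real joint covariate
distribution (no copulas beyond the trait), item-level heterogeneity in
covariate effects, nonresponse/measurement error, and any causal pathway
between stages beyond the simple carryover terms. Passing calibration and
recovery tests therefore shows the pipeline is correct under the assumed
mechanism, not that the mechanism is the truth of any real survey.

**Parameter recovery.** In the default 12-item generator, category-level
indicators are any-item unions over correlated items, so their regression
coefficients are attenuated relative to the item mechanism — by design, no
estimator should "recover" item coefficients from union outcomes. Recovery
studies therefore use `recovery_config()` with `single_item_catalog()`:
one item per category, zero latent factors, zero carryover, zero cluster
shift, no hierarchy forcing. The category indicator is then exactly
Bernoulli(logistic(a + β'x)) and the estimating model coincides with the
mechanism. Under this design, 200 replicates at n=1322 with 3 hospitals
give mean coefficient bias within Monte-Carlo tolerance and 95% CI
coverage of 0.93–0.96 for the age, rural and literacy coefficients.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng(seed)`; the
  response stream uses seed+101 so covariates are reproducible
  independently of responses.
- Pipeline outputs (rates JSON/CSV, matrix figure data, regression table,
  manifest with config hash) are byte-deterministic under a fixed config;
  the manifest contains everything needed to reproduce a run.
- Problem sizes in the shipped tests (n=900–20000, 200 recovery
  replicates, 60000-draw calibration) were chosen as the smallest sizes at
  which Monte-Carlo noise is comfortably below the tolerances being
  checked.
- Figure rendering (matplotlib) is an optional thin layer over the
  deterministic JSON figure data; the JSON is the contract, the image is
  best-effort.

## Known limitations

- Only three clusters in the reference design: CR1 + t(2) inference is
  defensible but inherently low-information; a design with more sites
  would warrant wild-cluster bootstrap, which is out of scope.
- The 16-cell classifier's behavior outside the opened quadrant follows
  the package's mirroring convention and has no published exemplars.
- The generator's calibration targets are category rates computed from the
  published counts; two printed figures in the source table (overall gap
  27.6, treatment adoption 23.1%) are internally inconsistent with their
  own counts (27.5, 23.4%), and the package always reports computed
  values.
- Whether stage questions were asked per item or per service block in the
  original instrument is not documented; the data model assumes per item,
  the finest granularity consistent with the published category counts.
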