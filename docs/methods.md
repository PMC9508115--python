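# Methods

## The problem and the model

Breeding age structure matters for the dynamics of long-lived bird
populations, but the age of an individual breeder is rarely observable. In
colonial gulls, maternal age leaves a measurable trace: both young (newly
recruited, 3–4 years old) and senescent females lay fewer and smaller eggs
than middle-aged ones. `eggage` turns that trace into an age assay in two
steps.

**Step 1 — is egg volume age-structured, and how?** Per-egg volume is
computed from field calipers as `V (cm³) = 0.000476 · length · width²`
(length and width in mm; the coefficient implies these units and we document
them as such). Per nest we use the total volume `VT = Σ V`, the mean
`VM = VT / clutch`, and clutch size (an unordered 5-level factor). Gaussian
identity-link linear models of `VM` (or `VT`) compare eight age
parameterizations — none, linear, quadratic, log, and 14/6/3/2-class
poolings — each with clutch size; a second stage fixes the winning age form
and adds annual covariates. Candidates are ranked by `AIC = 2k − 2 ln L`,
where `k` includes the residual-variance parameter and `ln L` is the
Gaussian maximum likelihood (this matches the convention of the common
R-style GLM output; statsmodels' built-in AIC omits the variance parameter,
so we compute AIC ourselves from the ML log-likelihood).

A structural constraint discovered during design: annual covariates (NAO
indices, food, population sizes) are constant within a year, so a year
factor spans them exactly and any candidate containing both is perfectly
aliased. `fit_glm` detects rank deficiency and raises; the environmental
candidate set therefore crosses food-per-capita with one NAO index (winter
*or* annual, never both — they proxy the same climate signal) without the
year factor, plus a year-factor-only candidate, optionally with an
age × annual-covariate interaction (main effects always accompany an
interaction).

**Step 2 — classify age classes from the measurable variables.** Ages are
pooled into one of four schemes (AGE14: 3..15 single years + 16+ 'Old';
AGE6: 3,4,5,6 + 7–15 'Middle-aged' + 16+ 'Old'; AGE3: 3–4 'Young' + 5–15
'Middle-aged' + 16+ 'Old'; AGE2: 3–4 'Young' + 5+ 'Others'). Because the
age pyramid is bottom-heavy, a classifier trained on the raw table would
simply vote for the majority class. The core procedure is therefore a
*balanced-subsample bootstrap*: each iteration draws, without replacement,
`m` rows from every class (`m` = minority class size), fits a random
forest on the balanced subset, and records

- the forest's out-of-bag (OOB) error and OOB confusion matrix,
- per-predictor Gini (mean-decrease-impurity) importances,
- the forest's predicted class for every nest of the *original* table
  (in-bag rows included, as the procedure prescribes; an OOB-only variant
  is available behind a flag).

Aggregation over iterations: accuracy = mean of `100·(1 − OOB)`;
sensitivity/specificity = mean one-vs-rest rates for the positive class
('Young' by default; schemes without that label report none); importances =
arithmetic means (importances are relative and only comparable within one
run); and a per-nest mismatch count. Nests mismatched in **at least half**
of the iterations (the boundary is inclusive) are flagged as consistently
misclassified, and the flag rate per year and per age gives the error
profile. A regression-forest variant treats age as continuous and reports
the OOB pseudo-R², `100·(1 − OOB-MSE / var(age))`, which can be negative.

Predictor subsets mirror field-data availability: M4.1 = all ten predictors
(VM, VT, Clutch, Year, Food, Foodpc, La_Popsize, Popsize, WNAO, ANAO);
M4.2 = M4.1 without Year; M4.3 = VM, VT, Clutch, Year; M4.4 = VM, VT,
Clutch only.

## Synthetic colony generator

No field dataset is bundled, so the generator produces one with the
statistical structure the analysis assumes — it inverts the fitted model:

- **Age pyramid**: truncated geometric on [3, 28],
  `P(a) ∝ s^(a−3)` with annual survival `s = 0.9` — the stable age
  distribution under constant adult survival, right-skewed as observed in
  long-lived gulls.
- **Clutch size**: multinomial on 1–5 with probabilities
  (0.05, 0.20, 0.60, 0.12, 0.03) — modal clutch 3 in ~60% of nests,
  independent of age by default (clutch is a covariate, not an outcome).
- **Egg volume**: per-egg expectation
  `μ = β₀ + β₁·age + β₂·age² + β_w·WNAO + β_f·Foodpc_z + year effect +
  individual effect`, with defaults β₀ = 52 cm³, β₁ = 1.6, β₂ = −0.064
  (concave, maximum near age 12.5), β_w = 0.5, β_f = 0.8, and independent
  Gaussian effects σ_year = 1.2, σ_ind = 1.8 and per-egg σ_egg = 1.8 cm³
  (volumes truncated positive). These put egg volumes at ≈ 48–60 cm³ —
  realistic for a large gull — with an age signal of a few cm³ against
  comparable noise, so the two-class assay lands in the ~65–70% accuracy
  regime characteristic of this kind of field data. A
  `strong_signal_config()` variant (β₁ = 2, β₂ = −0.08, roughly halved
  noise) is the fixed condition for checks that need clear class
  separation; a `null_signal_config()` (β₁ = β₂ = 0) is the negative
  control.
- **Dimensions**: only volume enters the analysis, so length/width are
  back-solved from the drawn volume at a fixed width/length ratio of 0.68,
  making the volume formula an exact round-trip.
- **Environment**: NAO indices i.i.d. standard normal; April fish landings
  log-normal around a configurable median; both gull populations follow a
  smooth exponential trend with small multiplicative noise. Food per capita
  = landings / combined population, z-scored once over the year table
  (sample SD, n−1) and joined to nests — never re-standardized per subset.

All randomness descends from one master seed through named substreams
(environment / ages / nests), and each bootstrap iteration derives its own
stream from (seed, iteration index), so every stage is bit-reproducible and
insensitive to execution order.

What the generator does *not* emulate: assortative-mating age error in the
labels, age-dependent clutch size (a hook exists but is off), colony-level
habitat differences, non-Gaussian volume tails, and temporal autocorrelation
in covariates. Passing tests on this generator show the machinery is
correct and well-calibrated under the assumed model — not that any
particular wild population carries this much age signal.

## Numerical and design choices

- Forest defaults: 500 trees, `mtry = floor(√p)` for classification and
  `p/3` for regression; Year and Clutch are integer-coded for the forest
  (split-finding on ordered codes; one-hot differs slightly and either is a
  defensible reconstruction).
- Balanced subsampling is without replacement at exactly the minority size.
- Majority-vote prediction for new data breaks ties toward the non-'Young'
  class — conservative toward the rarer positive call.
- The flagging threshold is `count ≥ n_iterations/2`, inclusive at the
  boundary.
- Chi-square tests of young-proportion homogeneity use the Pearson statistic
  on the k×2 table without continuity correction (toggleable), df = k−1.
- Analyses in this package run the bootstrap at 100 iterations and 100–200
  trees, and learning-curve fits at 30 iterations with 10 stratified
  repetitions per sample size; with the default colony, moving from 3000 to
  100 iterations changes the aggregated accuracy by well under one point,
  since the aggregate is a mean over exchangeable iterations.

## Known limitations

- The assay identifies *young* breeders; senescent birds sit on the falling
  limb of the same concave curve and are systematically confused with young
  ones — a limitation of the biology, reproduced faithfully here.
- OOB accuracy at very small training sizes is slightly pessimistic with few
  trees (each row's OOB committee is ~1/3 of the forest), which matters for
  learning-curve endpoints; the learning-curve default therefore uses more
  trees than iterations.
- GLM inference assumes independent Gaussian errors; the generator's shared
  year effects mildly violate independence, which inflates AIC differences
  between year-aware and year-blind candidates but leaves the age-form
  comparison intact.
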