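# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The analysis chain

The pipeline estimates a three-variable causal chain:

```
knowledge  --a-->  attention deployment (area ratio)  --b-->  text novelty
     \_________________________ c' _________________________/
```

**Area ratio.** For an image with a binary object mask, the area ratio is
the object-pixel count divided by the total pixel count, in [0, 1]. With
only a detector bounding box, the box-area fraction is used instead (an
upper bound on the mask ratio for any mask inside the box). In 8-bit PNG
masks, a pixel counts as object when its value exceeds 127; the filled
mask's pixel count is used, not a contour length.

**Text novelty.** Documents are bags of tokens (default tokenizer:
lowercase, split on whitespace/punctuation; morphological analyzers can be
registered). Two corpus statistics are computed per document `d`:

- *novelty to a group*: `Σ_{w∈d} p_{w,d} log(|D|/f_{w,D})` over the
  **distinct** words of `d`, where `p_{w,d}` is the within-document
  relative frequency and `f_{w,D}` the document frequency in the evaluated
  collection `D`. Summing over distinct types (not occurrences) is the
  only reading that does not double-count frequency, since `p_{w,d}`
  already carries it.
- *novelty in history*: `−Σ_{w∈d} p_{w,d} log(p̃_{w,Q})` against a large
  background corpus `Q`. Natural logarithms are the default throughout;
  the base is configurable and rescales both scores by a constant.

Out-of-vocabulary handling for the background score is explicit because the
raw formula is undefined for unseen words: the default is add-one
smoothing over the union vocabulary (`p̃ = (c_w + 1)/(N + V')`), with a
`floor` mode (unseen words get `1/N`) and a `strict` mode (raises) for
reproducing the raw formula exactly.

*Novelty to individuals* is the median of a panel of ordinal 1–5 expert
ratings; an even panel uses the midpoint of the central pair.

**Distance to the specialists.** For review-platform data, professional
knowledge is proxied by the mean cosine distance (`1 − cosine similarity`,
in [0, 2]) between a review's vector and the vectors of specialist-written
reviews. The vectorizer is a pluggable backend; the shipped backend is a
deterministic term-count vectorizer, which keeps the geometry claim (closer
to specialists = more specialist-like vocabulary) testable without any
stochastic embedding. Averaging over specialist documents is the default;
distance to the specialist centroid is available as an option.

**Group comparisons.** Participants are split into the top and bottom
quantile (default 25%, group size `floor(q·n)`, ties broken by id) of one
metric and compared on another with a two-sample *t*-test (pooled-variance
Student by default, Welch by flag). Area ratios are variance-stabilised
before the test with `x → arcsin(x²)`; because the transform is strictly
increasing, the quantile groups are identical on either scale, and group
means are reported both raw and transformed. The effect size is the
standard conversion `r = √(t²/(t²+df))`. For skewed outcomes (rating
medians) a group-wise bootstrap is provided: each group is resampled with
replacement `B` times (default 10 000), the two-sided p-value is the
percentile position of the null-centred statistic, and the CI is the
percentile interval. The `(count + 1)/(B + 1)` correction avoids exactly
zero p-values.

**Beta regression.** The area ratio is modelled as
`y_i ~ Beta(μ_i φ, (1−μ_i) φ)` with `logit(μ_i) = x_i'β` and a single
precision φ, fitted by maximum likelihood (the optimizer is the
`statsmodels` beta-model engine; φ is estimated on the log scale and its
standard error delta-transformed). Responses exactly on the boundary are
compressed into (0, 1) with `y' = (y(n−1) + 0.5)/n` automatically, with a
logged notice. The reported pseudo-R² is the squared correlation between
`logit(y)` and the fitted linear predictor — the common choice for
interpreting the R² of a beta regression; it is reported as a descriptive,
not a decomposition.

**LASSO with AIC-selected λ.** Novelty metrics are regressed on the area
ratio plus knowledge and usage covariates with an L1 penalty to handle the
strong collinearity among those predictors. Predictors are standardized
internally (penalty on unit-variance slopes; intercept unpenalised),
coefficients are reported back on the original scale, and the path is
computed over an ascending λ grid (default log-spaced 1e-3…10, 50 points).
λ is chosen by `AIC = n·log(RSS/n) + 2k` with `k` = number of nonzero
coefficients including the intercept — the standard degrees-of-freedom
estimator for the LASSO; ties go to the smaller λ. At λ = 0 the solution
is exactly OLS; for a single unit-variance predictor it is the
soft-thresholded OLS slope, and both limits are tested.

**Path analysis.** The two regression parts are estimated as
seemingly-unrelated OLS regressions rather than by a general SEM
optimizer: for this saturated linear graph the point estimates are
identical and the identity `total = c' + a·b` becomes an exactly testable
invariant (machine precision, given identical covariate sets in all three
regressions). The indirect-effect SE is Sobel
(`√(a²se_b² + b²se_a²)`) by default; a seeded participant-level bootstrap
(percentile CI) is available and agrees with the delta method within ~20%
on well-behaved simulations. Mediator and outcome enter on the scales the
pipeline produced (raw area ratio, raw novelty); an arcsine-transformed
mediator is a caller-side option since either scale is defensible.

## The synthetic-data generator

The generator emulates a 200-participant survey (and, in `amazon_like`
mode, a larger review platform where only a subset of participants upload
pictures). Defaults are anchored to the survey-scale effect estimates the
pipeline is built to recover and are treated as fixed study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_participants` | 200 | survey sample size |
| `knowledge_items` | 20 | knowledge-test length; score ~ Binomial(items, aptitude), aptitude ~ U(0,1) |
| `beta_intercept`, `beta_knowledge` | −1.4, 0.044 | logit-scale area-ratio model; slope at the survey-scale estimate |
| `precision_phi` | 5.58 | beta-distribution precision of area ratios |
| `gamma_intercept`, `gamma_area`, `rare_noise_sd` | 0.5, −3.0, 0.5 | logit-scale rare-word weight of idea texts; negative `gamma_area` couples focused attention to low novelty |
| `vocab_size`, `zipf_exponent` | 2000, 1.1 | Zipfian background vocabulary |
| `tokens_per_doc` | 80 | idea/review/reference document length |
| `n_reference_docs` | 300 | history corpus size (~24k tokens) |
| `n_specialist_docs` | 645 | specialist reference corpus size |
| `n_raters`, `rater_noise_sd` | 7, 0.8 | expert panel; noise set analytically so implied inter-rater correlations fall in the moderate 0.26–0.63 band |
| `image_size` | 100 | square mask side length |

Mechanics worth noting:

- One root seed spawns a named `SeedSequence` stream per stage
  (participants, reference, specialists, texts, masks, ratings), so each
  stage is bit-reproducible in isolation and the whole dataset is
  bit-identical for identical configs.
- Idea texts mix a common-head distribution (Zipf head, top 20% of ranks)
  and a rare-tail distribution (uniform over the remaining ranks); the
  participant's rare-tail weight is `sigmoid(γ0 + γ1·area + ε)`. This
  mixture was chosen over topic models because it makes the
  novelty↔attention coupling analytically controllable: both corpus
  novelty statistics are strictly increasing in the rare-tail weight.
- The latent rare weight is drawn once per participant and shared by the
  idea text and the expert ratings, so the rating median and the corpus
  scores measure the same underlying novelty.
- The specialist topic is a *narrow* band of 50 mid-rank word types
  (90% of specialist token mass). The band must be narrow: with a wide
  band, two specialist documents barely overlap and cosine similarity is
  dominated by the common head, inverting the intended
  knowledge–distance coupling.
- Masks realise each area ratio as a centred, near-rectangular blob with
  exactly `round(ratio·S²)` object pixels (full-width centred rows plus one
  centred partial row), so the mask→ratio round-trip error is below one
  pixel (`< 2/S` as a fraction).
- Covariates (gender 0/1 with female probability 0.14, age uniform 20–60,
  four ordinal 1–5 usage variables) are drawn independently; the survey
  instrument's covariate marginals are not public, so these are pragmatic
  shapes, flagged in the config, and carry no signal.

**What passing tests do and do not show.** The generator produces the
*statistical* structure of the study — unit-interval attention proxies
whose mean rises with knowledge, texts whose rare-word usage falls with
the attention proxy, ordinal panels with moderate agreement — but not
natural language, real photographs, or realistic covariate dependence.
Green tests demonstrate that the estimators recover the generating
parameters and reproduce the qualitative knowledge → attention → novelty
pattern under the assumed model; they do not certify the substantive
findings on real survey or review data, which additionally depend on
tokenizer, log base and corpus choices that published tables do not pin
down.

## Numerical choices and degenerate inputs

- Natural log everywhere a base is not specified; configurable.
- Strictly generated area ratios are clipped to `[1e-9, 1 − 1e-9]` so the
  open-interval invariant survives floating point.
- `t = 0` by convention when both groups are constant and equal; constant
  groups with unequal means are a fit error, not a silent infinity.
- Quantile splits sort by (metric, id) — deterministic under ties.
- LASSO at λ = 0 switches to a least-squares solve (coordinate descent is
  unstable at zero penalty); elsewhere coordinate descent runs at
  tolerance 1e-10.
- Beta-regression non-convergence or non-finite parameters raise a fit
  error carrying the optimizer diagnostics rather than returning garbage.
- JSON outputs round floats to 12 significant digits, making pipeline
  re-runs byte-identical.

## Problem sizes

Simulation-based tests use the smallest sizes at which the checked
property is stable: parameter-recovery runs use n = 2000 with 50
replicates (beta regression) and n = 500 with 100 replicates (LASSO
support recovery); the end-to-end pattern check uses one n = 1000
dataset; the acceptance script reproduces the full chain at the survey's
own scale, n = 200.

## Known limitations

- The bootstrap comparison is a documented stand-in contract (group-wise
  resampling, percentile p); published analyses of this design do not
  fully specify their resampling scheme, so exact replication of a
  particular bootstrap t statistic is not claimed.
- Only a constant-precision beta regression is implemented (no variable
  dispersion), and only AIC-based λ selection for the LASSO (no CV).
- The neural document-embedding backend is a contract, not a shipped
  implementation; all shipped results use the count vectorizer.
- Exact reproduction of published score magnitudes (e.g. a mean Tf-idf of
  41.51 on a specific idea collection) requires the original tokenizer,
  log base and corpora and is out of scope; the package reproduces the
  formulas and the qualitative pattern.
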