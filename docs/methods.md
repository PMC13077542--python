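# Methods

## Anchor-relative ionization efficiency

Electrospray response in the linear range is proportional to analyte
amount, so the slope of an external calibration line (peak area vs. mass
concentration, ng/mL) serves as the operational ionization efficiency
(IE). Absolute slopes do not transfer between runs or instruments;
ratios against a co-analyzed anchor compound largely do. The package
fixes FHUEA (2H-perfluoro-2-octenoic acid) as the default anchor — a
high-response, stable calibrant — and works throughout with

    exp_logIE = log10( (S_c / S_anchor) · (MW_anchor / MW_c) )

The molecular-weight ratio converts mass-based slopes to a molar
response basis; concentrations stay in ng/mL everywhere and no internal
molar representation exists. The anchor's own experimental logIE is
identically 0, relative logIE is antisymmetric under swapping compound
and anchor, and rescaling all areas by a common factor (a detector gain
change) leaves every relative logIE untouched. These three identities
are enforced as property tests.

Calibration lines are fitted by unweighted ordinary least squares with a
free intercept (`scipy.stats.linregress`); the reported r² is the
squared correlation of fitted vs. observed areas. Inversion of a
predicted logIE into concentration,

    C_pred = A · MW_anchor / (10^logIE · S_anchor · MW_c),

uses the slope only. Intercepts are estimated and reported but never
subtracted: that asymmetry is deliberate, and it is the mechanism that
degrades the lowest calibration levels when intercepts are large (see
the generator's `intercept_scale`). A series needs at least two distinct
levels to fit; non-positive slopes cannot be log-transformed and raise a
domain error naming the compound.

## Feature cleaning and selection

Descriptor tables arrive in the PaDEL export layout (first column
`Name`, remaining columns numeric; empty cells are missing, never zero).
With ~50 compounds against hundreds to thousands of descriptors, four
filters run in a fixed order, each column removal attributed to exactly
one stage:

1. **Missing filter** — any column containing a missing or non-finite
   value is deleted (deletion, not imputation).
2. **Near-zero variance** — a column is dropped iff the ratio of the two
   largest value frequencies exceeds `freq_ratio` (default 19, i.e. a
   95/5 split) *and* the percentage of distinct values is below
   `unique_pct` (default 10). Constant columns always drop. These are
   the long-standing defaults of the R modelling ecosystem's
   `nearZeroVar` filter.
3. **Correlation filter** — while any pair has |Pearson r| > 0.8, the
   member of the currently worst pair with the larger mean absolute
   correlation to the remaining columns is removed (ties: the
   earlier-ordered column). Greedy and deterministic rather than an
   exact minimum vertex cover; an exhaustive pairwise scan of the
   survivors is asserted in tests. |r| is used, not signed r.
4. **Recursive feature elimination** — for each of `folds × repeats`
   (default 5 × 5) resamples, a random forest ranks all candidates on
   the analysis fold and a fresh forest per candidate subset size is
   scored on the held-out fold (RMSE). The selected size minimizes mean
   CV RMSE with exact ties resolved toward the smaller size
   (`pick="best"`); a one-standard-error rule (`pick="1se"`) is
   available for flat profiles. The full column count is always
   profiled alongside the requested sizes. The final subset is the
   top-s ranking of a forest fit on all rows. Everything derives from
   one integer seed.

The random forest is used as the RFE importance engine because the
response is continuous and nonlinear and forests need no tuning to rank;
300 trees by default.

In the end-to-end pipeline the cleaning cascade and RFE see **training
compounds only**. The held-out compounds therefore pass through the
workflow exactly as a standards-free analyte would — a deliberately
strict no-leakage choice, since it is also defensible to select features
on all calibrated compounds.

## Models

Three families map the selected descriptors to relative logIE:

- **Elastic net** (scikit-learn), features centered/scaled inside the
  model pipeline only; grid over mixing l1_ratio 0.1–1.0 and a log-spaced
  penalty.
- **Random forest** (scikit-learn), 500 trees, mtry grid {p/3, √p, p/2};
  raw feature values.
- **Gradient-boosted trees** (XGBoost), depth {2, 3}, learning rate
  {0.05, 0.1}, 200/500 rounds; raw feature values.

Grids are tuned by cross-validated RMSE with repeated K-fold (5 × 2) —
a single 5-fold split of ~40 rows is too noisy to rank hyperparameters —
then refit on the full training data; the CV record is retained on the
model object. The train/test split is uniform at random without
stratification (default 42/8 at n = 50). Metrics are RMSE in logIE units
and R² = 1 − SSE/SST; a zero-variance response is flagged degenerate and
reported with R² = 0. Importances (impurity gain for trees, absolute
standardized coefficients for the elastic net) are normalized to sum to
one and tie-broken by feature name.

## Error metrics

Two conventions coexist. The symmetric IE fold error
`max(pred/actual, actual/pred)` is always ≥ 1 and equals the larger of
the directional error `pred/actual` and its reciprocal — an identity
kept under test. Summaries report median, arithmetic mean, and two RMS
forms: the geometric `10^sqrt(mean(log10(e)²))` (headline; invariant
under elementwise reciprocal and ≥ 1 by construction) and the plain RMS
of the raw ratios. The geometric form is the headline because for ratio
data it is the only RMS that can sit *below* the arithmetic mean — a
median/mean/RMS triple like 1.04/1.10/1.06 is arithmetically impossible
for a plain RMS of values ≥ 1 but natural in log space. Display tables
round half-up to two decimals.

The packaged fish-powder worked example carries certified values, their
uncertainties, isotope-dilution MS results, and QSAR-predicted
concentrations (ng/g) for nine PFASs in a certified reference material;
`table2_report` reproduces its directional error column.

## Synthetic studies

The generator exists so every stage is testable against known truth
without a descriptor calculator or instrument. Defaults describe one
study: 50 compounds, 200 descriptors, the six-level ladder 0.2/0.5/1/2/
5/10 ng/mL, and a 42/8 split downstream.

Structure and rationale:

- **Informative family** (18 columns): equicorrelated at r = 0.65
  around one latent factor. Real 2D-descriptor panels are strongly
  collinear — size, fluorination and polarity surface in dozens of
  descriptors at once — and that redundancy is precisely why a QSAR on
  50 compounds can work. The correlation sits below the 0.8 cleaning
  threshold so the family (mostly) survives the cascade.
- **Latent logIE**: a small linear share (`composite_coef` 0.25) on a
  geometrically weighted composite (decay 0.9) of the whole family, a
  saturating term `tanh(1.6·z₁)` on the leading descriptor (electrospray
  response plateaus against the dominant molecular property), and an
  interaction `0.15·z₂·z₃`. The sum is centred, scaled to extremes of
  ±1.5 (the observed span of relative logIE), noised with
  `ie_noise_sd` = 0.02 log10 units (replicate precision of slope ratios
  from r² > 0.999 curves), and anchored to 0 at the anchor compound.
  A `linear_ie` mode keeps only the composite, for linear-model sanity
  tests. The nonlinearity rides on *observed* descriptors, not the
  latent factor, which is what lets tree ensembles outperform the
  elastic net here.
- **Nuisance columns**: 45 % sit in equicorrelated blocks of 5
  (r = 0.85) to exercise the correlation filter, the rest are
  independent; 5 % of columns are near-constant (a handful of spiked
  values) and 5 % carry missing cells, each planted set designed to be
  caught by exactly one cascade stage.
- **Calibration**: molecular weights uniform on 200–750 g/mol (the PFAS
  range); true slopes follow from the anchored logIE by inverting the
  relative-IE definition, so the noiseless calibrate→anchor roundtrip is
  exact to machine precision. Areas are
  `intercept + slope·level·(1+ε)` with ε ~ N(0, 0.03) (a typical
  full-scan peak-area CV) and intercept ~ |N(0, 0.05·slope)|, which
  reproduces the low-level bias of slope-only inversion: per-level error
  dispersion shrinks as concentration grows.

All randomness flows from `GeneratorConfig.seed` through numbered
SeedSequence spawn keys (descriptors / logIE / molecular weights /
calibration), so stages regenerate independently and exactly.

What the generator does **not** emulate: chromatography, matrix effects,
ion suppression, instrument drift, real descriptor marginals (counts,
skewed distributions), or structure-driven descriptor semantics. Passing
tests demonstrate the pipeline's statistical machinery, not chemical
validity on real panels.

## Scale, runtime, and known limitations

Test and acceptance runs use the 50 × 200 default study (the descriptor
panel trimmed from the thousands a calculator emits, keeping the cleaned
matrix near 120 columns) so a full three-model study completes in a few
minutes on one core.

Two documented tensions at this scale, both visible in the acceptance
suite:

- **Redundancy vs. recovery.** Held-out accuracy at n = 42 demands a
  redundant informative family, but redundancy makes small RFE subsets
  CV-optimal: the profile can legitimately bottom at 5 features, so the
  selected set recovers only a few of the 18 planted descriptors even
  when the full importance ranking places them on top. Giving each
  descriptor enough unique signal to push the CV optimum to 18 makes the
  response unlearnable at this sample size.
- **Held-out fold-error floor.** With 42 training compounds and a
  nonlinear 18-descriptor response, tree-model held-out RMSE plateaus
  around 0.15 log10 units across structural variants, i.e. a median
  held-out IE fold error near 1.2–1.3. Substantially smaller medians at
  this scale would require either more compounds or a response easy
  enough that the linear baseline wins instead.

Other limitations: the anchor is assumed linear with negligible
intercept; calibration weighting (e.g. 1/x) is not offered; descriptors
are consumed as a table, never computed; model transfer across
instruments or mobile phases is out of scope.
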