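# Methods

## Problem and model

`cbqsar` builds quantitative structure–activity relationship (QSAR)
regression models that map numeric molecular descriptors of synthetic
cannabinoids to their cannabinoid receptor 1 (CB1R) binding affinity,
expressed as pKᵢ = −log₁₀(Kᵢ in mol/L) = 9 − log₁₀(Kᵢ in nM).  The
regime of interest is the hard one: a handful of measured compounds
(order 10–15) against hundreds of computed descriptors, most of them
redundant or irrelevant.  Two linear model families are implemented on
the standardized descriptor scale:

* **Forward-selection MLR.**  Ordinary least squares,
  β̂ = (ZᵀZ)⁻¹Zᵀy on centered/standardized predictors with intercept
  ȳ, grown greedily one descriptor at a time.  A candidate is accepted
  only if it strictly increases the adjusted coefficient of
  determination, R²_adj = 1 − (1 − R²)(N − 1)/(N − p − 1).  Ties are
  broken by the larger absolute marginal correlation with the
  response, then lexicographically.  Variance inflation factors,
  VIF_j = 1/(1 − R²_j), diagnose residual multicollinearity in the
  selected set.
* **NIPALS PLS1.**  Partial least squares with a univariate response.
  Per component: w = X′y/‖X′y‖, t = Xw, p = X′t/(t′t), q = y′t/(t′t),
  then deflation X ← X − tp′, y ← y − qt.  This yields X = TP′ + E with
  mutually orthogonal scores; the collapsed coefficient vector
  b = W(P′W)⁻¹q is the prediction contract, so a fitted PLS model is
  consumed downstream exactly like an MLR model.  At full rank the
  collapsed PLS model reproduces OLS, which the test suite checks on
  random instances.

Because every predictor is standardized before fitting, the intercept
of either family equals the training mean response; evaluating any
model at the all-zero standardized vector returns that intercept.

## Descriptor filtering

Before any model is fit, training descriptors pass a fixed three-stage
chain (test rows never influence retention):

1. **Near-zero variance.**  A column is dropped when constant, or when
   its most-frequent/second-most-frequent value-count ratio is
   ≥ `freq_cut` (default 19, i.e. a 95/5 split) and its percentage of
   distinct values is ≤ `unique_cut` (default 10%).  The thresholds are
   the conventional defaults for this filter and are exposed as
   configuration.
2. **Pairwise-correlation pruning** at |r| > 0.9 (Pearson).  While any
   pair exceeds the cutoff, the worst pair is located and the member
   with the larger mean absolute correlation to the other remaining
   columns is removed; ties keep the lexicographically earlier name.
   The greedy rule is deterministic and guarantees no surviving pair
   above the cutoff.
3. **Response correlation**: only descriptors with |r(x, y)| strictly
   greater than 0.3 survive.

Each stage emits a trace (counts in/out plus named removals with
reasons) serialized as JSON lines for audit.

## Validation battery

* R² = 1 − SSres/SStot, with the reference mean made explicit so
  external sets are scored about the *training* mean.
* RMSE with denominator n.
* Leave-one-out Q²: every fold refits the complete procedure —
  standardization included, and forward selection too when the model
  is the forward-MLR — on the n−1 remaining rows; SStot is about the
  full training mean.  Re-standardizing inside each fold is the
  stricter convention and can shift Q² slightly relative to
  implementations that standardize once.
* Predictive R² for an external/test set:
  R²pred = 1 − Σ(y − ŷ)² / Σ(y − ȳ_train)².  The denominator is the
  *squared* deviation about the training mean; the package checks this
  form reproduces the bundled reference statistics where the unsquared
  variant does not.
* Y-randomization: the response is shuffled (X unchanged), the whole
  procedure refit, and cRp² = R·√(max(0, R² − R̄r²)) computed, where R
  is the original model's fitted-vs-observed correlation and R̄r the
  mean correlation of the 25 (by default) permuted models.  The model
  passes when cRp² > 0.5.  The radical form is the standard definition
  of this coefficient; it collapses to 0 when permuted models match
  the original and to R² when they are uncorrelated.
* Grubbs single-outlier test, two-sided at α = 0.05:
  G = max|xᵢ − x̄|/s against
  G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t = t₁₋α/(2n), n−2.  Run once
  (single exclusion), matching the workflow's one-outlier screen.
* Q-Q data for residual normality at plotting positions (i − ½)/n
  (alternative offsets are an argument), with the Pearson correlation
  of the paired quantiles as a straightness summary.

## Applicability domain

All pairwise Euclidean distances among standardized training rows are
computed; the subset strictly below their mean defines ⟨d⟩ and σ
(sample sd), and the threshold is APD = ⟨d⟩ + Zσ with Z = 0.5 by
default.  A query is inside the domain when its distance to the
nearest training row is at most the threshold.  Degenerate
conventions: an empty strict subset (all distances equal) takes ⟨d⟩ as
the common distance with σ = 0; a singleton subset has σ = 0.
Distances are taken in the standardized model space, the same space
every model operates in; raw-space screening is possible by fitting
the domain on unstandardized rows.

## Pipeline

`run_pipeline` fixes the stage order: Grubbs screen on training
responses (with exclusion and logging) → filter chain (train rows
only) → standardization (train-fit, applied to test) → model fits →
validation (Q², R²pred, Y-randomization) → applicability domain →
reports.  The component count for PLS is a user decision informed by a
leave-one-out Q²/R² scan; the default picks the Q² maximum, but the
count can be pinned because small-sample Q² curves are often too flat
to dictate a unique choice.  Everything is deterministic given the
config and seed; the prediction table reports residuals as
observed − predicted.

## Synthetic data

The generator emulates the pathology of real descriptor tables:
informative columns loading on a few shared latent factors (fixed
loadings 0.9/0.8/0.7/0.85/0.75 cycled, idiosyncratic sd 0.4), exact
duplicate columns, i.i.d. junk columns, and constants.  The response
is linear in the standardized informative columns,
y = 6.0 + Σβⱼzⱼ + ε, ε ~ N(0, noise_sd²), on a pKᵢ-like scale, with an
optional planted response outlier.  Roles come from a seeded 80/20
split.  All randomness flows through one seeded PCG64 generator, so a
spec plus seed reproduces a dataset byte for byte.  Column names
encode roles (`info_*`, `dup_*`, `junk_*`, `const_*`) so tests assert
planted structure without re-deriving statistics.

What the generator does **not** emulate: the marginal distributions of
real cheminformatics descriptors (heavy tails, integer counts, bounded
fractions), nonlinear structure–activity relationships, and assay
noise correlated with chemistry.  Passing tests therefore demonstrate
algorithmic correctness and the advertised statistical behavior under
the stated linear-Gaussian conditions, not predictive performance on
real compounds.

The benchmark variants used in tests: a small one (15 compounds,
~286 raw columns, 11 train / 3 test / 1 pre-excluded outlier) matching
the bundled study's scale, and a large one (100 compounds, same column
structure) where cross-validated statistics are stable enough to
assert on.  Benchmark coefficients are chosen so every planted
informative signal carries a marginal correlation safely above the 0.3
filter threshold — a construction requirement, since the benchmark's
purpose is to verify that the chain keeps real signal while discarding
junk.

## Bundled reference dataset

The package ships the study it was built around: 15 compounds (THC and
14 synthetic cannabinoids) with measured CB1R pKᵢ, an 11/3 train/test
split, one excluded outlier (JWH-015, pKᵢ 2.252), the reference PLSR
predictions and applicability-domain distances, and two published
coefficient vectors on the standardized scale — a 2-descriptor MLR
(XLogP 0.8038, ATSc4 −0.4269, intercept 6.3243) and a 16-descriptor
collapsed PLSR (same intercept).  `reference_check()` (CLI:
`cbqsar ref-check`) recomputes from that table alone: training
R² = 0.864, training RMSE = 0.330, test RMSE = 0.370, R²pred = 0.778,
per-compound residuals, the observed-pKᵢ spread 2.737, the Grubbs
screen flagging exactly JWH-015, and the intercept property.

## Known limitations

The reference study's underlying descriptor values were never
published, so everything that requires the descriptor matrix cannot be
recomputed and is deliberately absent from `reference_check`: the
internal Q² values of either model, the applicability-domain threshold
(4.753) and per-compound test distances, the per-component X-variance
fractions, the cRp² value of the reference model, and the external
evaluation-set statistics (Pearson r and R²pred of the literature
compounds).  The saturation-assay dissociation constant is likewise
raw-assay territory, out of computational scope.  These quantities are
all *computable* by the package on user data — they are simply not
verifiable against the bundled study without its descriptors.

Other limitations: only single-response models (no PLS2), no
regularized alternatives (ridge/lasso), no leverage-based or
probability-density applicability domains, and descriptor computation
from structures is out of the core (the pipeline consumes descriptor
CSVs; any engine that emits the documented dialect can feed it).
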