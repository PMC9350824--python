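# Methods

This note records the models, conventions and design choices behind
`edcast`, in the spirit of a statistical software methods appendix.  It
states no empirical claim that the test-suite or `scripts/acceptance.py`
does not itself compute.

## Weekly data model

All series live on a contiguous weekly grid; each week opens on a Sunday
and carries the average daily ED arrival count for that week (so a
baseline of ≈380 corresponds to a large urban ED), or a query's 0–100
search-popularity value.  Gaps are construction-time errors: every
container validates 7-day spacing, so downstream code never handles
missing weeks.

## Synthetic scenario generator

The generator emulates the data regime the analysis assumes — roughly a
year of weekly arrivals spanning an epidemic, with a query panel whose
small signal-bearing subset *leads* arrivals.  Components and defaults:

* **Arrivals.** `baseline 380` + monthly offsets (January and July peaks,
  ±15–30 average daily visits, the bimodal pattern of subtropical ED
  demand) + `6` visits per public-holiday day and `2` per school-holiday
  day + a temperature effect (−1.2 visits per °C of weekly low-temperature
  deviation; cold weeks are busier) + Gaussian epidemic pulses + AR(1)
  noise (coefficient 0.45, innovation SD 8).  Arrivals are truncated at 0
  (never binding at these scales).
* **Epidemic bursts.** Two Gaussian pulses: a large wave (height 80,
  width 1.5 weeks) centred at week 18, inside the 27-week training
  window, and a smaller later outbreak (height 45, width 2) at week 40 in
  the test window.  The pair mirrors a pandemic wave followed by a second
  seasonal outbreak, and gives the leading queries something genuinely
  predictive in the test period; a single-burst configuration is one
  config field away.
* **Temperatures.** Annual sinusoid peaking mid-July (high ≈ 27 ± 5 °C,
  low 5 °C beneath), with independent weekly shocks (SD 1 °C) on the high
  and low series so the two covariates are not collinear.
* **Holidays.** ~17 public-holiday days per year scattered by a dedicated
  RNG substream; whole-week school closures in July–August, late December
  and mid-February.
* **Planted queries.** Nine queries at lags {1,1,1,1,2,2,2,6,7} with
  signed target correlations (−0.33, 0.50, 0.36, 0.43, 0.31, 0.49,
  −0.32, 0.38, −0.42) — the magnitude range 0.31–0.50 of a typical
  screening table.  A planted query at lag ℓ carries the standardized
  epidemic + monthly-seasonal signal read ℓ weeks ahead plus white noise
  whose SD is solved in closed form so that the *expected* Pearson
  correlation between the lag-shifted query and arrivals over the
  27-week screening window equals the target (the solution uses
  across-window moments of the deterministic paths plus the stationary
  arrival-noise variance).  A Monte-Carlo test (200 regenerations)
  verifies each mean realized correlation lands within 0.1 of target;
  in practice it lands within ~0.03.
* **Noise queries.** Independent AR(1) series (coefficient 0.3 — weak
  week-to-week persistence, as observed in trend series for unrelated
  queries).  Every query is min–max scaled to [0,100], mimicking
  search-trend normalization; scaling is affine, so it changes no
  correlation.
* **Seeding.** One master `SeedSequence` spawns substreams for
  temperatures, arrival noise, holidays and each query, so changing the
  panel size never perturbs the arrivals realization, and identical
  configs are bit-identical.

What the generator does **not** emulate: real holiday calendars and
weather, media-driven query spikes and search-engine renormalization
events, non-Gaussian heavy-tailed arrival shocks, and any cross-query
correlation among noise queries.  Passing tests therefore demonstrate
that the pipeline's machinery behaves as specified under its assumed
structure, not that the index would carry the same value on any given
hospital's data.

## Index construction

Screening correlates `q[t − lag]` with `arrivals[t]` for lag = 1…7 over
the training window only; p-values use the two-sided t-distribution on
(pairs − 2) degrees of freedom, assuming approximate normality by
convention.  The best lag is the argmax of |r| with ties broken toward
the smallest lag (shortest memory).  The FDR family is one p-value per
query (its best-lag p), adjusted by Benjamini–Hochberg; selection
requires |r| ≥ 0.30 **and** adjusted p ≤ .05.  The absolute value
matters: negatively correlated queries are legitimate leaders and enter
the sum with their raw sign.

`build_index` is an exact shift-and-sum (hence linear in the panel); the
pipeline min–max weights each query on the training window before fusion
so no single 0–100 series dominates, and the fused index is re-normalized
downstream together with all other predictors.

**A caveat the synthetic experiments make explicit.**  With a 27-week
screening window the sampling SD of r̂ is ≈0.18 and both series are
smooth, so correlation screening has a substantial in-sample
false-selection rate (dozens of noise queries can clear the gate) while
genuinely leading queries with population |r| ≈ 0.3 often fail it —
indeed |r̂| ≈ 0.31 at 25 pairs has raw p ≈ 0.13, which no step-up
adjustment can bring under .05.  On long windows (200 weeks) the
procedure is well behaved (pure-noise selection < 1%).  The package
implements the stated procedure faithfully and reports what it finds;
window length is the binding constraint, not the implementation.

## Validation battery

Pearson correlation runs on min–max normalized raw series; ADF, Johansen
and Granger run on logs (damping outliers).  Conventions:

* **ADF**: constant term, no trend, AIC lag selection.  Rejection is
  evidence of stationarity around a constant.
* **Johansen**: statsmodels' trace test with an unrestricted constant and
  no trend (`det_order=0`, `k_ar_diff=1`); the tabulated 10/5/1% critical
  values for that specification are reported alongside the statistics.
  "Cointegrated" means the rank-0 null is rejected.  Note the boundary
  case: for *driftless* random walks the unrestricted-constant table
  over-rejects somewhat in finite samples (≈12–16% at n=150 and nominal
  5%); with drifting levels the size is nominal.  A collinear pair is
  reported as a degenerate-input error, not a verdict.
* **Granger**: F-test of the AR model of the effect against the model
  augmented with lagged cause.  The lag order is chosen by Gaussian AIC
  of the *restricted* (effect-only) autoregression over 1…7 on a common
  sample.  Selecting on the restricted model means the choice never looks
  at the cause, so under the no-causality null the subsequent F-test
  keeps its nominal size (measured 0.060 at nominal .05 over 2,000
  null replicates in the acceptance suite); selecting by AIC of the
  augmented model inflates size to ≈0.11 and is deliberately avoided.
  A constant cause yields a degenerate result (F = 0), not an error.

## Forecasting

Feature rows for target week t+1 use arrivals(t), month(t+1) as 12
one-hot indicators, temperatures(t), holiday counts of week t+1 (known
in advance from the calendar), and — in the richest set — index(t+1),
which by construction aggregates only query values from weeks t−6…t.
When an index exists, its start-up weeks (before the largest selected
lag) are dropped from *all* predictor sets so accuracy comparisons share
identical target weeks; this comparability mode is the default.  The
split is a contiguous prefix of 27 scenario weeks (26 usable training
targets after the one-step lag) versus the remaining 24 test targets,
with min–max normalization fitted on training rows only (one-hot columns
pass through; training-constant continuous columns are zeroed).
Out-of-window values may map outside [0,1] and are kept.

* **ELM** (native): hidden weights/biases uniform on [−1,1] from the
  seed, `satlins` activation, `β = H⁺Y` via SVD pseudoinverse with a
  machine-epsilon–scaled cutoff (saturation can make H rank-deficient;
  the minimum-norm solution is then well defined).  Hidden-node counts
  are pinned at 20 / 120 / 150 for the three predictor sets.  Because
  the hidden layer is random, the default forecast is the mean of 5
  restarts with seeds spawned from the master seed (the repeat protocol
  caps restarts at 10); `elm_repeat_eval` reports per-restart and mean
  MAPE/RMSE.  With 150 nodes and ~20 training rows the network
  interpolates the training set (training error ~0) and generalizes
  through the minimum-norm property — the intended regime, not a bug.
* **GLM** (native): Gaussian GLM = ordinary least squares with an
  intercept; one in-training month indicator and all training-constant
  columns are dropped, and any remaining rank deficiency raises an
  estimation error.
* **Adapters**: ARIMA(X) via statsmodels SARIMAX (small AIC grid over
  p ∈ {0,1,2}, d ∈ {0,1}, q ∈ {0,1}; the fitted model is *applied* to
  the full series so test forecasts are one-step-ahead with fixed
  parameters), SVR (RBF), MLP and random forest via scikit-learn.
  These delegate deliberately; only the ELM and GLM are contributions.

## Evaluation

MAPE (percent), RMSE (arrival units) and mismatch weeks (absolute
percentage error strictly > 18%) require strictly positive actuals.
The Diebold–Mariano statistic uses the squared-error loss differential
`d_i = (y_i − ŷ_re,i)² − (y_i − ŷ_te,i)²` and the long-run variance
`(γ̂₀ + 2Σ_{k<h} γ̂_k)/N`; with the default horizon h = 1 this is
γ̂₀/N.  The null is "reference at least as accurate as test"
(one-sided, standard-normal reference; the Harvey small-sample
correction with a t reference is available but off by default).  A
zero-variance differential returns statistic 0, p 0.5 and a degeneracy
flag.  Swapping the models negates the statistic exactly (bitwise).
Measured size under an equal-accuracy null at N=24 is ≈0.064 at nominal
.05.

Pairwise DM tables adjust one BH family per table, containing one
p-value per unordered model pair (canonical orientation = input order);
the reversed orientation carries the negated statistic and raw p only.
Note that BH adjusted p-values are not monotone under family growth in
general, so no such invariant is asserted.

Robustness re-runs the full pipeline (index re-screened each run) on 20
expanding windows whose endpoints are evenly spaced over the final third
of the series, and reports the SD of test MAPE and RMSE per model and
predictor set.  Runs in which screening selects nothing fall back to the
no-index sets and are flagged, never silently dropped.

## Problem sizes and numerical conventions

Simulation studies in the suite use the scales at which their
statistical targets are meaningful: 50 random instances (N=30, n=5,
L=20) for ELM optimality, 2,000 replicates at N=24 for DM size, 100
scenario seeds for screening recovery and 100 pure-noise 200-week panels
for the null rate, 200/2,000/100 replicates at n=150 for Granger power,
Granger size and Johansen power, and 20 scenario seeds for the
directional index comparison.  Tolerances: 1e−8 for least-squares
oracles, 1e−12 for closed-form identities.  Degenerate inputs (constant
series, collinear pairs, empty selections, zero-variance loss
differentials) are first-class outcomes with explicit flags or typed
errors, as documented per operation.

## Known limitations

* Correlation screening at 27 weeks is noisy by construction (see the
  caveat above); the index inherits its false selections.
* The Johansen verdict depends on the deterministic-term table; only the
  unrestricted-constant specification is provided.
* Granger causality is predictive precedence, not mechanism; the report
  exposes both directions and adjudicates neither.
* LSTM-style recurrent baselines are out of scope; the adapter registry
  covers the remaining reference models.
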