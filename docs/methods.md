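# Methods

## Model and estimation

The core object is the conditional error-correction form of an ARDL(p, q, r)
equation for annual data: the first difference of the dependent variable is
regressed on a constant, the lagged *levels* of all variables (the long-run
part), lagged *differences* (the short-run part) and impulse dummies. The lag
convention is that order `p` contributes `p − 1` lagged differences, so
`p = q = r = 1` is a levels-plus-constant equation. With max lag m the
estimation sample is the `n − m − 1` rows on which every regressor is
observed; we require `n − m ≥ k + 5` regressors of headroom.

Estimation is ordinary least squares. No estimator is canonical beyond OLS in
this literature, and homoskedastic OLS covariance keeps the Wald F exactly
equal to its restricted-vs-unrestricted RSS formulation, which the test suite
verifies to 1e−8 against independent brute-force refits. The Schwarz criterion
is computed as `ln(RSS/T) + k·ln(T)/T`; lag selection evaluates all candidates
on a common sample (trimmed to the largest candidate lag) and breaks ties
toward fewer parameters, then the lexicographically smallest lag tuple.

## Bounds test and bootstrap

Three statistics decide cointegration: the overall F on all lagged levels, the
t-ratio on the lagged dependent level, and the F on the lagged independent
levels. The t test is one-sided in the lower tail — error correction requires
a negative coefficient. Because asymptotic bound tables are unreliable at
n ≈ 20–60, critical values are bootstrapped:

1. re-estimate the dependent equation with **all lagged levels removed** (the
   no-cointegration null) and fit marginal equations of each independent's
   differences on its own lagged differences;
2. resample residual rows i.i.d. **jointly** across the three equations, so
   contemporaneous innovation correlation survives;
3. regenerate the trivariate system recursively from the observed pre-sample
   levels, dummies pinned to their observed positions;
4. re-estimate the full equation on every replicate and take the empirical
   (1 − α) quantiles of the F statistics and the α quantile of t.

Defaults: B = 2,000 for analysis runs, B = 199 inside Monte-Carlo studies,
α = 0.05. The replicate loop is fully vectorised (batched normal-equation
solves across B), so one bootstrap on n = 50 costs ~10 ms. Everything is
driven by one integer seed; identical seeds give bit-identical critical
values. A replicate system that overflows raises a regeneration error rather
than silently polluting quantiles.

The outcome classifier maps the three significance flags to
{cointegration, degenerate #1, degenerate #2, no cointegration} as described
in the README. Two numerical conventions: a statistic exactly at its critical
value does **not** reject, and the logically possible but substantively empty
cell "overall F significant, neither component significant" maps to no
cointegration with an attached warning.

## Granger causality

Short-run causality from x to y is the Wald F on all lagged-difference
coefficients of x in the y equation, with asymptotic F(m, T − k) p-values.
Long-run causality is the significance of x's lagged level and is *gated* on a
cointegration outcome for that equation — a lagged level in a non-cointegrated
equation is unbalanced and its t-ratio has no usable null distribution. The
statistic is reported in F form with the signed t attached when a single
coefficient is tested. The sign of the summed relevant coefficients is
reported separately from significance, because "positive and significant" are
distinct claims.

## Unit-root battery and the I(2) gate

ADF and KPSS delegate to statsmodels (ADF lag order by Schwarz criterion
within 0..⌊12(n/100)^¼⌋, MacKinnon response-surface critical values; KPSS
against its published quantile table). Phillips–Perron Z-t is implemented
here: the Dickey–Fuller regression with zero lags, corrected through the
Bartlett-kernel long-run variance at truncation ⌊4(n/100)^¼⌋ (the Newey–West
short rule). With bandwidth 0 it reduces exactly to ADF(0); the test suite
also pins it against an independently computed R `stats::PP.test` value and
against Monte-Carlo size under a random walk. A Monte-Carlo critical-value
generator is provided for sample sizes where response surfaces are not
trusted.

Integration order is a majority vote over the stationarity verdicts of
{ADF, PP, KPSS} (KPSS's null inverted), ties resolved toward non-stationarity.
I(0)/I(1) pass the gate; I(2+) refuses the bounds test. **Known limitation:**
at study-like lengths (n ≈ 20–25) ADF and PP have little power on first
differences, so genuinely I(1) variables can be refused as I(2+). That
reflects the true information content of such samples; users can respond with
α = 0.10 for the battery, a longer window, or an explicit override by running
the bounds stage directly.

## Synthetic generator

The generator emulates what the analysis assumes about the real data:
independents evolve as random walks with drift (weak exogeneity), the
dependent follows the conditional error-correction equation, innovations are
drawn from a configurable 3×3 covariance, and one-off shock years enter the
dependent equation as impulses. Level calibration — initial values
(9.0, 61, 2.9), drifts (0.09, 0.28, 0.12), innovation standard deviations
(0.03, 0.25, 0.15) — mimics log GDP around 9–11, life expectancy in the
60s–70s gaining ~0.3 years annually, and alcohol consumption of a few litres,
so demo output looks plausible; the test statistics are invariant to these
scales. Default n = 24 matches a 1992–2015 annual window; burn-in 100
washes out initial conditions.

Scenario presets: cointegration uses error-correction speed −0.5 toward
y = x + 0.5z; degenerate #2 mean-reverts the dependent alone (speed −0.5,
no level links); degenerate #1 puts direct lagged-level coefficients
(0.1, −0.1) of the independents into the dependent equation with zero error
correction — note this makes the dependent I(2)-like by construction, which is
exactly why the case is "degenerate"; one-way short-run causality uses a
lagged-difference coefficient of 0.8 from x into y; bidirectional adds an 0.8
feedback of lagged Δy into the x equation. What the generator does **not**
emulate: measurement revisions, structural breaks in drift, bounded support of
life expectancy, or cross-country dependence — so green calibration tests
certify the inference machinery, not the realism of any one country's series.

A single seed drives each simulation; the Monte-Carlo harness derives
per-replicate (simulation, bootstrap) seed pairs from its master seed with a
PCG64 stream, making nested experiments reproducible bit-for-bit.

## Problem sizes and numerical choices

Monte-Carlo studies in the test suite use the sizes at which the properties
are claimed: bootstrap size at n = 50 with 500 replicates × B = 199;
power with error-correction speed −0.7 at n = 50 (200 replicates);
degenerate-#2 fidelity at n = 100; unit-root calibration at n = 200 with
1,000 seeds; causality directionality at n = 100 with 200 seeds; coefficient
recovery at n = 10,000 with 30 replicates, judged against three Monte-Carlo
standard errors of the replicate mean. The equation spec used in Monte-Carlo
runs is ARDL(2, 2, 2), which nests the generating processes while leaving the
short-run space non-trivial. Rank deficiency raises a collinearity error
naming the offending columns (QR with pivoting); zero-variance inputs raise
degenerate-data errors rather than NaNs.
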