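# Methods

This note documents the generative model, the statistical battery, the
numerical choices, and the limits of what the tests demonstrate.

## The generative model

Surveillance streams for region *r* on day *t* are driven by a latent
aeroallergen level

```
A_r(t) = Σ_k a_k exp(−d(doy(t), p_k)² / 2w_k²)  +  W_r(t)  +  u_r(t)
```

* **Seasonality** — a sum of Gaussian bumps in day-of-year, with circular
  distance `d` computed on a 365.25-day wrap so peaks near January 1
  behave correctly (winter allergy seasons exist). Default: a spring bump
  (day 90 + 4·r, amplitude 1, σ = 30 d — a two-month tree/grass season)
  and a fall bump (day 270 + 2·r, amplitude 0.4, σ = 20 d — a shorter
  ragweed season). The per-region drift in peak day gives the toy
  geography a timing gradient.
* **Trend** — `W_r` is a Gaussian random walk with per-day innovation sd
  `trend_sd = 0.02`, giving a 4-year drift of sd ≈ 0.76 latent units,
  comparable to the seasonal amplitude. The walk is shared across the
  three streams *within* a region — that is what makes them cointegrated —
  and is per-region by default (a single cross-region walk with per-region
  scaling is available for gradient demonstrations).
* **Anomaly** — `u_r` is AR(1) with φ = 0.7 and marginal sd 0.2,
  representing weather-driven day-to-day fluctuations in aeroallergen
  load. Because it too is shared across streams within a region, it is
  the main source of the residual (deseasonalized) correlations the
  validation battery measures; sd 0.2 against seasonal amplitude 1 yields
  residual correlations comfortably above 0.5 at metro-county volumes.

Observation (pop in units of 100,000; `wk` a day-of-week multiplier with
mean 1, default Mon–Fri 0.95 / Sat 1.10 / Sun 1.15):

```
ED_r(t)      ~ Poisson( pop_r · (b_E + c_E·A_r(t) + V_E,r(t))⁺ · wk(t) )
Total_r(t)   ~ Poisson( pop_r · b_P · wk(t) )
Allergy_r(t) ~ Binomial( Total_r(t), expit(logit(f₀) + c_P·A_r(t) + V_P,r(t)) )
Search_r(t)  = clip( expit(logit(s₀) + c_S·A_r(t) + V_S,r(t)) + U(−η, η), 0, 1 )
```

Defaults: `b_E = 0.6` ED visits per 100k/day and `f₀·b_P ≈ 0.6` allergy
posts per 100k/day (`b_P = 30`, `f₀ = 0.02`) — chosen so that a 4-year
window lands on the same per-100k scale as the 450 ED / 80 post inclusion
thresholds; couplings `c_E = 1.2`, `c_P = 0.8`, `c_S = 1.0`; `s₀ = 0.05`,
`η = 0.01`. The `V` terms are optional *independent* per-stream random
walks (`stream_walk_sd`, default 0); together with zero couplings they
produce the no-cointegration null (`null_config()`): three unrelated I(1)
streams.

Rates truncate at zero rather than passing through an exponential link, so
counts stay interpretable; relevant-post selection is Binomial thinning,
which enforces `Allergy ≤ Total` identically. All randomness flows from
one seed through keyed sub-streams per (purpose, region), so adding a
region never perturbs existing draws, and the post-text generator consumes
the *same* count sub-streams as the stream generator — aggregating the
emitted relevant posts reproduces the allergy-post series draw for draw.

The post generator emits first-person symptom templates (relevant) and
confounder templates that share the retrieval keywords (irrelevant:
expo announcements, a sneezing chicken, COVID-adjacent chatter) at a
Poisson rate calibrated so irrelevant posts make up the configured
contamination fraction (default 20%) of keyword-matching posts.

What the generator does **not** emulate: realistic linguistic variety
(templates are deliberately separable), demographic and platform biases,
real US geography (counties are rectangles), reporting delays, or
platform-volume drift. A classifier that is perfect here says nothing
about transformer-scale performance on real posts; what the tests *do*
show is that the pipeline's statistical battery behaves correctly when its
assumptions hold, and fails to find structure when it is absent.

## Processing rules

* **7-day moving average** — centered (±3 days), since the analysis is
  retrospective; a value requires ≥4 non-missing days in the window (the
  same rule covers the 3 edge days). A centered 7-term mean covers each
  weekday exactly once, so pure day-of-week patterns vanish identically on
  interior days.
* **Post probability** — allergy/total per day; a day with zero total
  posts is missing, not zero.
* **Quality rules** — a region enters validation/mapping only with
  population ≥ 500,000 and, over the full analysis window, ≥450
  allergy-coded ED encounters and ≥80 allergy posts per 100,000
  ("fewer than" excludes, so exact boundary values pass). Totals are
  normalized over the whole configured window; per-year normalization is
  a caller choice.
* **Timestamps** are binned by UTC calendar date; counts are never
  interpolated; exclusion windows (e.g. a pandemic year) blank values but
  keep the date index.

## The validation battery

Per region, on 7-day-smoothed streams:

1. **Canova–Hansen seasonal stability** per stream, on calendar-month
   aggregates with period 12. The test regresses the series on an
   intercept plus the full set of seasonal harmonics, cumulates the
   seasonal scores, and compares the normalized functional against the 5%
   point of the Cramér–von Mises distribution with period−1 degrees of
   freedom (critical values tabulated by Monte Carlo; the q ≤ 12 entries
   match the published table). Two deliberate choices:
   * *Bandwidth.* The Bartlett truncation for the long-run covariance is
     the period-independent `round(4·(n/100)^¼)`. The period-scaled rule
     found elsewhere absorbs the very instability signal being tested
     and leaves the test with little power at realistic sample sizes;
     the shorter bandwidth keeps size conservative and delivers full
     power in both Monte-Carlo scenarios the tests run.
   * *Aggregation.* Weekly aggregates with period 52 would need five full
     years under the test's own minimum-periods rule; month/12 works on
     the 4-year validation window. Both are configurable
     (`canova_hansen(series, period, min_periods)`).
2. **Engle–Granger**, both directions. Step 1: OLS of one smoothed series
   on the other with intercept. Step 2: ADF on the residuals with no
   deterministic term, AIC lag selection up to Schwert's rule, compared
   against MacKinnon two-variable cointegration critical values (the
   statistic and p-value match `statsmodels.tsa.stattools.coint` exactly;
   that equality is a test).
3. **Johansen trace** on the (ED, posts, search) triple, lag order 7
   (weekly dynamics in daily data), with the constant **restricted to the
   cointegrating relation**. This case matters: an unrestricted constant
   compares the final trace statistic against χ²-type critical values that
   presume the remaining common trend has drift. Surveillance streams are
   driftless, and under that misspecification the trace test over-rejects
   the last rank hypothesis badly even on an ideal shared-walk system.
   The restricted-constant case is implemented here via the reduced-rank
   regression, with 5% critical values (9.22 / 20.21 / 35.10 for 1–3
   common trends) matching the published restricted-constant table. The eigenvalue routine is
   cross-checked against statsmodels for the no-deterministic case.
4. **Dual residualization** — parametric: OLS on intercept, 11
   calendar-month dummies and a linear time index; nonparametric: STL
   remainder at period 365 with robust weighting (outer iterations capped
   at 5 — indistinguishable from 15 on year-scale series at a third of the
   cost). Interior gaps are linearly interpolated for STL and restored to
   missing afterwards. ADF on the remainders verifies stationarity.
5. **Zero-lag Pearson** on the raw (smoothed) pair and on both residual
   pairs; missing pairs dropped, ≥10 complete pairs required, zero
   variance reported as undefined rather than 0. P-values are reported
   per region with no multiplicity adjustment; the report is explicit
   about that.

## Monte-Carlo scenario choices

The power/size scenarios fix scale parameters that the statistics are
sensitive to; these are design choices made once:

* *Null size* uses 3M-population regions. In much smaller regions,
  Poisson/binomial noise so dominates the per-stream walks that the
  residual unit-root test sees near-white noise and spuriously "finds"
  cointegration well above nominal; raising the stream-walk sd instead
  trips the zero-truncation of the ED rate and distorts size the other
  way. At 3M the size test sits inside its band.
* *Parameter recovery* (amplitude rank order, peak dates) switches the
  latent trend (and, for peaks, the anomaly) off and uses 10M-population
  regions with a sharp σ = 10 d spring bump. With a per-region walk on,
  the deterministic amplitude/peak is not what the latent process
  realizes, so there is no identifiable truth to recover; and near the
  maximum of a wide bump the signal is locally flat, so count noise moves
  the argmax by far more than the recovery tolerance regardless of
  volume. The scenario isolates what
  it claims to measure: deterministic truth + observation noise.

## Mapping stage

Z-scores are computed **across regions** (maps compare counties), with the
sample standard deviation; within-region standardization is an option, not
the default. Seasonal means pool all days of a season across years.
Season windows: spring Mar 1–May 31, summer Jun 1–Aug 31, fall
Sep 1–Oct 31, winter Nov 1–Feb 28/29 (winter of year Y runs into year
Y+1). Peak detection runs on the 7-day-smoothed series, ties break to the
earliest day, and an all-missing window returns an explicit "undefined"
rather than a sentinel. The weekly matrix is the ISO-week mean of the raw
post probability, rows ordered north→south by region centroid by default.

## Degenerate inputs and determinism

Constant series, zero-variance regressors, exact collinearity, and
single-class training sets raise typed errors (`DegenerateInputError`)
rather than returning numbers. Points on a shared polygon edge are
assigned to the lexicographically smallest region id — determinism over
geometric fuzz. Every stochastic stage takes an explicit seed; the
pipeline splits one seed per stage and rerunning a config byte-identically
reproduces all outputs. File writers emit sorted keys and fixed float
formatting for the same reason.

## Known limitations

* Engle–Granger on 7-day-smoothed streams inherits an MA(7)-type residual
  structure; AIC lag selection absorbs most of it, but it nudges the
  empirical size at the 5% level upward within the acceptable band. Johansen lag
  order 7 is likewise tuned to daily data with weekly structure; other
  cadences need a different lag.
* The Canova–Hansen critical values are tabulated to 60 degrees of
  freedom; longer periods than 61 raise a configuration error.
* Johansen's restricted-constant case is the only in-house deterministic
  specification; unrestricted constant/trend delegate to statsmodels and
  carry that implementation's critical values.
* The probability streams assume the post denominator is observed. Days
  with zero total posts propagate as missing through every later stage;
  sparse regions therefore lose battery power before they are formally
  excluded by the quality rules — which is the operational reason the
  rules exist.
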