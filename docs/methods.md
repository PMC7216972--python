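# Methods

## The model

A subject can fail from the cause of interest (cause 1) or from a competing
cause (cause 2), at cause-specific hazard rates α₁(t|x) and α₂(t|x).  The
state-occupation probabilities are the event-free survival
S(t) = exp{−A₁(t)−A₂(t)} and the cumulative incidences
Fₖ(t) = ∫₀ᵗ αₖ(s) S(s) ds.  The *subdistribution hazard* of cause 1 is
λ(t) = −d log{1−F₁(t)}/dt; a proportional model on λ is the Fine–Gray
model, whose partial likelihood runs over *extended* risk sets that retain
subjects after a competing failure.

The package is organised around the **reduction factor**

    r(t) = λ(t)/α₁(t) = S(t) / {1 − F₁(t)},

the proportion of the extended risk set that is still truly at risk.  It
satisfies r(0) = 1, r ∈ (0,1], is non-increasing, and obeys

    −d log r(t)/dt = α₁(t){1 − r(t)} + α₂(t),

so near t = 0 it falls like a survival function with hazard α₂.  With
proportional covariate effects on both scales, the coefficients relate as
β_RF(t) = β_FG(t) − β_CS(t); in particular β_FG(0) = β₁ and
β_FG′(0) = α₂₀(0){1 − exp(β₂)}: the implied subdistribution coefficient
initially moves *opposite* in sign to the competing-cause effect, because a
harmful competing effect drains the level's extended risk set faster.
(Some accounts print this derivative with the opposite sign; the sign used
here follows from differentiating β₁ + log r(t|1) − log r(t|0) and matches
the qualitative behaviour of the computed curves.)

The central estimation identity: since α₁(t|x) = λ(t|x)/r(t|x), a
proportional subdistribution model λ₀(t)exp(β_FG x) can be fitted on the
*natural* cause-specific risk sets by maximising the cause-specific partial
likelihood with the time- and covariate-dependent offset −log r̂(t|x).  For
a categorical covariate with a saturated (per-level, per-event-time) r̂,
the offset-route maximiser is *identical* to the Fine–Gray maximiser —
algebraically, the per-level offset rescales each level's cause-specific
risk-set count into its weighted extended count.  The identity requires
r̂ > 0 wherever the extended risk set has mass; when a level is exhausted
from the cause-specific risk set while its past competing failures remain
in the extended set (virtually certain in *complete* data at the very last
event times, rare under end-of-study censoring with non-negligible
survival), the two estimators legitimately differ.

## Estimators

* **Reverse Kaplan–Meier** Ĝ(t) for the censoring distribution
  (lifelines' product-limit estimator with the censoring indicator as the
  event), right-continuous with left limits.
* **IPCW weights** on the cause-1 event-time grid: w = 1 while under
  observation, Ĝ(t)/Ĝ(T−) after a competing failure, 0 after censoring.
  Subjects censored at exactly t are treated as still usable at t (closed
  inequality in the at-risk definition).  Event times at which Ĝ = 0 are
  dropped from the grid with a warning.  Large samples avoid the dense
  (n × #event-times) weight matrix via sorted prefix sums.
* **Non-parametric r̂**: ratio of the (unit-weighted) cause-specific count
  to the IPCW-weighted extended count, overall or per covariate level; the
  per-time Poisson log-link GLM with a categorical covariate reproduces
  these ratios exactly (saturation).  Undefined points (empty weighted
  extended set) are NaN and never interpolated silently.
* **Partial likelihood engine**: Newton–Raphson with step-halving on the
  (weighted, offset) Cox partial likelihood; convergence at max|score| ≤
  1e−9 and relative log-likelihood change ≤ 1e−12, at most 50 iterations.
  |β| > 25 is flagged as monotone likelihood (separation).  The offset is
  re-evaluated per risk set at every event time (time-varying covariate
  mechanics).  Variances come from the inverse observed information; for
  the weighted Fine–Gray likelihood this is mildly anti-conservative and
  bootstrap standard errors are recommended.
* **Reduction-factor GLMs**: per-event-time Poisson (log link, the default
  — it tolerates fitted means above 1) or binomial (log/logit/cloglog)
  fits with IPCW case weights, risk sets treated as independent; or a
  pooled fit with a natural cubic spline in log t for the baseline
  (interior knots at the 0.25/0.5/0.75 quantiles of the event times) and
  optional covariate-by-time interactions.  The constraint β_RF(0) = 0 is
  *not* enforced in pooled fits.  Non-converged per-time fits are flagged
  NaN.

## Cumulative incidence, four ways

1. *Multistate*: plug-in sum Σ α̂₁(s|x*) exp{−Â₁(s|x*)−Â₂(s|x*)} over
   pooled event times.  This exponential form does not conserve
   Ŝ+F̂₁+F̂₂ = 1 exactly; a product-limit (Aalen–Johansen) variant that
   does — and that reproduces the non-parametric Aalen–Johansen estimator
   at β = 0 — is available via `variant="product-limit"`.  The default
   follows the plug-in formula.
2. *Subdistribution through r*: λ̂ = r̂·α̂₁ accumulated into 1−exp(−Σλ̂).
3. *Fine–Gray*: weighted Breslow baseline λ̂₀ = 1/Σ Y_FG w exp(β̂x)
   accumulated the same way.
4. *Fine–Gray via offset*: the Breslow baseline of the offset fit already
   embeds r̂; with a saturated categorical r̂ methods 3 and 4 give the same
   coefficients (≤1e−6) and the same curves (≤1e−8).

Bootstrap standard errors resample subjects with replacement and refit the
whole pipeline — including Ĝ and the reduction factor — per replicate
("refit" mode); "fixed-rf" keeps the original r̂ to mimic analyses that
ignore its sampling uncertainty.  Replicates are re-jittered when
resampling duplicates event times; failed replicates are dropped, more
than 10% failures is an error.

## Numerical choices

* Hazards with Weibull shape b < 1 diverge at t = 0.  Point evaluations use
  max(t, 1e−6); cumulative hazards use the exact closed form a·t^b.
* CIF quadrature: each grid interval (default 2001 points on [0, 2.5]) is
  subdivided in u = √t; the increment is π₁(midpoint)·ΔS with π₁ =
  α₁/(α₁+α₂) the instantaneous cause ratio and ΔS the exact survival drop.
  Conservation S+F₁+F₂ = 1 then holds to machine precision and the
  √t-substitution keeps the midpoint rule accurate for shapes ≥ ½.
* The reduction-factor ODE is integrated for log r (positivity) with
  classical fixed-step RK4, also in u = √t (the Weibull terms
  2u·αₖ(u²) = 2aₖbₖu^{2bₖ−1} stay bounded at the origin for shapes ≥ ½),
  4 substeps per grid interval.  The ratio and ODE routes agree to ≲5e−7
  sup-norm over all nine early/middle/late pairs.
* Tie-breaking jitters *every* duplicated time value (events and
  censorings: event–censoring ties are equally convention-sensitive) by
  uniform noise smaller than half the minimal positive gap, preserving the
  order of non-tied observations; seeded and reproducible.
* All estimators refuse tied data rather than applying tie corrections.

## Simulator: what it emulates, and what it does not

`simulate_competing_risks` draws from two Weibull cause-specific hazards
with proportional effects of one binary covariate (success probability
p = 0.5 by default, the standard design here): total event time by
inversion of A₁+A₂ (closed form at equal shapes, Brent root-finding
otherwise), cause 1 assigned with probability α₁/(α₁+α₂) at the drawn
time, then independent censoring.  Censoring options: none, administrative
at a horizon, uniform, exponential, or uniform-plus-horizon (staggered
entry into a fixed-duration study).  One seeded generator with a fixed
draw order makes datasets bitwise-reproducible.

`simulate_subdistribution` is the complementary test utility with an
*exactly* proportional subdistribution hazard, via the classical mixture
F₁(t|x) = 1 − {1 − p(1−e^(−t))}^{exp(β_FG x)} and an exponential
competing-event time.

The generator emulates independent censoring, a single binary covariate
and smooth parametric hazards.  It does not emulate covariate-dependent
censoring, tied recording of times, multi-level or continuous covariate
structure, or non-proportional covariate effects — so passing tests show
correctness of the estimators under the stated sampling laws, not
robustness to those violations.  Default study conditions used in tests:
rates calibrated to S(2.5) = 0.05 (1.895, 1.198, 0.479 for shapes 0.5, 1,
2), β₁ = 0.5, β₂ = 0.25; uniform censoring on [0, 1.1] yields ≈30%
censoring for the middle/middle pair (calibrated in closed form as
E[(1−e^{−λ(x)c})/(λ(x)c)]); the offset-equivalence checks use an
end-of-study horizon at τ = 0.6 (with or without additional uniform
censoring on [0, 1.8]) so that every covariate level keeps event-free mass
through the last event time, which is the regime in which the saturated
offset identity is defined.  Replication counts (50 at n = 2000 for
coefficient recovery; 120 bootstrap replicates vs 150 Monte-Carlo datasets
at n = 300 for the bootstrap calibration) are the package's chosen
simulation sizes.

## Design notes and limitations

* The EBMT chronic-myeloid-leukemia demo (`redfac.datasets.load_ebmt1`)
  shells out to R's mstate package at call time; nothing is bundled.  The
  adult cohort (n = 1835; 421 relapses, 641 non-relapse deaths, 773
  censored) reproduces the published cause-specific and Fine–Gray
  coefficients to ~3 decimals after seeded tie-breaking; exact third-decimal
  agreement depends on the (unspecified) jitter used in the original
  analysis.
* The binary-covariate design mean p is recorded on `TwoCauseModel`
  (`covariate_mean`) but unused: the implied β_FG(t) is a conditional
  contrast between covariate levels and does not involve p.  It is kept
  for a possible least-false time-constant summary, which is out of scope.
* Closed-form standard errors for the four CIF estimators are not
  implemented; the bootstrap substitutes.  Confidence bands, dynamic /
  landmark conditional incidence F₁(t|s), covariate-dependent censoring
  models Ĝ(t|x), and tie-correction formulas are out of scope.
* GLM "GEE" fits use working independence; sandwich variances are
  available through the underlying statsmodels results where needed, other
  working correlations are not implemented.
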