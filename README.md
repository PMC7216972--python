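# redfac

Competing-risks regression built around the **reduction factor**

    r(t | x) = λ(t | x) / α₁(t | x) = S(t | x) / {1 − F₁(t | x)},

the proportion of the extended (Fine–Gray) risk set that is still truly at
risk.  The reduction factor links the two standard ways of modelling a
cause of interest in the presence of competing events — proportional
cause-specific hazards α₁(t|x) = α₁₀(t)exp(β_CS x) and the proportional
subdistribution-hazards (Fine–Gray) model λ(t|x) = λ₀(t)exp(β_FG x) — via
β_RF(t) = β_FG(t) − β_CS(t).  It also makes the Fine–Gray estimator itself
less mysterious: maximising the cause-specific partial likelihood on
*natural* risk sets with the offset −log r̂(t|x) reproduces the Fine–Gray
coefficient exactly when r̂ is saturated over a categorical covariate.

The package is aimed at biostatisticians analysing right-censored
competing-risks data (e.g. relapse with death as competing risk) who want
to estimate, model and exploit r(t|x).  It provides:

* **theory** — S, F₁, F₂, r(t), λ(t) and the implied time-varying
  coefficient β_FG(t) under Weibull cause-specific hazards, by closed-form
  survival + quadrature and, independently, by solving
  −d log r/dt = α₁(1−r) + α₂;
* **nonparametric** — reverse Kaplan–Meier censoring distribution, IPCW
  weights, cause-specific and subdistribution Nelson–Aalen increments, and
  r̂ overall / per covariate level / censoring-weighted;
* **regression** — a Newton partial-likelihood engine with per-risk-set
  offsets and weights behind statsmodels-style models:
  `CauseSpecificCox`, `FineGrayModel`, `fit_fine_gray_via_offset`, and
  `ReductionFactorGLM` (per-event-time or pooled-spline GLMs for r(t|x));
* **cif** — four covariate-conditional cumulative-incidence estimators
  (multistate, subdistribution-through-r, Fine–Gray, Fine–Gray-via-offset)
  with subject-resampling bootstrap standard errors;
* **simulate** — a seeded Weibull competing-risks generator and an
  exactly-proportional-subdistribution test generator;
* a `redfac` command-line interface (`simulate`, `curves`, `fit`, `cif`,
  `illustrate`).

## Worked example

```python
import redfac as rf

# middle-risk (constant) hazards calibrated so S(2.5) = 0.05
a = rf.solve_rate_for_survival(shape=1.0, horizon=2.5, survival=0.05)  # 1.198
model = rf.TwoCauseModel(rf.WeibullHazard(a, 1.0), rf.WeibullHazard(a, 1.0),
                         beta1=0.5, beta2=0.25)
data = rf.simulate_competing_risks(rf.SimulationDesign(
    n=2000, model=model, covariate_p=0.5, censoring=("uniform", 1.1), seed=7))
print(data)

csh = rf.CauseSpecificCox(data, ["x"]).fit()
fg = rf.FineGrayModel(data, ["x"]).fit()
print(csh.summary().round(3))
print(fg.summary().round(3))

weights = rf.ipcw_weights(data)
sat = rf.reduction_factor_np(data, by="x", weights=weights)
off = rf.fit_fine_gray_via_offset(data, ["x"], sat)
print(f"Fine-Gray vs offset route: {abs(fg.params['x'] - off.params['x']):.2e}")

curve = rf.cif_fine_gray(fg, {"x": 1.0})
print(f"F1(0.5 | x=1) = {curve(0.5):.3f}")

bfg = rf.beta_fg_curve(model, rf.default_grid(1.5, 301))
print(f"beta_FG(0) = {bfg[0]:.3f}, beta_FG(1.5) = {bfg[-1]:.3f}")
```

Output:

```
CompetingRisksData(n=2000, events1=784, events2=659, censored=557, covariates=['x'])
    coef  se(coef)      z    p  [0.025  0.975]
x  0.496     0.072  6.869  0.0   0.355   0.638
    coef  se(coef)      z    p  [0.025  0.975]
x  0.372     0.072  5.165  0.0   0.231   0.513
Fine-Gray vs offset route: 8.72e-15
F1(0.5 | x=1) = 0.478
beta_FG(0) = 0.500, beta_FG(1.5) = -1.023
```

Reading this: the cause-specific fit recovers the simulated β₁ = 0.5
(0.496 ± 0.072).  The Fine–Gray coefficient is smaller (0.372) even though
the covariate *raises* the cause-1 hazard — the same covariate also raises
the competing hazard (β₂ = 0.25), which drains the extended risk set for
x = 1 faster; this is exactly what β_FG(t) = β₁ + log r(t|1) − log r(t|0)
quantifies, starting at β₁ = 0.5 at t = 0 and falling over follow-up.  The
offset-route estimate agrees with the Fine–Gray maximiser to machine
precision (saturated categorical r̂), and the fitted cumulative incidence
for x = 1 at t = 0.5 is 47.8%.

The same pipeline runs from the shell:

```sh
redfac simulate --design design.json --out data.csv
redfac fit --data data.csv --covars x --model fg --out fit.json
redfac cif --data data.csv --covars x --method fine-gray \
       --profile profile.json --boot 200 --seed 7 --out cif.csv
redfac illustrate --data cohort.csv --group score --age age --out-dir results/
```

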