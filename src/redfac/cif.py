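"""Covariate-conditional cumulative incidence by four routes.

Given fitted hazard models, the cumulative incidence of the cause of
interest for a covariate profile x* can be assembled in four ways:

1. **multistate** — proportional cause-specific hazards for both causes;
   plug the Breslow baselines into the competing-risks identity
   F̂₁(t|x*) = Σ_{s≤t} α̂₁(s|x*)·Ŝ(s|x*).
2. **subdist-rf** — cause-specific hazard for cause 1 times an estimated
   reduction factor: λ̂ = r̂·α̂₁, then F̂₁ = 1 − exp(−Σλ̂).
3. **fine-gray** — the proportional subdistribution-hazards fit with its
   weighted Breslow baseline.
4. **fg-offset** — the Fine–Gray coefficient estimated on natural risk sets
   with offset −log r̂(t|x); the baseline of that fit already embeds the
   reduction factor.

Methods 3 and 4 coincide (coefficients and curves) when the reduction
factor is saturated over a categorical covariate; all four coincide when
there is neither censoring nor competing events.  Pointwise standard errors
come from subject-level bootstrap resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CompetingRisksData
from .nonparametric import (
    OVERALL,
    ReductionFactorEstimate,
    ipcw_weights,
    reduction_factor_np,
)
from .regression import (
    CauseSpecificCox,
    CoxResults,
    FineGrayModel,
    ReductionFactorGLMResults,
    fit_fine_gray_via_offset,
)

__all__ = [
    "CifEstimate",
    "cif_multistate",
    "cif_subdist_via_rf",
    "cif_fine_gray",
    "cif_fg_offset",
    "bootstrap_se",
    "METHODS",
]

METHODS = ("multistate", "subdist-rf", "fine-gray", "fg-offset")


@dataclass
class CifEstimate:
    """A non-decreasing step curve F̂₁(t|x*) on an event-time grid."""

    times: np.ndarray
    values: np.ndarray
    method: str
    profile: dict = field(default_factory=dict)
    se: np.ndarray | None = None

    def __call__(self, t):
        """Right-continuous step evaluation; 0 before the first event time."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        out = np.where(idx < 0, 0.0, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.times, "F1": self.values, "method": self.method}
        if self.se is not None:
            d["se"] = self.se
        return pd.DataFrame(d)


def _linpred(res: CoxResults, profile: dict) -> float:
    missing = set(res.params.index) - set(profile)
    if missing:
        raise ValueError(f"profile missing covariates {sorted(missing)}")
    return res.linear_predictor({k: profile[k] for k in res.params.index})


def cif_multistate(res1: CoxResults, res2: CoxResults, profile: dict,
                   variant: str = "exponential") -> CifEstimate:
    """Cumulative incidence from both cause-specific hazard fits.

    ``variant="exponential"`` evaluates survival inside the sum as
    exp(−Â₁−Â₂) with the cumulative hazards summed up to and including the
    current event time; it does not conserve S+F₁+F₂=1 exactly.
    ``variant="product-limit"`` uses the Aalen–Johansen discrete product
    Ŝ(s−)=Π_{u<s}(1−α̂₁−α̂₂), which conserves exactly and reproduces the
    non-parametric Aalen–Johansen estimator when both fits have no
    covariate effect.
    """
    m1, m2 = res1.model, res2.model
    if m1 is None or m2 is None or m1.data is not m2.data:
        if m1 is None or m2 is None or not (
            len(m1.data.time) == len(m2.data.time)
            and np.array_equal(m1.data.time, m2.data.time)
            and np.array_equal(m1.data.status, m2.data.status)
        ):
            raise ValueError("the two cause-specific fits must come from the same data")
    t1, t2 = res1.event_times, res2.event_times
    pooled = np.union1d(t1, t2)
    a1 = np.zeros_like(pooled)
    a2 = np.zeros_like(pooled)
    a1[np.searchsorted(pooled, t1)] = res1.baseline.increments * np.exp(_linpred(res1, profile))
    a2[np.searchsorted(pooled, t2)] = res2.baseline.increments * np.exp(_linpred(res2, profile))
    if variant == "exponential":
        surv = np.exp(-(np.cumsum(a1) + np.cumsum(a2)))
        F1 = np.cumsum(a1 * surv)
    elif variant == "product-limit":
        surv_before = np.concatenate([[1.0], np.cumprod(1.0 - a1 - a2)[:-1]])
        F1 = np.cumsum(a1 * surv_before)
    else:
        raise ValueError("variant must be 'exponential' or 'product-limit'")
    return CifEstimate(pooled, np.clip(F1, 0.0, 1.0), "multistate", dict(profile))


def _rf_values(rf, times, profile: dict, carry_forward: bool) -> np.ndarray:
    """r̂(t|x*) on the given times from a saturated estimate or a GLM fit."""
    if isinstance(rf, ReductionFactorEstimate):
        if rf.by is None:
            vals = np.asarray(rf.at(times, OVERALL), dtype=float)
        else:
            if rf.by not in profile:
                raise ValueError(f"profile must specify the level of {rf.by!r}")
            vals = np.asarray(rf.at(times, profile[rf.by]), dtype=float)
        # before the first event time the reduction factor is 1 by definition
        vals = np.where(times < rf.event_times[0], 1.0, vals)
    elif isinstance(rf, ReductionFactorGLMResults):
        names = rf.model.covariate_names
        missing = set(names) - set(profile)
        if missing:
            raise ValueError(f"profile missing reduction-factor covariates {sorted(missing)}")
        X = np.array([[profile[k] for k in names]], dtype=float)
        vals = rf.predict_r(times, X)[0]
    else:
        raise TypeError("rf must be a ReductionFactorEstimate or ReductionFactorGLMResults")
    if np.any(~np.isfinite(vals)):
        if not carry_forward:
            raise ValueError(
                "reduction factor undefined (flagged) at some event times; "
                "pass carry_forward=True to reuse the last defined value"
            )
        vals = pd.Series(vals).ffill().fillna(1.0).to_numpy()
    return vals


def cif_subdist_via_rf(res1: CoxResults, rf, profile: dict,
                       carry_forward: bool = False) -> CifEstimate:
    """Cumulative incidence from λ̂(t|x*) = r̂(t|x*)·α̂₁(t|x*).

    ``res1`` is the cause-specific fit for the cause of interest; ``rf`` a
    saturated reduction-factor estimate or a fitted reduction-factor GLM.
    """
    times = res1.event_times
    a1 = res1.baseline.increments * np.exp(_linpred(res1, profile))
    r = _rf_values(rf, times, profile, carry_forward)
    lam = r * a1
    F1 = 1.0 - np.exp(-np.cumsum(lam))
    return CifEstimate(times, F1, "subdist-rf", dict(profile))


def cif_fine_gray(fg_res: CoxResults, profile: dict) -> CifEstimate:
    """Cumulative incidence from the weighted Fine–Gray fit,
    F̂₁(t|x*) = 1 − exp(−Σ_{t*≤t} λ̂₀(t*) exp(β̂ x*))."""
    lam = fg_res.baseline.increments * np.exp(_linpred(fg_res, profile))
    F1 = 1.0 - np.exp(-np.cumsum(lam))
    return CifEstimate(fg_res.event_times, F1, "fine-gray", dict(profile))


def cif_fg_offset(offset_res: CoxResults, rf=None, profile: dict | None = None) -> CifEstimate:
    """Cumulative incidence from the offset-route Fine–Gray fit.

    The subdistribution hazard is exp(β̃x*) / Σ_{k∈R_CS(t*)} exp(β̃x_k +
    o(t*, x_k)) with o = −log r̂ — exactly the Breslow baseline of the
    offset fit scaled by exp(β̃x*).  The reduction factor used in fitting is
    already embedded in that baseline; ``rf`` is accepted for interface
    symmetry and must be the one the model was fitted with.
    """
    if profile is None:
        raise ValueError("profile is required")
    model = offset_res.model
    if model is None or getattr(model, "offset", None) is None:
        raise ValueError("offset_res must come from a fit with a reduction-factor offset")
    lam = offset_res.baseline.increments * np.exp(_linpred(offset_res, profile))
    F1 = 1.0 - np.exp(-np.cumsum(lam))
    return CifEstimate(offset_res.event_times, F1, "fg-offset", dict(profile))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _pipeline(method: str, covariates, by: str | None, cause: int,
              profile: dict, carry_forward: bool, fixed_rf=None):
    """Build data -> CifEstimate for one of the four methods."""

    def run(data: CompetingRisksData) -> CifEstimate:
        if method == "multistate":
            r1 = CauseSpecificCox(data, covariates, cause=cause).fit()
            r2 = CauseSpecificCox(data, covariates,
                                  cause=(2 if cause == 1 else 1)).fit()
            return cif_multistate(r1, r2, profile)
        if method == "subdist-rf":
            r1 = CauseSpecificCox(data, covariates, cause=cause).fit()
            rf = fixed_rf if fixed_rf is not None else reduction_factor_np(
                data, by=by, weights=ipcw_weights(data, cause=cause), cause=cause)
            return cif_subdist_via_rf(r1, rf, profile, carry_forward)
        if method == "fine-gray":
            fg = FineGrayModel(data, covariates, cause=cause).fit()
            return cif_fine_gray(fg, profile)
        if method == "fg-offset":
            rf = fixed_rf if fixed_rf is not None else reduction_factor_np(
                data, by=by, weights=ipcw_weights(data, cause=cause), cause=cause)
            res = fit_fine_gray_via_offset(data, covariates, rf, cause=cause)
            return cif_fg_offset(res, rf, profile)
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")

    return run


def bootstrap_se(method, data: CompetingRisksData, profile: dict, B: int,
                 seed: int, grid, covariates=None, by: str | None = None,
                 cause: int = 1, mode: str = "refit",
                 carry_forward: bool = True, max_fail_frac: float = 0.10):
    """Pointwise bootstrap standard errors for a cumulative incidence curve.

    Subjects are resampled with replacement; the full pipeline — censoring
    distribution, weights, reduction factor, partial likelihood — is refit
    in every replicate (``mode="refit"``).  ``mode="fixed-rf"`` keeps the
    reduction factor from the original data, mimicking analyses that ignore
    its sampling uncertainty.  ``method`` may also be a callable
    ``data -> CifEstimate`` for custom pipelines.

    Returns the array of pointwise standard deviations on ``grid``.
    Replicates whose fits fail are dropped; more than ``max_fail_frac``
    failures raise.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    grid = np.asarray(grid, dtype=float)
    if callable(method):
        run = method
    else:
        fixed_rf = None
        if mode == "fixed-rf" and method in ("subdist-rf", "fg-offset"):
            fixed_rf = reduction_factor_np(
                data, by=by, weights=ipcw_weights(data, cause=cause), cause=cause)
        run = _pipeline(method, covariates, by, cause, profile,
                        carry_forward, fixed_rf=fixed_rf)
    rng = np.random.default_rng(seed)
    curves, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            boot = data.subset(idx)
            boot.require_tie_free()  # resampling duplicates event times
        except ValueError:
            from .data import break_ties
            boot = break_ties(data.subset(idx), seed=int(rng.integers(2**31)))
        try:
            curves.append(run(boot)(grid))
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_fail_frac * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    return np.std(np.vstack(curves), axis=0, ddof=1)
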