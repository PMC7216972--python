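"""Non-parametric estimation of hazards, censoring weights and the reduction factor.

All estimators live on the grid ``D1`` of observed event times of the cause
of interest.  At an event time t*, the cause-specific risk set contains the
subjects with ``T_i ≥ t*`` while the extended (Fine–Gray) risk set keeps, in
addition, subjects who already failed from the competing cause.  Censoring is
handled by inverse-probability-of-censoring weights built from the reverse
Kaplan–Meier estimate Ĝ of the censoring distribution: subjects still under
observation get weight 1, a subject with a competing event at T_i < t* gets
Ĝ(t*)/Ĝ(T_i−), and a subject censored before t* gets weight 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import CompetingRisksData, StepFunction

__all__ = [
    "reverse_km",
    "ipcw_weights",
    "WeightMatrix",
    "nelson_aalen_cs",
    "subdist_hazard_np",
    "reduction_factor_np",
    "ReductionFactorEstimate",
]

OVERALL = "overall"


def reverse_km(data: CompetingRisksData) -> StepFunction:
    """Reverse Kaplan–Meier estimate Ĝ(t) = P(C > t) of the censoring distribution.

    Censorings play the role of events and true events the role of
    censorings; Ĝ(0) = 1.  Returned as a right-continuous step function
    supporting left limits (needed for Ĝ(T−)).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=(data.status == 0))
    sf = kmf.survival_function_.iloc[:, 0]
    knots = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)
    keep = knots > 0
    return StepFunction(knots[keep], vals[keep], left_value=1.0)


class WeightMatrix:
    """IPCW weights w_i(t*_j), one row per subject, one column per event time.

    The dense (n, m) array is materialised lazily through ``.weights`` —
    partial-likelihood fits need it, but the ratio estimators work from the
    censoring distribution and sorted prefix sums, which keeps very large
    samples affordable.
    """

    def __init__(self, event_times, weights=None, *, G: StepFunction | None = None,
                 time=None, status=None, cause: int = 1):
        self.event_times = np.asarray(event_times, dtype=float)
        self._dense = weights
        self.G = G
        self._time = time
        self._status = status
        self.cause = cause

    @property
    def structured(self) -> bool:
        """True when Ĝ and the data view are available for the fast path."""
        return self.G is not None and self._time is not None

    @property
    def weights(self) -> np.ndarray:
        if self._dense is None:
            self._dense = self._materialise()
        return self._dense

    def _materialise(self) -> np.ndarray:
        t, s = self._time, self._status
        Gt = np.asarray(self.G(self.event_times), dtype=float)
        at_risk = t[:, None] >= self.event_times[None, :]
        w = np.where(at_risk, 1.0, 0.0)
        comp = (s != 0) & (s != self.cause)
        if comp.any():
            Gminus = np.asarray(self.G.left_limit(t[comp]), dtype=float)
            past = ~at_risk[comp]
            ratio = Gt[None, :] / Gminus[:, None]
            w[comp] = np.where(past, ratio, 1.0)
        return w

    def column(self, j: int) -> np.ndarray:
        return self.weights[:, j]

    def fg_denominator(self, mask=None) -> np.ndarray:
        """Σ_i Y_FG,i(t*_j)·w_i(t*_j) over subjects in ``mask`` without
        materialising the dense matrix: at-risk counts plus
        Ĝ(t*)·Σ_{past competing} 1/Ĝ(T_i−)."""
        t, s = self._time, self._status
        if mask is None:
            mask = np.ones(len(t), dtype=bool)
        tm = t[mask]
        at_risk = len(tm) - np.searchsorted(np.sort(tm), self.event_times, side="left")
        comp = mask & (s != 0) & (s != self.cause)
        tc = t[comp]
        order = np.argsort(tc)
        inv = 1.0 / np.asarray(self.G.left_limit(tc[order]), dtype=float)
        prefix = np.concatenate([[0.0], np.cumsum(inv)])
        k = np.searchsorted(tc[order], self.event_times, side="left")
        Gt = np.asarray(self.G(self.event_times), dtype=float)
        return at_risk + Gt * prefix[k]

    def cs_count(self, mask=None) -> np.ndarray:
        """#{T_i ≥ t*_j} over subjects in ``mask`` (numerator weights are 1)."""
        t = self._time if mask is None else self._time[mask]
        return (len(t) - np.searchsorted(np.sort(t), self.event_times,
                                         side="left")).astype(float)


def ipcw_weights(data: CompetingRisksData, G: StepFunction | None = None,
                 event_times=None, cause: int = 1) -> WeightMatrix:
    """Time-dependent censoring weights on the cause-1 event-time grid.

    ``w_i(t) = 1`` while subject i is still under observation (T_i ≥ t),
    ``Ĝ(t)/Ĝ(T_i−)`` after a competing event at T_i < t, and 0 after a
    censoring.  With no censoring in the data every weight is 0 or 1 and the
    matrix degenerates to Fine–Gray risk-set membership.
    """
    if G is None:
        G = reverse_km(data)
    if event_times is None:
        event_times = data.event_times(cause)
    event_times = np.asarray(event_times, dtype=float)
    Gt = np.asarray(G(event_times), dtype=float)

    usable = Gt > 0
    if not np.all(usable):
        warnings.warn(
            "censoring distribution hits 0 before some cause-1 event times; "
            "those event times are dropped from the estimation grid",
            stacklevel=2,
        )
        event_times = event_times[usable]

    comp = (data.status != 0) & (data.status != cause)
    if comp.any():
        Gminus = np.asarray(G.left_limit(data.time[comp]), dtype=float)
        if np.any(Gminus <= 0):
            raise ZeroDivisionError(
                "degenerate censoring tail: Ĝ(T−) = 0 at a competing event time"
            )
    return WeightMatrix(event_times, G=G, time=data.time, status=data.status,
                        cause=cause)


def nelson_aalen_cs(data: CompetingRisksData, cause: int) -> StepFunction:
    """Cause-specific Nelson–Aalen increments 1/#{T_i ≥ t*} at the cause's event times.

    The returned step function is the cumulative hazard; the per-time
    increments are available as ``.increments``.
    """
    data.require_tie_free()
    times = data.event_times(cause)
    at_risk = np.sum(data.time[:, None] >= times[None, :], axis=0)
    return StepFunction.from_increments(times, 1.0 / at_risk)


def subdist_hazard_np(data: CompetingRisksData,
                      weights: WeightMatrix | None = None,
                      cause: int = 1) -> StepFunction:
    """Weighted Nelson–Aalen-type increments 1/Σ_i Y_FG,i(t*) w_i(t*) for the
    subdistribution hazard of cause 1.

    Without censoring the denominator is the size of the extended risk set.
    Equals (reduction factor) × (cause-specific increment) pointwise.
    """
    data.require_tie_free()
    if weights is None:
        _require_uncensored(data)
        weights = ipcw_weights(data, cause=cause)
    times = weights.event_times
    if weights.structured:
        denom = weights.fg_denominator()
    else:
        comp = (data.status != 0) & (data.status != cause)
        fg = (data.time[:, None] >= times[None, :]) | comp[:, None]
        denom = np.sum(fg * weights.weights, axis=0)
    if np.any(denom <= 0):
        raise ZeroDivisionError("empty weighted Fine–Gray risk set")
    return StepFunction.from_increments(times, 1.0 / denom)


@dataclass
class ReductionFactorEstimate:
    """Non-parametric r̂ on the cause-1 event-time grid, per covariate level.

    ``values`` has one column per level (label "overall" when unstratified);
    entries are NaN where the weighted extended risk set for that level is
    empty.
    """

    event_times: np.ndarray
    levels: list
    values: pd.DataFrame  # index = event_times, columns = levels
    by: str | None = None

    def at(self, t, level=OVERALL) -> np.ndarray:
        """Right-continuous lookup r̂(t | level); NaN before the first event time."""
        col = self.values[level].to_numpy()
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right") - 1
        out = np.where(idx < 0, np.nan, col[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        long = self.values.reset_index(names="time").melt(
            id_vars="time", var_name="level", value_name="value")
        return long.sort_values(["time", "level"]).reset_index(drop=True)


def _require_uncensored(data):
    if np.any(data.status == 0):
        raise ValueError(
            "data contain censored observations; supply IPCW weights "
            "(redfac.ipcw_weights) for the weighted estimator"
        )


def reduction_factor_np(data: CompetingRisksData, by: str | None = None,
                        weights: WeightMatrix | None = None,
                        cause: int = 1) -> ReductionFactorEstimate:
    """Empirical reduction factor r̂(t*) = Σ Y_CS w / Σ Y_FG w, optionally per level.

    ``by`` names a categorical covariate column: the saturated estimator
    computes one ratio per level at each cause-1 event time.  Without
    ``weights`` the data must be censoring-free (the ratio of risk-set sizes);
    with weights the denominator adds Ĝ(t*)/Ĝ(T_i−) for each past competing
    event, the numerator weights being identically 1.
    """
    data.require_tie_free()
    if weights is None:
        _require_uncensored(data)
        weights = ipcw_weights(data, cause=cause)
    times = weights.event_times
    structured = weights.structured
    if not structured:
        cs = data.time[:, None] >= times[None, :]
        comp = (data.status != 0) & (data.status != cause)
        fg_w = (cs | comp[:, None]) * weights.weights

    if by is None:
        groups = {OVERALL: np.ones(data.n, dtype=bool)}
    else:
        col = data.frame[by]
        groups = {lev: (col == lev).to_numpy() for lev in sorted(col.unique())}
    cols = {}
    for lev, mask in groups.items():
        if not mask.any():
            raise ValueError(f"empty covariate level {lev!r}")
        if structured:
            num = weights.cs_count(mask)
            den = weights.fg_denominator(mask)
        else:
            num = cs[mask].sum(axis=0).astype(float)
            den = fg_w[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[lev] = np.where(den > 0, num / den, np.nan)
    values = pd.DataFrame(cols, index=pd.Index(times, name="time"))
    return ReductionFactorEstimate(times, list(values.columns), values, by=by)
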