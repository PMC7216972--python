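"""Subject-level competing-risks data and step-function plumbing.

The universal input is one row per subject: a positive follow-up time, a
status code (0 = censored, 1 = event of interest, 2 = competing event) and
any number of numeric covariate columns.  All estimators in this package
assume tie-free event times; :func:`break_ties` produces a tie-free copy by
seeded jitter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CompetingRisksData",
    "StepFunction",
    "break_ties",
    "read_competing_risks",
    "write_competing_risks",
]

_VALID_STATUS = (0, 1, 2)


class CompetingRisksData:
    """Right-censored competing-risks sample.

    Parameters
    ----------
    frame : pandas.DataFrame
        Must contain columns ``time`` and ``status`` plus covariate columns.
        ``status`` uses the fixed internal coding 0/1/2 (censored / cause of
        interest / competing cause).  Use :func:`read_competing_risks` to map
        other codings or column names.
    """

    def __init__(self, frame: pd.DataFrame):
        if "time" not in frame.columns or "status" not in frame.columns:
            raise ValueError("frame must have 'time' and 'status' columns")
        if len(frame) == 0:
            raise ValueError("empty competing-risks data")
        frame = frame.reset_index(drop=True)
        time = frame["time"].to_numpy(dtype=float)
        status = frame["status"].to_numpy()
        if np.any(~np.isin(status, _VALID_STATUS)):
            bad = int(np.flatnonzero(~np.isin(status, _VALID_STATUS))[0])
            raise ValueError(
                f"unknown status code {frame['status'].iloc[bad]} in row {bad}; "
                "expected 0 (censored), 1 (cause of interest) or 2 (competing)"
            )
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all follow-up times must be positive and finite")
        covs = [c for c in frame.columns if c not in ("time", "status")]
        if frame[covs].isna().any().any() or frame[["time", "status"]].isna().any().any():
            raise ValueError("missing values are not allowed")
        self.frame = frame
        self.time = time
        self.status = status.astype(int)
        self.covariate_names = covs

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    def covariates(self, names) -> np.ndarray:
        """Covariate matrix (n, p) for the given column names."""
        names = [names] if isinstance(names, str) else list(names)
        missing = [c for c in names if c not in self.frame.columns]
        if missing:
            raise KeyError(f"covariate column(s) not found: {missing}")
        return self.frame[names].to_numpy(dtype=float)

    def event_times(self, cause: int) -> np.ndarray:
        """Sorted distinct observed event times of the given cause."""
        t = np.sort(self.time[self.status == cause])
        return t

    @property
    def is_tie_free(self) -> bool:
        """True when event times (status 1 or 2) are pairwise distinct."""
        t = self.time[self.status > 0]
        return len(np.unique(t)) == len(t)

    def require_tie_free(self) -> None:
        if not self.is_tie_free:
            raise ValueError(
                "tied event times present; apply redfac.break_ties first"
            )

    def subset(self, idx) -> "CompetingRisksData":
        return CompetingRisksData(self.frame.iloc[np.asarray(idx)].reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = np.bincount(self.status, minlength=3)
        return (
            f"CompetingRisksData(n={self.n}, events1={c[1]}, events2={c[2]}, "
            f"censored={c[0]}, covariates={self.covariate_names})"
        )


class StepFunction:
    """Right-continuous piecewise-constant function with left limits.

    ``f(t) = left_value`` for ``t < knots[0]`` and ``f(t) = values[j]`` for
    ``knots[j] <= t < knots[j+1]``.  Used for the censoring distribution
    Ĝ(t), cumulative hazards and reduction-factor curves.
    """

    def __init__(self, knots, values, left_value: float = 1.0, increments=None):
        knots = np.asarray(knots, dtype=float)
        values = np.asarray(values, dtype=float)
        if knots.ndim != 1 or knots.shape != values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if len(knots) > 1 and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        self.values = values
        self.left_value = float(left_value)
        self.increments = None if increments is None else np.asarray(increments, float)

    @classmethod
    def from_increments(cls, times, increments, start: float = 0.0) -> "StepFunction":
        """Cumulative step function Σ_{s≤t} increment(s), remembering increments."""
        increments = np.asarray(increments, dtype=float)
        return cls(times, start + np.cumsum(increments), left_value=start,
                   increments=increments)

    def __call__(self, t):
        """Right-continuous evaluation f(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(idx < 0, self.left_value, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """Left limit f(t−)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="left") - 1
        out = np.where(idx < 0, self.left_value, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.knots, "value": self.values})

    def __len__(self) -> int:
        return len(self.knots)


def break_ties(data: CompetingRisksData, seed: int) -> CompetingRisksData:
    """Return a copy with tied observation times broken by seeded jitter.

    Every time value shared by two or more records (events or censorings —
    ties between an event and a censoring time are just as
    convention-sensitive as event–event ties) is perturbed by jitter
    uniform on (0, g/2), with g the minimal positive gap between distinct
    observed times, so the relative order of all non-tied observations is
    preserved.  Tie-free data are returned unchanged.  Deterministic given
    ``seed``.
    """
    t = data.time.copy()
    dup_vals = np.unique(t[pd.Series(t).duplicated(keep=False).to_numpy()])
    if dup_vals.size == 0:
        return data
    gaps = np.diff(np.unique(t))
    gap = gaps.min() if gaps.size else 1.0
    rng = np.random.default_rng(seed)
    for _ in range(100):
        tt = t.copy()
        mask = np.isin(t, dup_vals)
        tt[mask] = t[mask] + rng.uniform(0.0, gap / 2, size=mask.sum())
        if len(np.unique(tt)) == len(tt):
            frame = data.frame.copy()
            frame["time"] = tt
            return CompetingRisksData(frame)
    raise RuntimeError("could not break ties (degenerate data)")  # pragma: no cover


def read_competing_risks(path, time_col="time", status_col="status",
                         covariate_cols=None, status_map=None) -> CompetingRisksData:
    """Read a comma-separated table into :class:`CompetingRisksData`.

    ``status_map`` translates external status codes to the internal 0/1/2
    coding, e.g. ``{"cens": 0, "rel": 1, "nrm": 2}``.
    """
    df = pd.read_csv(path)
    for col in [time_col, status_col] + list(covariate_cols or []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    cols = {time_col: "time", status_col: "status"}
    keep = [time_col, status_col] + list(
        covariate_cols if covariate_cols is not None
        else [c for c in df.columns if c not in (time_col, status_col)]
    )
    out = df[keep].rename(columns=cols)
    if status_map is not None:
        unmapped = set(out["status"].unique()) - set(status_map)
        if unmapped:
            row = int(out.index[out["status"].isin(unmapped)][0])
            raise ValueError(
                f"unmapped status code {sorted(unmapped)[0]!r} (first in row {row})"
            )
        out["status"] = out["status"].map(status_map)
    return CompetingRisksData(out)


def write_competing_risks(data: CompetingRisksData, path) -> None:
    data.frame.to_csv(path, index=False)
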