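"""Static and dynamic Cox proportional hazards baselines.

Both regress time-to-progression on covariates via the partial likelihood
(lifelines).  The static model uses each patient's covariates at the first
time point; the dynamic model uses the full covariate path organized in
counting-process rows (start, stop, covariates, event), with demographics
as time-independent covariates.  Cases contribute an event at
T_tra - T_1; controls are censored at T_last + t_pre - T_1, the end of the
span they are known progression-free.

Risk scores are 1 - S(horizon | x) from the estimated baseline cumulative
hazard; the dynamic model evaluates the hazard at the last observed
covariate vector.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)


def _drop_constant(df: pd.DataFrame, protect: tuple[str, ...]) -> list[str]:
    keep = []
    for c in df.columns:
        if c in protect:
            keep.append(c)
            continue
        if df[c].nunique(dropna=False) > 1:
            keep.append(c)
        else:
            logger.info("dropping constant covariate column %r", c)
    return keep


def _cumhaz_at(baseline: pd.Series, t: float) -> float:
    """Step-function value of the baseline cumulative hazard at time t."""
    times = baseline.index.to_numpy(dtype=float)
    vals = baseline.to_numpy(dtype=float)
    i = np.searchsorted(times, t, side="right") - 1
    return float(vals[i]) if i >= 0 else 0.0


class StaticCoxModel:
    """Cox model on first-time-point covariates."""

    kind = "cox_static"

    def __init__(self, penalizer: float = 0.01, horizon: float = 365.0):
        self.penalizer = penalizer
        self.horizon = horizon
        self.fitter: CoxPHFitter | None = None
        self.columns_: list[str] | None = None

    def fit(self, X: pd.DataFrame, durations, events) -> "StaticCoxModel":
        events = np.asarray(events, dtype=int)
        if events.sum() == 0:
            raise ValueError("no events in training data (all censored)")
        df = X.copy()
        self.columns_ = _drop_constant(df, protect=())
        df = df[self.columns_]
        df["duration"] = np.asarray(durations, dtype=float)
        df["event"] = events
        self.fitter = CoxPHFitter(penalizer=self.penalizer)
        try:
            self.fitter.fit(df, duration_col="duration", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"static Cox fit failed to converge: {err}") from err
        return self

    def score(self, X: pd.DataFrame, horizon: float | None = None) -> np.ndarray:
        """Probability of progression by ``horizon`` given baseline covariates."""
        if self.fitter is None:
            raise RuntimeError("model is not fitted")
        h = self.horizon if horizon is None else horizon
        surv = self.fitter.predict_survival_function(X[self.columns_], times=[h])
        return 1.0 - surv.iloc[0].to_numpy(dtype=float)


def build_counting_process(
    times: np.ndarray,
    covariates: np.ndarray,
    seq_mask: np.ndarray,
    durations: np.ndarray,
    events: np.ndarray,
    feature_names: list[str],
) -> pd.DataFrame:
    """Expand sequences into counting-process rows.

    ``times`` (n, T) grid midpoints (days, relative to origin), ``covariates``
    (n, T, D) imputed values, ``seq_mask`` (n, T) valid steps, ``durations``
    the per-patient end time measured from the first used point, ``events``
    the case indicator (event only on the final row).  Rows of one patient
    are contiguous: stop_i = start_{i+1}; the sum of row durations equals
    the patient's duration.
    """
    rows = []
    n = len(durations)
    for p in range(n):
        valid = np.nonzero(seq_mask[p])[0]
        t = times[p, valid]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"overlapping intervals for patient index {p}")
        t0 = t[0]
        start = t - t0
        stop = np.empty_like(start)
        stop[:-1] = start[1:]
        stop[-1] = durations[p]
        if stop[-1] <= start[-1]:
            raise ValueError(
                f"patient index {p}: duration {durations[p]} does not extend "
                "past the last covariate time")
        ev = np.zeros(len(valid), dtype=int)
        ev[-1] = int(events[p])
        block = pd.DataFrame(covariates[p, valid], columns=feature_names)
        block.insert(0, "id", p)
        block["start"] = start
        block["stop"] = stop
        block["event"] = ev
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


class DynamicCoxModel:
    """Cox model with time-dependent covariates (counting-process fit)."""

    kind = "cox_dynamic"

    def __init__(self, penalizer: float = 0.01, horizon: float = 365.0):
        self.penalizer = penalizer
        self.horizon = horizon
        self.fitter: CoxTimeVaryingFitter | None = None
        self.columns_: list[str] | None = None

    def fit(self, long_df: pd.DataFrame) -> "DynamicCoxModel":
        if long_df["event"].sum() == 0:
            raise ValueError("no events in training data (all censored)")
        covs = [c for c in long_df.columns
                if c not in ("id", "start", "stop", "event")]
        keep = _drop_constant(long_df[covs], protect=())
        df = long_df[["id", "start", "stop", "event", *keep]]
        self.columns_ = keep
        self.fitter = CoxTimeVaryingFitter(penalizer=self.penalizer)
        try:
            self.fitter.fit(df, id_col="id", start_col="start",
                            stop_col="stop", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"dynamic Cox fit failed to converge: {err}") from err
        return self

    def score(self, X_last: pd.DataFrame, t_last=None,
              horizon: float | None = None) -> np.ndarray:
        """Risk within ``horizon`` days after ``t_last``, given the last
        observed covariates.

        ``t_last`` is each patient's last used time point on the same time
        axis as the fit (days since the first used point); the conditional
        risk uses the baseline-hazard increment over (t_last, t_last +
        horizon].  With ``t_last=None`` the window starts at 0.
        """
        if self.fitter is None:
            raise RuntimeError("model is not fitted")
        h = self.horizon if horizon is None else horizon
        ph = self.fitter.predict_partial_hazard(X_last[self.columns_])
        base = self.fitter.baseline_cumulative_hazard_.iloc[:, 0]
        if t_last is None:
            t_last = np.zeros(len(X_last))
        t_last = np.asarray(t_last, dtype=float)
        dH0 = np.array([_cumhaz_at(base, t + h) - _cumhaz_at(base, t)
                        for t in t_last])
        return 1.0 - np.exp(-dH0 * ph.to_numpy(dtype=float))

    @property
    def params_(self) -> pd.Series:
        return self.fitter.params_
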