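"""Conversion of longitudinal observations into labeled feature-vector series.

Each patient's irregular observations are binned into consecutive
``t_w``-day intervals anchored at the patient's first observation.  Interval
``n`` is stamped with its midpoint T_n = (n-1+0.5)*t_w.  Within an interval,
lab/vital readings are averaged, behavior codes take the latest reading, and
demographics are constant columns; T_n itself is appended as the ``time``
feature.  Case series are cut at T_tra - t_gap (a gap period that prevents
label leakage from near-transition measurements) and must place the
transition inside the prediction window (t_gap <= T_tra - T_last <= t_pre);
control series lose their final t_pre span.  Series are truncated to the
latest ``max_len`` points.

Missing cells are carried as NaN with an observation mask; imputation
(LOCF -> NOCB -> training-fold median) and z-scoring are deferred to
cross-validation time so that fold statistics never leak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    BEHAVIOR,
    DEFAULT_CATALOG,
    DEMOGRAPHICS,
    TIME_FEATURE,
    Variable,
    by_name,
)
from .cohort import DEFAULT_BANDS, StageBands, assign_status

logger = logging.getLogger(__name__)

_ALLOWED_T_PRE = (90.0, 365.0, 1095.0, 1825.0)


@dataclass(frozen=True)
class AssemblyConfig:
    """Binning/windowing configuration.

    ``t_w`` interval width, ``t_gap`` gap period, ``t_pre`` prediction
    window (days); ``max_len`` sequence cap; ``min_case_len`` minimum usable
    time points; ``variable_set`` one of {"all", "essential"};
    ``exclude_IIIb`` truncates each patient's stream at the first eGFR <= 44.
    """

    t_w: float = 7.0
    t_gap: float = 7.0
    t_pre: float = 365.0
    max_len: int = 100
    min_case_len: int = 5
    variable_set: str = "all"
    exclude_IIIb: bool = False
    catalog: tuple[Variable, ...] = field(default=DEFAULT_CATALOG)

    def validate(self) -> None:
        if self.t_w <= 0 or self.t_gap <= 0 or self.t_pre <= 0:
            raise ValueError("t_w, t_gap, t_pre must be positive")
        if self.min_case_len < 1:
            raise ValueError("min_case_len must be >= 1")
        if self.variable_set not in ("all", "essential"):
            raise ValueError("variable_set must be 'all' or 'essential'")

    def variables(self) -> list[Variable]:
        """Time-varying variables in the configured set (demographics excluded)."""
        out = []
        for v in self.catalog:
            if v.category == DEMOGRAPHICS:
                continue
            if self.variable_set == "essential" and not v.essential:
                continue
            out.append(v)
        return out


@dataclass
class FeatureVectorSeries:
    """One patient's binned series before padding.

    ``values`` is (N, D) with NaN for missing cells; ``observed`` the
    pre-imputation mask; ``grid_times`` the interval midpoints (days,
    relative to the grid origin); ``origin`` the absolute day of the
    patient's first observation.
    """

    patient_id: str
    grid_times: np.ndarray
    values: np.ndarray
    observed: np.ndarray
    feature_names: list[str]
    origin: float = 0.0

    def __len__(self) -> int:
        return len(self.grid_times)

    @property
    def T_last(self) -> float:
        return float(self.grid_times[-1]) if len(self) else float("nan")


def bin_observations(
    obs: pd.DataFrame,
    static_row: pd.Series,
    config: AssemblyConfig,
) -> FeatureVectorSeries:
    """Bin one patient's observations onto the t_w grid.

    ``obs`` holds that patient's rows (variable, t_days, value), restricted
    by this function to the configured variable set.  Intervals are
    half-open [k*t_w, (k+1)*t_w) anchored at the first observation time.
    """
    config.validate()
    variables = config.variables()
    var_names = [v.name for v in variables]
    known = set(by_name(config.catalog))
    for name in obs["variable"].unique():
        if name not in known:
            raise ValueError(f"unknown variable {name!r}")
    obs = obs[obs["variable"].isin(var_names)]
    if len(obs) == 0:
        raise ValueError("patient has no observations in the configured set")

    t = obs["t_days"].to_numpy(dtype=float)
    origin = float(t.min())
    rel = t - origin
    bins = np.floor(rel / config.t_w).astype(int)
    n_bins = int(bins.max()) + 1
    grid_times = (np.arange(n_bins) + 0.5) * config.t_w

    demo_names = [
        v.name for v in config.catalog if v.category == DEMOGRAPHICS
    ]
    feature_names = demo_names + var_names + [TIME_FEATURE]
    D = len(feature_names)
    values = np.full((n_bins, D), np.nan)
    observed = np.zeros((n_bins, D), dtype=bool)

    # demographics: constant, always observed
    for j, name in enumerate(demo_names):
        values[:, j] = float(static_row[name])
        observed[:, j] = True

    behavior = {v.name for v in variables if v.category == BEHAVIOR}
    col_of = {name: len(demo_names) + j for j, name in enumerate(var_names)}
    cols = obs["variable"].map(col_of).to_numpy(dtype=int)
    vals = obs["value"].to_numpy(dtype=float)
    is_beh = obs["variable"].isin(behavior).to_numpy()

    # labs/vitals: arithmetic mean within each interval
    sums = np.zeros((n_bins, D))
    counts = np.zeros((n_bins, D))
    np.add.at(sums, (bins[~is_beh], cols[~is_beh]), vals[~is_beh])
    np.add.at(counts, (bins[~is_beh], cols[~is_beh]), 1.0)
    got = counts > 0
    values[got] = sums[got] / counts[got]
    observed |= got

    # behaviors: latest reading in the interval wins (time-ascending
    # assignment leaves the last write)
    if is_beh.any():
        order = np.argsort(rel[is_beh], kind="stable")
        bb, cb, vb = bins[is_beh][order], cols[is_beh][order], vals[is_beh][order]
        values[bb, cb] = vb
        observed[bb, cb] = True

    values[:, -1] = grid_times
    observed[:, -1] = True
    return FeatureVectorSeries(
        str(static_row["patient_id"]), grid_times, values, observed,
        feature_names, origin,
    )


def apply_case_window(
    series: FeatureVectorSeries, T_tra: float, config: AssemblyConfig
) -> tuple[FeatureVectorSeries, bool]:
    """Trim a case series at the gap period and test window validity.

    Drops every time point with T_n >= T_tra - t_gap (``T_tra`` given
    relative to the series' grid origin).  The trimmed series is valid iff
    it retains at least ``min_case_len`` points and the transition falls
    inside the prediction window measured from the last used point:
    t_gap <= T_tra - T_last <= t_pre.
    """
    keep = series.grid_times < T_tra - config.t_gap
    trimmed = _subset_series(series, keep)
    if len(trimmed) < config.min_case_len:
        return trimmed, False
    dt = T_tra - trimmed.T_last
    valid = config.t_gap <= dt <= config.t_pre
    return trimmed, valid


def apply_control_truncation(
    series: FeatureVectorSeries, config: AssemblyConfig
) -> FeatureVectorSeries:
    """Remove a control's final t_pre span.

    T_end is the last grid midpoint carrying any observation (beyond the
    constant demographic/time columns); all points with
    T_n > T_end - t_pre are dropped so the retained series is known
    progression-free for t_pre days.
    """
    dyn = np.array(
        [n != TIME_FEATURE and _is_dynamic(n, series) for n in series.feature_names]
    )
    has_obs = series.observed[:, dyn].any(axis=1)
    if not has_obs.any():
        return _subset_series(series, np.zeros(len(series), dtype=bool))
    T_end = float(series.grid_times[np.nonzero(has_obs)[0][-1]])
    keep = series.grid_times <= T_end - config.t_pre
    return _subset_series(series, keep)


def _is_dynamic(name: str, series: FeatureVectorSeries) -> bool:
    # demographic columns are constant & always observed; treat the leading
    # always-observed constant columns as non-dynamic by name
    return name not in ("sex", "race")


def truncate_length(
    series: FeatureVectorSeries, max_len: int = 100
) -> FeatureVectorSeries:
    """Keep only the latest ``max_len`` time points."""
    if len(series) <= max_len:
        return series
    keep = np.zeros(len(series), dtype=bool)
    keep[-max_len:] = True
    return _subset_series(series, keep)


def _subset_series(
    series: FeatureVectorSeries, keep: np.ndarray
) -> FeatureVectorSeries:
    return FeatureVectorSeries(
        series.patient_id,
        series.grid_times[keep],
        series.values[keep],
        series.observed[keep],
        series.feature_names,
        series.origin,
    )


def exclude_stage_IIIb(
    obs: pd.DataFrame, bands: StageBands = DEFAULT_BANDS
) -> pd.DataFrame:
    """Truncate a patient's observation stream at the first eGFR <= 44.

    Emulates building the harder stage II/IIIa prediction task: all
    information from the first stage-IIIb-or-worse eGFR reading onward is
    removed, for every variable.  Patients never below 45 are unchanged.
    """
    egfr = obs[obs["variable"] == "egfr"].sort_values("t_days", kind="mergesort")
    low = egfr[egfr["value"] <= bands.IIIb[1]]
    if len(low) == 0:
        return obs
    t_cut = float(low["t_days"].iloc[0])
    return obs[obs["t_days"] < t_cut]


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SequenceDataset:
    """Padded assembled dataset.

    ``X`` (n, T, D) float with NaN missing cells and zero-filled padding
    rows; ``observed`` (n, T, D) pre-imputation mask; ``seq_mask`` (n, T)
    True on real time steps (post-padding: step 0..seq_len-1 are real);
    ``meta`` one row per sample (patient_id, label, seq_len, race, sex,
    age, T_last, T_tra, set_id).
    """

    X: np.ndarray
    observed: np.ndarray
    seq_mask: np.ndarray
    meta: pd.DataFrame
    feature_names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy(dtype=int)

    def subset(self, idx) -> "SequenceDataset":
        idx = np.asarray(idx)
        return SequenceDataset(
            self.X[idx],
            self.observed[idx],
            self.seq_mask[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            list(self.feature_names),
        )

    def select_features(self, names: Sequence[str]) -> "SequenceDataset":
        """Restrict to the given feature columns (order preserved as given)."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise ValueError(f"unknown features {missing}")
        cols = [self.feature_names.index(n) for n in names]
        return SequenceDataset(
            self.X[:, :, cols],
            self.observed[:, :, cols],
            self.seq_mask,
            self.meta.copy(),
            list(names),
        )

    def with_labels(self, labels: np.ndarray) -> "SequenceDataset":
        meta = self.meta.copy()
        meta["label"] = np.asarray(labels, dtype=int)
        return SequenceDataset(
            self.X, self.observed, self.seq_mask, meta, list(self.feature_names)
        )


def assemble_dataset(
    observations: pd.DataFrame,
    static: pd.DataFrame,
    config: AssemblyConfig,
    bands: StageBands = DEFAULT_BANDS,
) -> tuple[SequenceDataset, pd.DataFrame]:
    """Run the full per-patient pipeline and return the labeled dataset.

    Per patient: optional stage-IIIb stream truncation, cohort status from
    the eGFR series, binning, case window / control truncation, length
    truncation, labeling.  Returns the padded dataset of retained patients
    plus a diagnostics frame recording every patient's outcome.
    """
    config.validate()
    static = static.set_index("patient_id", drop=False)
    series_list: list[FeatureVectorSeries] = []
    meta_rows: list[dict] = []
    diag: list[dict] = []

    for pid, obs_p in observations.groupby("patient_id", sort=True):
        if config.exclude_IIIb:
            obs_p = exclude_stage_IIIb(obs_p, bands)
        egfr = obs_p[obs_p["variable"] == "egfr"].sort_values(
            "t_days", kind="mergesort"
        )
        if len(egfr) == 0:
            diag.append({"patient_id": pid, "outcome": "dropped_no_egfr"})
            continue
        a = assign_status(
            egfr["t_days"].to_numpy(), egfr["value"].to_numpy(), bands, patient_id=pid
        )
        if a.status == "excluded":
            diag.append({"patient_id": pid, "outcome": f"excluded_{a.exclusion_reason}"})
            continue

        srow = static.loc[pid]
        series = bin_observations(obs_p, srow, config)
        if a.status == "case":
            T_tra_rel = a.T_tra - series.origin
            series, valid = apply_case_window(series, T_tra_rel, config)
            if not valid:
                diag.append({"patient_id": pid, "outcome": "case_window_invalid"})
                continue
            label = 1
            T_tra_out = T_tra_rel
        else:
            series = apply_control_truncation(series, config)
            if len(series) < config.min_case_len:
                diag.append({"patient_id": pid, "outcome": "control_too_short"})
                continue
            label = 0
            T_tra_out = np.nan
        series = truncate_length(series, config.max_len)

        T_last = series.T_last
        meta_rows.append(
            {
                "patient_id": pid,
                "label": label,
                "seq_len": len(series),
                "race": int(srow["race"]),
                "sex": int(srow["sex"]),
                "age": float(srow["age_at_start"]) + T_last / 365.25,
                "T_last": T_last,
                "T_tra": T_tra_out,
                "set_id": -1,
            }
        )
        series_list.append(series)
        diag.append({"patient_id": pid, "outcome": f"retained_{a.status}"})

    diagnostics = pd.DataFrame(diag)
    if not series_list:
        empty = SequenceDataset(
            np.zeros((0, 0, 0)), np.zeros((0, 0, 0), bool), np.zeros((0, 0), bool),
            pd.DataFrame(meta_rows), [],
        )
        return empty, diagnostics

    feature_names = series_list[0].feature_names
    T = max(len(s) for s in series_list)
    D = len(feature_names)
    n = len(series_list)
    X = np.zeros((n, T, D))
    observed = np.zeros((n, T, D), dtype=bool)
    seq_mask = np.zeros((n, T), dtype=bool)
    for i, s in enumerate(series_list):
        L = len(s)
        X[i, :L] = s.values
        observed[i, :L] = s.observed
        seq_mask[i, :L] = True

    meta = pd.DataFrame(meta_rows)
    return SequenceDataset(X, observed, seq_mask, meta, feature_names), diagnostics


# ---------------------------------------------------------------------------
# fold-level imputation and standardization


@dataclass
class FoldStats:
    """Per-feature imputation medians and z-score moments from training folds."""

    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    feature_names: list[str]

    @classmethod
    def fit(cls, ds: SequenceDataset, idx: Iterable[int]) -> "FoldStats":
        idx = np.asarray(list(idx))
        D = len(ds.feature_names)
        medians = np.zeros(D)
        X = ds.X[idx]
        obs = ds.observed[idx] & ds.seq_mask[idx][:, :, None]
        for j in range(D):
            vals = X[:, :, j][obs[:, :, j]]
            if len(vals):
                medians[j] = float(np.median(vals))
            else:
                logger.info("feature %s unobserved in training folds; median=0",
                            ds.feature_names[j])
        # moments on imputed training data
        Xi = _impute_array(X, obs, ds.seq_mask[idx], medians)
        valid = ds.seq_mask[idx]
        means = np.zeros(D)
        sds = np.ones(D)
        for j in range(D):
            vals = Xi[:, :, j][valid]
            means[j] = float(vals.mean())
            sd = float(vals.std())
            sds[j] = sd if sd > 1e-12 else 1.0
        return cls(medians, means, sds, list(ds.feature_names))

    def transform(self, ds: SequenceDataset, standardize: bool = True) -> np.ndarray:
        """Impute (LOCF -> NOCB -> median) and optionally z-score.

        Returns a dense (n, T, D) array with padding rows zeroed.
        """
        if self.feature_names != ds.feature_names:
            raise ValueError("feature sets of stats and dataset differ")
        obs = ds.observed & ds.seq_mask[:, :, None]
        Xi = _impute_array(ds.X, obs, ds.seq_mask, self.medians)
        if standardize:
            Xi = (Xi - self.means) / self.sds
        Xi = np.where(ds.seq_mask[:, :, None], Xi, 0.0)
        return Xi


def _ffill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise last-observation-carried-forward on a (n, T) slice."""
    n, T = values.shape
    idx = np.where(mask, np.arange(T)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    out = np.where(idx >= 0, np.take_along_axis(values, np.maximum(idx, 0), axis=1),
                   np.nan)
    return out


def _impute_array(
    X: np.ndarray, obs: np.ndarray, seq_mask: np.ndarray, medians: np.ndarray
) -> np.ndarray:
    """LOCF then NOCB then median, per feature, within each sample's valid span."""
    n, T, D = X.shape
    out = np.empty_like(X)
    for j in range(D):
        v = np.where(obs[:, :, j], X[:, :, j], np.nan)
        f = _ffill(v, obs[:, :, j])
        b = _ffill(v[:, ::-1], obs[:, :, j][:, ::-1])[:, ::-1]
        filled = np.where(np.isnan(f), b, f)
        filled = np.where(np.isnan(filled), medians[j], filled)
        out[:, :, j] = filled
    return out
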