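"""Cox baselines: parameter recovery, counting-process contract, dynamics."""

import numpy as np
import pandas as pd
import pytest

from ckdprog.models import (
    DynamicCoxModel,
    StaticCoxModel,
    build_counting_process,
)


def _exponential_toy(n=2000, seed=0, log_hr=np.log(2.0)):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    rate = 0.01 * np.exp(log_hr * x)
    T = rng.exponential(1.0 / rate)
    C = rng.exponential(1.0 / 0.005, size=n)
    duration = np.minimum(T, C)
    event = (T <= C).astype(int)
    X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
    return X, duration, event


def test_static_recovers_known_log_hazard_ratio():
    X, duration, event = _exponential_toy()
    m = StaticCoxModel(penalizer=0.0).fit(X, duration, event)
    est = float(m.fitter.params_["x"])
    se = float(m.fitter.standard_errors_["x"])
    assert abs(est - np.log(2.0)) < 3 * se


def test_all_censored_rejected():
    X, duration, _ = _exponential_toy(n=50)
    with pytest.raises(ValueError, match="no events"):
        StaticCoxModel().fit(X, duration, np.zeros(50, int))


def test_column_permutation_leaves_predictions_unchanged():
    X, duration, event = _exponential_toy(n=400, seed=3)
    m1 = StaticCoxModel(penalizer=0.0).fit(X, duration, event)
    m2 = StaticCoxModel(penalizer=0.0).fit(X[["noise", "x"]], duration, event)
    s1 = m1.score(X.head(30), horizon=100.0)
    s2 = m2.score(X.head(30)[["noise", "x"]], horizon=100.0)
    assert np.allclose(s1, s2, atol=1e-10)


def test_constant_covariate_column_dropped():
    X, duration, event = _exponential_toy(n=300, seed=1)
    X = X.assign(flat=1.0)
    m = StaticCoxModel(penalizer=0.0).fit(X, duration, event)
    assert "flat" not in m.columns_


class TestCountingProcess:
    def test_rows_contiguous_and_lossless(self):
        times = np.array([[3.5, 10.5, 17.5]])
        cov = np.arange(6, dtype=float).reshape(1, 3, 2)
        mask = np.ones((1, 3), bool)
        df = build_counting_process(times, cov, mask, durations=np.array([30.0]),
                                    events=np.array([1]), feature_names=["a", "b"])
        assert len(df) == 3
        assert np.allclose(df["start"], [0.0, 7.0, 14.0])
        assert np.allclose(df["stop"], [7.0, 14.0, 30.0])
        # contiguity and losslessness: total row span equals the duration
        assert np.allclose(df["stop"].iloc[:-1], df["start"].iloc[1:])
        assert (df["stop"] - df["start"]).sum() == pytest.approx(30.0)
        assert list(df["event"]) == [0, 0, 1]

    def test_overlapping_intervals_rejected(self):
        times = np.array([[3.5, 3.5, 17.5]])
        cov = np.zeros((1, 3, 1))
        mask = np.ones((1, 3), bool)
        with pytest.raises(ValueError, match="overlapping"):
            build_counting_process(times, cov, mask, np.array([30.0]),
                                   np.array([1]), ["a"])

    def test_duration_must_extend_past_last_row(self):
        times = np.array([[3.5, 10.5]])
        cov = np.zeros((1, 2, 1))
        mask = np.ones((1, 2), bool)
        with pytest.raises(ValueError, match="extend"):
            build_counting_process(times, cov, mask, np.array([5.0]),
                                   np.array([1]), ["a"])


def test_time_constant_covariates_reduce_to_static_fit():
    """With constant covariates the counting-process likelihood collapses to
    the ordinary Cox likelihood, so the coefficients must agree."""
    X, duration, event = _exponential_toy(n=300, seed=2)
    static = StaticCoxModel(penalizer=0.0).fit(X, duration, event)

    n = len(duration)
    steps = 3
    times = np.linspace(0.01, 0.02, steps)[None, :] * duration[:, None]
    cov = np.repeat(X.to_numpy()[:, None, :], steps, axis=1)
    mask = np.ones((n, steps), bool)
    long_df = build_counting_process(times, cov, mask, duration, event,
                                     list(X.columns))
    dynamic = DynamicCoxModel(penalizer=0.0).fit(long_df)
    for c in X.columns:
        assert float(dynamic.params_[c]) == pytest.approx(
            float(static.fitter.params_[c]), abs=1e-6)


def test_dynamic_beats_static_when_hazard_tracks_current_value():
    """Hazard driven by a drifting covariate's current value: using the
    trajectory must rank patients better than the baseline snapshot."""
    from ckdprog.evaluation import auroc

    rng = np.random.default_rng(8)
    n, steps = 500, 8
    dt = 10.0
    base0 = rng.normal(0.0, 1.0, n)
    drift = rng.normal(0.0, 0.25, n)
    grid = np.arange(steps) * dt
    z = base0[:, None] + drift[:, None] * np.arange(steps)[None, :]
    lam = 0.002 * np.exp(1.2 * z)
    event_time = np.full(n, np.inf)
    for k in range(steps):
        t_ev = rng.exponential(1.0 / lam[:, k]) + grid[k]
        hit = (event_time == np.inf) & (t_ev < grid[k] + dt)
        event_time[hit] = t_ev[hit]
    horizon = steps * dt
    event = (event_time < horizon).astype(int)
    duration = np.where(event == 1, event_time, horizon)

    # observed covariate path up to each patient's end
    keep = grid[None, :] < duration[:, None]
    keep[:, 0] = True
    labels = event
    train = np.arange(n) < 350
    test = ~train

    long_df = build_counting_process(
        grid[None, :].repeat(n, 0)[train][:, :][:, keep[train][0] | True],
        z[train][:, :, None], np.ones((train.sum(), steps), bool) & keep[train],
        duration[train] + 1e-6, event[train], ["z"])
    dyn = DynamicCoxModel(penalizer=0.0).fit(long_df)
    last_idx = keep.sum(axis=1) - 1
    z_last = z[np.arange(n), last_idx]
    s_dyn = dyn.score(pd.DataFrame({"z": z_last[test]}), horizon=horizon)

    stat = StaticCoxModel(penalizer=0.0).fit(
        pd.DataFrame({"z": z[train, 0]}), duration[train], event[train])
    s_stat = stat.score(pd.DataFrame({"z": z[test, 0]}), horizon=horizon)

    assert auroc(labels[test], s_dyn) > auroc(labels[test], s_stat)
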