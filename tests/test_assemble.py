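"""Binning, windowing, truncation, imputation, and leakage invariants."""

import numpy as np
import pandas as pd
import pytest

from ckdprog import AssemblyConfig, assemble_dataset
from ckdprog.assemble import (
    FoldStats,
    apply_case_window,
    apply_control_truncation,
    bin_observations,
    exclude_stage_IIIb,
    truncate_length,
)
from ckdprog.synthetic import reduced_catalog

STATIC = pd.Series(
    {"patient_id": "P0", "sex": 1, "race": 0, "age_at_start": 60.0}
)


def _obs(rows):
    return pd.DataFrame(rows, columns=["patient_id", "variable", "t_days", "value"])


def _cfg(**kw):
    kw.setdefault("catalog", reduced_catalog(2))
    return AssemblyConfig(**kw)


class TestBinObservations:
    def test_lab_values_averaged_with_midpoint_time(self):
        obs = _obs([("P0", "egfr", 1.0, 10.0), ("P0", "egfr", 3.0, 20.0)])
        s = bin_observations(obs, STATIC, _cfg())
        # grid anchored at the first observation (day 1); both readings in
        # the first half-open week, whose midpoint is 3.5
        j = s.feature_names.index("egfr")
        assert s.values[0, j] == pytest.approx(15.0)
        assert s.grid_times[0] == pytest.approx(3.5)

    def test_behavior_takes_latest_reading_in_interval(self):
        obs = _obs(
            [("P0", "egfr", 1.0, 50.0),
             ("P0", "smoking_status", 1.0, 0.0),
             ("P0", "smoking_status", 5.0, 1.0)]
        )
        s = bin_observations(obs, STATIC, _cfg())
        j = s.feature_names.index("smoking_status")
        assert s.values[0, j] == 1.0

    def test_unknown_variable_named_in_error(self):
        obs = _obs([("P0", "flux_capacitance", 0.0, 1.0)])
        with pytest.raises(ValueError, match="flux_capacitance"):
            bin_observations(obs, STATIC, _cfg())

    def test_time_column_is_uniform_grid(self, small_cohort):
        cfg = AssemblyConfig()
        count = 0
        for pid, grp in small_cohort.observations.groupby("patient_id"):
            if count >= 50:
                break
            srow = small_cohort.static.set_index("patient_id", drop=False).loc[pid]
            s = bin_observations(grp, srow, cfg)
            steps = np.diff(s.grid_times)
            assert np.allclose(steps, cfg.t_w)
            assert np.allclose(s.values[:, -1], s.grid_times)
            assert s.grid_times[0] == pytest.approx(cfg.t_w / 2)
            count += 1


def _series_with_grid(n, t_w=7.0):
    """Minimal series with an egfr reading in every interval."""
    rows = [("P0", "egfr", k * t_w + 1.0, 50.0) for k in range(n)]
    return bin_observations(_obs(rows), STATIC, _cfg(t_w=t_w))


class TestCaseWindow:
    def test_window_arithmetic_on_weekly_grid(self):
        s = _series_with_grid(40)
        trimmed, valid = apply_case_window(s, T_tra=200.0, config=_cfg(t_pre=365.0))
        # points with T_n >= 193 dropped; last midpoint below 193 is 192.5
        assert trimmed.grid_times[-1] == pytest.approx(192.5)
        assert 200.0 - trimmed.T_last == pytest.approx(7.5)
        assert valid

    def test_transition_beyond_prediction_window_invalid(self):
        s = _series_with_grid(10)
        _, valid = apply_case_window(s, T_tra=500.0, config=_cfg(t_pre=365.0))
        assert not valid  # T_tra - T_last = 433.5 > 365

    def test_too_few_remaining_points_invalid(self):
        s = _series_with_grid(10)
        # T_tra - t_gap = 31 keeps midpoints 3.5..24.5 -> 4 points < 5
        _, valid = apply_case_window(s, T_tra=38.0, config=_cfg())
        assert not valid


class TestControlTruncation:
    def test_final_prediction_span_removed(self):
        s = _series_with_grid(105)  # last midpoint 731.5
        out = apply_control_truncation(s, _cfg(t_pre=365.0))
        assert out.grid_times[-1] <= 731.5 - 365.0
        # last grid midpoint not exceeding 366.5 is 360.5
        assert out.grid_times[-1] == pytest.approx(360.5)

    def test_series_shorter_than_window_becomes_empty(self):
        s = _series_with_grid(10)
        out = apply_control_truncation(s, _cfg(t_pre=365.0))
        assert len(out) == 0

    def test_zero_t_pre_rejected_at_validation(self):
        with pytest.raises(ValueError):
            _cfg(t_pre=0.0).validate()


class TestTruncateLength:
    def test_long_series_keeps_latest_100(self):
        s = _series_with_grid(150)
        out = truncate_length(s, 100)
        assert len(out) == 100
        assert out.grid_times[0] == s.grid_times[50]
        assert out.grid_times[-1] == s.grid_times[-1]

    def test_short_series_unchanged(self):
        s = _series_with_grid(80)
        assert truncate_length(s, 100) is s

    def test_case_length_distribution_has_atom_at_cap(self, small_dataset):
        lens = small_dataset.meta.query("label == 1")["seq_len"]
        assert (lens == 100).mean() > 0.2
        assert (lens <= 100).all()


class TestStageIIIbExclusion:
    def test_stream_cut_at_first_low_reading(self):
        obs = _obs(
            [("P0", "egfr", 0.0, 80.0), ("P0", "egfr", 100.0, 60.0),
             ("P0", "egfr", 200.0, 43.0), ("P0", "egfr", 300.0, 25.0),
             ("P0", "smoking_status", 250.0, 1.0)]
        )
        out = exclude_stage_IIIb(obs)
        assert (out["t_days"] < 200.0).all()
        assert len(out) == 2

    def test_patient_never_below_45_unchanged(self):
        obs = _obs([("P0", "egfr", 0.0, 80.0), ("P0", "egfr", 100.0, 60.0)])
        pd.testing.assert_frame_equal(exclude_stage_IIIb(obs), obs)

    def test_exclusion_shrinks_valid_cases(self, small_cohort):
        with_ = assemble_dataset(
            small_cohort.observations, small_cohort.static, AssemblyConfig()
        )[0]
        without = assemble_dataset(
            small_cohort.observations, small_cohort.static,
            AssemblyConfig(exclude_IIIb=True),
        )[0]
        n_with = int(with_.labels.sum())
        n_without = int(without.labels.sum()) if without.n else 0
        assert n_without < n_with


class TestImputation:
    def _ds_one_feature(self, col):
        """1-sample dataset with a single lab column plus time."""
        from ckdprog.assemble import SequenceDataset

        col = np.asarray(col, float)
        T = len(col)
        X = np.zeros((1, T, 2))
        X[0, :, 0] = np.where(np.isnan(col), 0.0, col)
        X[0, :, 1] = (np.arange(T) + 0.5) * 7
        observed = np.zeros((1, T, 2), bool)
        observed[0, :, 0] = ~np.isnan(col)
        observed[0, :, 1] = True
        meta = pd.DataFrame(
            {"patient_id": ["P0"], "label": [0], "seq_len": [T],
             "race": [0], "sex": [0], "age": [50.0], "T_last": [X[0, -1, 1]],
             "T_tra": [np.nan], "set_id": [-1]}
        )
        return SequenceDataset(X, observed, np.ones((1, T), bool), meta,
                               ["hgb", "time"])

    def test_locf_then_nocb(self):
        ds = self._ds_one_feature([np.nan, 5.0, np.nan, np.nan])
        stats = FoldStats.fit(ds, [0])
        out = stats.transform(ds, standardize=False)
        assert np.allclose(out[0, :, 0], [5.0, 5.0, 5.0, 5.0])

    def test_all_missing_falls_back_to_training_median(self):
        ds = self._ds_one_feature([np.nan, np.nan, np.nan])
        stats = FoldStats.fit(ds, [0])
        stats.medians[0] = 42.0
        out = stats.transform(ds, standardize=False)
        assert np.allclose(out[0, :, 0], 42.0)

    def test_observed_cells_unchanged_and_nothing_missing(self, small_dataset):
        idx = np.arange(min(80, small_dataset.n))
        stats = FoldStats.fit(small_dataset, idx)
        out = stats.transform(small_dataset, standardize=False)
        assert not np.isnan(out).any()
        obs = small_dataset.observed & small_dataset.seq_mask[:, :, None]
        assert np.allclose(out[obs], small_dataset.X[obs])

    def test_unknown_feature_set_rejected(self, small_dataset):
        stats = FoldStats.fit(small_dataset, [0, 1])
        other = small_dataset.select_features(["egfr", "time"])
        with pytest.raises(ValueError, match="feature sets"):
            stats.transform(other)


class TestDatasetInvariants:
    def test_labels_match_status_and_no_leakage(self, small_dataset):
        meta = small_dataset.meta
        cases = meta[meta["label"] == 1]
        cfg = AssemblyConfig()
        # every case keeps a gap of at least t_gap before its transition
        assert (cases["T_tra"] - cases["T_last"] >= cfg.t_gap).all()
        assert (cases["T_tra"] - cases["T_last"] <= cfg.t_pre).all()
        assert meta[meta["label"] == 0]["T_tra"].isna().all()
        assert (meta["seq_len"] >= cfg.min_case_len).all()
        assert (meta["seq_len"] <= cfg.max_len).all()

    def test_reassembly_is_deterministic(self, small_cohort):
        a = assemble_dataset(
            small_cohort.observations, small_cohort.static, AssemblyConfig()
        )[0]
        b = assemble_dataset(
            small_cohort.observations, small_cohort.static, AssemblyConfig()
        )[0]
        assert np.array_equal(a.X, b.X, equal_nan=True)
        assert np.array_equal(a.seq_mask, b.seq_mask)
        pd.testing.assert_frame_equal(a.meta, b.meta)
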