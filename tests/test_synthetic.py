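"""Generator contracts: determinism, stage plausibility, slope recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ckdprog import GeneratorConfig, build_cohort, generate_cohort
from ckdprog.synthetic import reduced_catalog, trajectory_slope_check


def test_identical_config_and_seed_reproduces_tables_exactly():
    cfg = GeneratorConfig(n_patients=40, seed=11, variable_catalog=reduced_catalog(2))
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.observations, b.observations)
    pd.testing.assert_frame_equal(a.static, b.static)
    pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)


def test_zero_progressor_fraction_yields_no_cases():
    cfg = GeneratorConfig(
        n_patients=80, progressor_fraction=0.0, seed=3,
        variable_catalog=reduced_catalog(0),
    )
    cohort = generate_cohort(cfg)
    assert cohort.ground_truth["progressor"].sum() == 0
    table = build_cohort(cohort.observations)
    assert (table["status"] == "case").sum() == 0


def test_progressor_fraction_within_binomial_interval():
    cfg = GeneratorConfig(
        n_patients=2000, progressor_fraction=0.15, seed=1,
        variable_catalog=reduced_catalog(0),
    )
    cohort = generate_cohort(cfg)
    k = int(cohort.ground_truth["progressor"].sum())
    lo, hi = stats.binom.interval(0.99, 2000, 0.15)
    assert lo <= k <= hi


def test_first_egfr_reading_always_in_stage_II_III(small_cohort):
    egfr = small_cohort.observations.query("variable == 'egfr'")
    firsts = egfr.sort_values("t_days").groupby("patient_id")["value"].first()
    assert ((firsts >= 30.0) & (firsts <= 89.0)).all()


def test_every_patient_has_positive_egfr_rows(small_cohort):
    obs = small_cohort.observations
    egfr = obs.query("variable == 'egfr'")
    assert set(egfr["patient_id"]) == set(small_cohort.static["patient_id"])
    assert (egfr["value"] > 0).all()
    assert (obs["t_days"] >= 0).all()


def test_last_egfr_separates_progressors(small_cohort):
    """Sanity floor: the generated signal is strong enough to learn from."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    egfr = small_cohort.observations.query("variable == 'egfr'")
    last = egfr.sort_values("t_days").groupby("patient_id")["value"].last()
    truth = small_cohort.ground_truth.set_index("patient_id")["progressor"]
    truth = truth.loc[last.index]
    lr = LogisticRegression().fit(last.to_numpy()[:, None], truth.to_numpy())
    auc = roc_auc_score(truth, lr.predict_proba(last.to_numpy()[:, None])[:, 1])
    assert auc > 0.7


class TestSlopeRecovery:
    def test_noiseless_generation_recovers_slopes_exactly(self):
        cfg = GeneratorConfig(
            n_patients=60, seed=5, egfr_noise_sd=0.0,
            slope_progressor=(-10.0, 0.0), slope_nonprogressor=(-1.0, 0.0),
            missingness_rate=0.0, variable_catalog=reduced_catalog(0),
        )
        res = trajectory_slope_check(generate_cohort(cfg))
        # only flat-trajectory patients clip at the eGFR floor of 5, and
        # progressor follow-up stops shortly after the crossing of 29
        assert res["progressor"]["mean_slope"] == pytest.approx(-10.0, abs=1e-6)
        assert res["nonprogressor"]["mean_slope"] == pytest.approx(-1.0, abs=1e-6)

    def test_group_mean_within_three_se(self):
        cfg = GeneratorConfig(
            n_patients=200, seed=9, slope_progressor=(-10.0, 3.0),
            progressor_fraction=0.5, variable_catalog=reduced_catalog(0),
        )
        res = trajectory_slope_check(generate_cohort(cfg))
        est, se = res["progressor"]["mean_slope"], res["progressor"]["se"]
        # the slope prior is clipped to [-20, -4], which pulls the mean of
        # N(-10, 3) up by a small, bounded amount
        assert abs(est - (-10.0)) < 3 * se + 0.5

    def test_empty_group_raises(self):
        cfg = GeneratorConfig(
            n_patients=30, progressor_fraction=0.0, seed=2,
            variable_catalog=reduced_catalog(0),
        )
        with pytest.raises(ValueError, match="progressor"):
            trajectory_slope_check(generate_cohort(cfg))


@pytest.mark.parametrize(
    "bad",
    [
        dict(progressor_fraction=float("nan")),
        dict(progressor_fraction=1.5),
        dict(baseline_egfr_range=(20.0, 80.0)),
        dict(followup_days_range=(100.0, 400.0)),
        dict(n_patients=0, progressor_fraction=0.1),
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        GeneratorConfig(**bad).validate()


def test_missingness_thins_observations():
    base = dict(n_patients=30, seed=4, variable_catalog=reduced_catalog(2))
    dense = generate_cohort(GeneratorConfig(missingness_rate=0.0, **base))
    sparse = generate_cohort(GeneratorConfig(missingness_rate=0.5, **base))
    assert len(sparse.observations) < 0.75 * len(dense.observations)
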