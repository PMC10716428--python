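"""Synthetic longitudinal EHR generator.

Real EHR cohorts suitable for stage II/III → IV/V progression modeling are
proprietary, so this module generates cohorts with the statistical structure
the downstream pipeline assumes: irregularly timed clinic visits, an eGFR
trajectory per patient (a progressor subpopulation declines into the ≤29
band), correlated serum creatinine, stationary noisy labs/vitals, two-state
Markov behavior indicators, and MCAR per-observation missingness.

The generator is the study-condition definition for every synthetic
experiment in this package; its defaults are documented in
``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import BEHAVIOR, DEFAULT_CATALOG, LAB, VITAL, Variable

logger = logging.getLogger(__name__)

# Population level (mean, sd) for each continuous lab/vital, in customary
# clinical units.  Per-patient offsets use 0.7*sd, per-visit noise 0.5*sd.
_LEVELS: dict[str, tuple[float, float]] = {
    "systolic_bp": (132.0, 15.0),
    "diastolic_bp": (78.0, 10.0),
    "bmi": (29.0, 5.0),
    "oxygen_saturation": (97.0, 1.5),
    "height": (168.0, 10.0),
    "weight": (82.0, 15.0),
    "albumin": (4.0, 0.5),
    "blood_urea_nitrogen": (20.0, 8.0),
    "calcium": (9.4, 0.6),
    "creatinine": (1.2, 0.4),  # used only when decoupled from eGFR
    "ferritin": (150.0, 80.0),
    "hba1c": (6.5, 1.2),
    "hgb": (12.5, 1.8),
    "cholesterol": (180.0, 35.0),
    "ldl": (100.0, 30.0),
    "hdl": (50.0, 14.0),
    "parathyroid_hormone": (65.0, 30.0),
    "phosphorous": (3.6, 0.6),
    "saturation": (25.0, 8.0),
    "triglycerides": (140.0, 60.0),
    "uric_acid": (6.0, 1.5),
    "urine_creatinine": (100.0, 40.0),
    "urine_micro_albumin": (30.0, 25.0),
    "urine_protein": (15.0, 12.0),
    "urine_rbc_count": (2.0, 2.0),
    "vitamin_d25": (28.0, 10.0),
    "bicarbs_co2": (24.0, 3.0),
}

# Stationary prevalence of the "yes" state for each behavior chain.
_PREVALENCE: dict[str, float] = {
    "illegal_drug_use": 0.08,
    "injection_use": 0.02,
    "iv_use": 0.02,
    "pill_use": 0.04,
    "marijuana_use": 0.10,
    "alcohol_use": 0.40,
    "smoking_status": 0.25,
    "cigarette_use": 0.20,
    "cigar_use": 0.04,
    "tobacco_use": 0.06,
}

_BEHAVIOR_PERSISTENCE = 0.9  # lag-one autocorrelation of each 2-state chain


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Attributes
    ----------
    n_patients : int
        Cohort size.
    progressor_fraction : float
        Probability a patient is a ground-truth progressor whose eGFR
        trajectory declines into the stage IV/V band (≤ 29).
    baseline_egfr_range : (float, float)
        Uniform range of the baseline (t=0) expected eGFR, mL/min/1.73m².
        Must lie inside [30, 89] so every patient starts in stages II/III.
    slope_progressor : (float, float)
        Mean and sd of the annual eGFR change for progressors
        (mL/min/1.73m² per year; mean negative).  Draws are clipped to
        [-20, -4] so the crossing of 29 happens at a finite, plausible time.
    slope_nonprogressor : (float, float)
        Mean and sd for non-progressors; draws clipped to [-2, 1].
    egfr_noise_sd : float
        Measurement noise sd added to each eGFR reading.
    visit_gap_mean_days : float
        Mean inter-visit interval; gaps are 1 + Gamma(shape=2) days.
    followup_days_range : (float, float)
        Uniform range of non-progressor follow-up; progressor follow-up is
        extended past the expected crossing of eGFR 29 by 200-500 days so a
        stable stage IV/V period is constructible.
    missingness_rate : float
        Per-observation MCAR drop probability (non-demographic variables;
        each patient's first eGFR reading is always retained).
    variable_catalog : tuple of Variable
        Variables to emit.
    covariate_signal : bool
        If True (default), serum creatinine is inversely monotone in the
        patient's underlying eGFR; if False, every covariate is independent
        of progression, confining the predictive signal to eGFR itself.
    seed : int
        Master seed; identical config + seed reproduces the cohort exactly.
    """

    n_patients: int = 2000
    progressor_fraction: float = 0.15
    baseline_egfr_range: tuple[float, float] = (50.0, 80.0)
    slope_progressor: tuple[float, float] = (-10.0, 3.0)
    slope_nonprogressor: tuple[float, float] = (-1.0, 1.0)
    egfr_noise_sd: float = 5.0
    visit_gap_mean_days: float = 30.0
    followup_days_range: tuple[float, float] = (540.0, 2190.0)
    missingness_rate: float = 0.3
    variable_catalog: tuple[Variable, ...] = field(default=DEFAULT_CATALOG)
    covariate_signal: bool = True
    seed: int = 0

    def validate(self) -> None:
        import math

        scalars = [
            self.progressor_fraction,
            *self.baseline_egfr_range,
            *self.slope_progressor,
            *self.slope_nonprogressor,
            self.egfr_noise_sd,
            self.visit_gap_mean_days,
            *self.followup_days_range,
            self.missingness_rate,
        ]
        if any(not math.isfinite(x) for x in scalars):
            raise ValueError("non-finite value in generator config")
        if not (0.0 <= self.progressor_fraction <= 1.0):
            raise ValueError("progressor_fraction must be in [0, 1]")
        if not (0.0 <= self.missingness_rate <= 1.0):
            raise ValueError("missingness_rate must be in [0, 1]")
        lo, hi = self.baseline_egfr_range
        if not (30.0 <= lo <= hi <= 89.0):
            raise ValueError("baseline_egfr_range must lie within [30, 89]")
        if self.followup_days_range[0] <= 180:
            raise ValueError("followup minimum must exceed 180 days")
        if self.n_patients == 0 and self.progressor_fraction > 0:
            raise ValueError("progressor_fraction > 0 requires n_patients > 0")
        if self.visit_gap_mean_days <= 1:
            raise ValueError("visit_gap_mean_days must exceed 1 day")


@dataclass
class Cohort:
    """Generated cohort: long observations, static fields, ground truth.

    ``observations`` columns: patient_id, variable, t_days, value.
    ``static`` columns: patient_id, sex, race, age_at_start, followup_days.
    ``ground_truth`` columns: patient_id, progressor — written separately and
    never read by the pipeline.
    """

    observations: pd.DataFrame
    static: pd.DataFrame
    ground_truth: pd.DataFrame


def _behavior_chain(rng: np.random.Generator, n: int, prevalence: float) -> np.ndarray:
    """Two-state Markov chain with stationary marginal ``prevalence``."""
    rho = _BEHAVIOR_PERSISTENCE
    p01 = (1 - rho) * prevalence
    p11 = rho + (1 - rho) * prevalence
    u = rng.random(n)
    s = np.empty(n, dtype=np.int64)
    s[0] = u[0] < prevalence
    for i in range(1, n):
        stay = p11 if s[i - 1] else p01
        s[i] = u[i] < stay
    return s


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a synthetic longitudinal EHR cohort.

    Returns the long-format observation table, per-patient static fields,
    and the ground-truth progressor flags.  Deterministic for fixed config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    root = np.random.default_rng(ss)
    n = config.n_patients

    names_lab_vital = [
        v.name
        for v in config.variable_catalog
        if v.category in (LAB, VITAL) and v.name != "egfr"
    ]
    names_behavior = [v.name for v in config.variable_catalog if v.category == BEHAVIOR]
    has_egfr = any(v.name == "egfr" for v in config.variable_catalog)
    if not has_egfr:
        raise ValueError("variable_catalog must include egfr")

    progressor = root.random(n) < config.progressor_fraction
    sex = root.integers(0, 2, size=n)
    race = root.choice(3, size=n, p=[0.5, 0.35, 0.15])
    age = root.uniform(40.0, 85.0, size=n)

    child_seeds = ss.spawn(n)
    pid_col: list[np.ndarray] = []
    var_col: list[np.ndarray] = []
    t_col: list[np.ndarray] = []
    val_col: list[np.ndarray] = []
    followups = np.empty(n)
    pids = np.array([f"P{i:06d}" for i in range(n)])

    lo_b, hi_b = config.baseline_egfr_range
    for i in range(n):
        rng = np.random.default_rng(child_seeds[i])
        baseline = rng.uniform(lo_b, hi_b)
        if progressor[i]:
            m, s = config.slope_progressor
            slope = float(np.clip(rng.normal(m, s), -20.0, -4.0))
            t_cross = (baseline - 29.0) / (-slope) * 365.0
            followup = t_cross + rng.uniform(200.0, 500.0)
        else:
            m, s = config.slope_nonprogressor
            slope = float(np.clip(rng.normal(m, s), -2.0, 1.0))
            followup = rng.uniform(*config.followup_days_range)
        followups[i] = followup

        # irregular visit times: 1 + Gamma-distributed gaps
        mean_gap = config.visit_gap_mean_days
        n_max = int(followup / mean_gap * 2.5) + 10
        gaps = 1.0 + rng.gamma(2.0, (mean_gap - 1.0) / 2.0, size=n_max)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t <= followup]
        nv = len(t)

        egfr_true = np.maximum(baseline + slope * t / 365.0, 5.0)
        egfr = np.maximum(egfr_true + rng.normal(0.0, config.egfr_noise_sd, nv), 5.0)
        # study entry: the first recorded reading is in stages II/III
        egfr[0] = float(np.clip(egfr[0], 30.0, 89.0))

        keep_masks = {}
        if config.missingness_rate > 0:
            n_vars = 1 + len(names_lab_vital) + len(names_behavior)
            drop = rng.random((n_vars, nv)) < config.missingness_rate
        else:
            drop = None

        vi = 0
        m_e = np.ones(nv, dtype=bool) if drop is None else ~drop[vi]
        m_e[0] = True  # every patient keeps at least one eGFR row
        keep_masks["egfr"] = m_e
        vi += 1

        pid_col.append(np.repeat(pids[i], int(m_e.sum())))
        var_col.append(np.repeat("egfr", int(m_e.sum())))
        t_col.append(t[m_e])
        val_col.append(egfr[m_e])

        for name in names_lab_vital:
            if name == "creatinine" and config.covariate_signal:
                vals = 70.0 / np.maximum(egfr_true, 5.0) + rng.normal(0.0, 0.2, nv)
                vals = np.maximum(vals, 0.3)
            else:
                mu, sd = _LEVELS[name]
                offset = rng.normal(0.0, 0.7 * sd)
                vals = mu + offset + rng.normal(0.0, 0.5 * sd, nv)
                vals = np.maximum(vals, 0.05 * mu)
            m = np.ones(nv, dtype=bool) if drop is None else ~drop[vi]
            vi += 1
            if m.any():
                pid_col.append(np.repeat(pids[i], int(m.sum())))
                var_col.append(np.repeat(name, int(m.sum())))
                t_col.append(t[m])
                val_col.append(vals[m])

        for name in names_behavior:
            vals = _behavior_chain(rng, nv, _PREVALENCE[name]).astype(float)
            m = np.ones(nv, dtype=bool) if drop is None else ~drop[vi]
            vi += 1
            if m.any():
                pid_col.append(np.repeat(pids[i], int(m.sum())))
                var_col.append(np.repeat(name, int(m.sum())))
                t_col.append(t[m])
                val_col.append(vals[m])

    observations = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_col),
            "variable": np.concatenate(var_col),
            "t_days": np.concatenate(t_col),
            "value": np.concatenate(val_col),
        }
    )
    observations = observations.sort_values(
        ["patient_id", "variable", "t_days"], kind="mergesort"
    ).reset_index(drop=True)

    static = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": sex,
            "race": race,
            "age_at_start": np.round(age, 2),
            "followup_days": np.round(followups, 1),
        }
    )
    ground_truth = pd.DataFrame(
        {"patient_id": pids, "progressor": progressor.astype(int)}
    )
    return Cohort(observations, static, ground_truth)


def trajectory_slope_check(
    cohort: Cohort, min_group: int = 10
) -> dict[str, dict[str, float]]:
    """Self-validation: recover per-group mean eGFR slopes by per-patient OLS.

    Fits an ordinary least-squares line eGFR ~ years to each patient's eGFR
    readings and averages the fitted slopes within the progressor and
    non-progressor groups.  Patients with fewer than two readings are
    skipped with a log record.

    Returns ``{"progressor": {...}, "nonprogressor": {...}}`` with keys
    ``mean_slope``, ``se`` (standard error of the group mean), and ``n``.
    """
    egfr = cohort.observations[cohort.observations["variable"] == "egfr"]
    truth = cohort.ground_truth.set_index("patient_id")["progressor"]
    slopes: dict[int, list[float]] = {0: [], 1: []}
    for pid, grp in egfr.groupby("patient_id", sort=True):
        t = grp["t_days"].to_numpy() / 365.0
        v = grp["value"].to_numpy()
        if len(t) < 2:
            logger.info("patient %s skipped in slope check (<2 eGFR readings)", pid)
            continue
        slope = np.polyfit(t, v, 1)[0]
        slopes[int(truth.loc[pid])].append(float(slope))

    out = {}
    for flag, label in ((1, "progressor"), (0, "nonprogressor")):
        vals = np.asarray(slopes[flag])
        if len(vals) == 0:
            raise ValueError(f"no patients in group {label!r}")
        if len(vals) < min_group:
            raise ValueError(
                f"group {label!r} has {len(vals)} patients; need >= {min_group}"
            )
        out[label] = {
            "mean_slope": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            "n": len(vals),
        }
    return out


def single_signal_config(**overrides) -> GeneratorConfig:
    """Config whose only progression signal is the eGFR trajectory itself.

    All covariates are decoupled from eGFR (``covariate_signal=False``); used
    for variable-selection recovery experiments.
    """
    cfg = GeneratorConfig(covariate_signal=False, **overrides)
    return cfg


def essential_catalog() -> tuple[Variable, ...]:
    """The essential-variable catalog (demographics, vitals, 8 labs, 3 behaviors)."""
    return tuple(v for v in DEFAULT_CATALOG if v.essential)


def reduced_catalog(n_noise_labs: int = 4) -> tuple[Variable, ...]:
    """Small catalog for fast experiments: eGFR plus a few other variables.

    Keeps demographics, ``n_noise_labs`` non-eGFR labs/vitals, smoking
    status, and eGFR itself.
    """
    keep = {"sex", "race", "egfr", "smoking_status"}
    extra = [
        v.name
        for v in DEFAULT_CATALOG
        if v.category in (LAB, VITAL) and v.name != "egfr"
    ][:n_noise_labs]
    keep.update(extra)
    return tuple(v for v in DEFAULT_CATALOG if v.name in keep)
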