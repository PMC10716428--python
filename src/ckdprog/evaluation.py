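"""Repeated cross-validation harness and performance metrics.

Each trial draws one stratified random partition of the matched dataset
into ten folds (matched case-control sets stay together by default so twins
never straddle folds), assigns eight folds to training, one to validation,
and one to testing, trains every requested model under its own protocol,
and scores the test fold with AUROC, AUPRC, and MCC (cutoff 0.5).  Race-
stratified AUROC is recorded per trial.  Everything is deterministic for a
fixed plan seed.

Model protocols: the LSTM selects its dropout rate and early-stops on the
validation fold; the Cox models and the random forest merge training and
validation folds (they tune nothing); the boosted-tree model uses the
validation fold to stop boosting rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .assemble import FoldStats, SequenceDataset
from .catalog import TIME_FEATURE
from .models import (
    DynamicCoxModel,
    GBDTModel,
    LSTMClassifier,
    LSTMConfig,
    RandomForestModel,
    StaticCoxModel,
    build_counting_process,
)

logger = logging.getLogger(__name__)

RACE_NAMES = {0: "african_american", 1: "white", 2: "others"}


# ---------------------------------------------------------------------------
# metrics


def auroc(labels, scores) -> float:
    """Probability a random case outranks a random control (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve (step-wise average precision)."""
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPRC requires at least one case")
    return float(average_precision_score(labels, scores))


def mcc(labels, scores, cutoff: float = 0.5) -> float:
    """Matthews correlation at a score cutoff; 0 for degenerate tables."""
    labels = np.asarray(labels, dtype=int)
    pred = np.asarray(scores) >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


# ---------------------------------------------------------------------------
# plan and model specs


@dataclass(frozen=True)
class CVPlan:
    """k-fold plan: 8 train / 1 validation / 1 test roles per trial."""

    k: int = 10
    n_trials: int = 5
    seed: int = 0
    group_by_matched_set: bool = True

    def validate(self) -> None:
        if self.k < 3:
            raise ValueError("k must allow train/val/test roles (k >= 3)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to run and its options (seed is injected per trial)."""

    kind: str
    lstm_config: LSTMConfig = field(default_factory=LSTMConfig)
    n_estimators: int = 300
    penalizer: float = 0.01

    def validate(self) -> None:
        kinds = ("lstm", "cox_static", "cox_dynamic", "random_forest", "gbdt")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")


def default_specs(lstm_config: LSTMConfig | None = None) -> dict[str, ModelSpec]:
    cfg = lstm_config if lstm_config is not None else LSTMConfig()
    return {
        "lstm": ModelSpec("lstm", lstm_config=cfg),
        "random_forest": ModelSpec("random_forest"),
        "gbdt": ModelSpec("gbdt"),
        "cox_dynamic": ModelSpec("cox_dynamic"),
        "cox_static": ModelSpec("cox_static"),
    }


# ---------------------------------------------------------------------------
# partitioning


def _units(ds: SequenceDataset, group: bool) -> tuple[list[np.ndarray], np.ndarray]:
    """Partition units (index arrays) and a per-unit has-case flag."""
    meta = ds.meta
    if group and "set_id" in meta.columns and (meta["set_id"] >= 0).any():
        units, flags = [], []
        for _, grp in meta.groupby("set_id", sort=True):
            idx = grp.index.to_numpy()
            units.append(idx)
            flags.append(int(grp["label"].max()))
        return units, np.asarray(flags)
    idx = np.arange(ds.n)
    return [np.array([i]) for i in idx], meta["label"].to_numpy(dtype=int)


def _deal_folds(units, flags, k, rng) -> list[np.ndarray]:
    """Stratified round-robin assignment of units to k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for stratum in (1, 0):
        sel = [u for u, f in zip(units, flags) if f == stratum]
        order = rng.permutation(len(sel))
        start = int(rng.integers(k))
        for j, ui in enumerate(order):
            folds[(start + j) % k].extend(sel[ui])
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _snapshot(X: np.ndarray, seq_mask: np.ndarray) -> np.ndarray:
    """Latest valid feature vector per sample."""
    last = seq_mask.sum(axis=1).astype(int) - 1
    return X[np.arange(len(last)), last]


def _durations_events(ds: SequenceDataset, t_pre: float):
    """Survival response measured from each patient's first used time point."""
    meta = ds.meta
    time_idx = ds.feature_names.index(TIME_FEATURE)
    T1 = ds.X[:, 0, time_idx]
    events = meta["label"].to_numpy(dtype=int)
    T_tra = meta["T_tra"].to_numpy(dtype=float)
    censor = meta["T_last"].to_numpy(dtype=float) + t_pre - T1
    # a label without a transition time (e.g. under label permutation) keeps
    # its censoring time as the event time
    durations = np.where((events == 1) & np.isfinite(T_tra), T_tra - T1, censor)
    return durations, events


def _cox_columns(ds: SequenceDataset):
    # the Cox models carry time through the hazard axis, not as a covariate
    cols = [c for c in ds.feature_names if c != TIME_FEATURE]
    return cols, [ds.feature_names.index(c) for c in cols]


def _fit_kind(
    spec: ModelSpec,
    ds: SequenceDataset,
    Xz: np.ndarray,
    idx_train: np.ndarray,
    idx_val: np.ndarray,
    t_pre: float,
    seed: int,
):
    y = ds.labels
    mask = ds.seq_mask
    trainval = np.concatenate([idx_train, idx_val])
    cox_cols, cox_j = _cox_columns(ds)

    if spec.kind == "lstm":
        cfg = LSTMConfig(**{**spec.lstm_config.__dict__, "seed": seed})
        return LSTMClassifier(cfg).fit(
            Xz[idx_train], mask[idx_train], y[idx_train],
            Xz[idx_val], mask[idx_val], y[idx_val],
        )
    if spec.kind == "random_forest":
        S = _snapshot(Xz, mask)
        return RandomForestModel(spec.n_estimators, seed=seed).fit(
            S[trainval], y[trainval])
    if spec.kind == "gbdt":
        S = _snapshot(Xz, mask)
        return GBDTModel(seed=seed).fit(
            S[idx_train], y[idx_train], S[idx_val], y[idx_val])

    durations, events = _durations_events(ds, t_pre)
    if spec.kind == "cox_static":
        first = pd.DataFrame(Xz[:, 0, cox_j], columns=cox_cols)
        return StaticCoxModel(spec.penalizer, horizon=t_pre).fit(
            first.iloc[trainval], durations[trainval], events[trainval])
    if spec.kind == "cox_dynamic":
        time_idx = ds.feature_names.index(TIME_FEATURE)
        times = ds.X[:, :, time_idx]  # raw grid midpoints
        long_df = build_counting_process(
            times[trainval], Xz[trainval][:, :, cox_j], mask[trainval],
            durations[trainval], events[trainval], cox_cols)
        return DynamicCoxModel(spec.penalizer, horizon=t_pre).fit(long_df)
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _score_kind(
    model,
    ds: SequenceDataset,
    Xz: np.ndarray,
    idx: np.ndarray,
    t_pre: float,
) -> np.ndarray:
    mask = ds.seq_mask
    if model.kind == "lstm":
        return model.score(Xz[idx], mask[idx])
    if model.kind in ("random_forest", "gbdt"):
        return model.score(_snapshot(Xz, mask)[idx])
    cox_cols, cox_j = _cox_columns(ds)
    if model.kind == "cox_static":
        first = pd.DataFrame(Xz[:, 0, cox_j], columns=cox_cols)
        return model.score(first.iloc[idx])
    if model.kind == "cox_dynamic":
        time_idx = ds.feature_names.index(TIME_FEATURE)
        S = _snapshot(Xz, mask)
        last = pd.DataFrame(S[idx][:, cox_j], columns=cox_cols)
        T1 = ds.X[:, 0, time_idx]
        t_last = ds.meta["T_last"].to_numpy(dtype=float)[idx] - T1[idx]
        return model.score(last, t_last=t_last)
    raise ValueError(f"unknown model kind {model.kind!r}")


def fit_single_model(
    ds: SequenceDataset,
    spec: ModelSpec,
    seed: int = 0,
    t_pre: float = 365.0,
    k: int = 5,
):
    """Fit one model on the whole dataset with an internal validation split.

    One of ``k`` stratified folds (matched sets kept together) serves as the
    validation fold under the model's own protocol.  Returns
    (model, fold_stats) so the model can score newly assembled data.
    """
    spec.validate()
    units, flags = _units(ds, True)
    rng = np.random.default_rng(seed)
    folds = _deal_folds(units, flags, k, rng)
    idx_val = folds[0]
    idx_train = np.concatenate(folds[1:])
    stats = FoldStats.fit(ds, idx_train)
    Xz = stats.transform(ds)
    model = _fit_kind(spec, ds, Xz, idx_train, idx_val, t_pre, seed)
    return model, stats


def score_dataset(model, ds: SequenceDataset, stats: FoldStats,
                  t_pre: float = 365.0) -> np.ndarray:
    """Progression scores for every sample of an assembled dataset."""
    Xz = stats.transform(ds)
    return _score_kind(model, ds, Xz, np.arange(ds.n), t_pre)


def run_trials(
    ds: SequenceDataset,
    specs: dict[str, ModelSpec],
    plan: CVPlan,
    t_pre: float = 365.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run repeated cross-validation trials for every model.

    Returns (results, summary): one row per model per trial with AUROC,
    AUPRC, MCC, race-stratified AUROC and test-fold composition; and the
    per-model mean/sd aggregation over trials.
    """
    plan.validate()
    for spec in specs.values():
        spec.validate()
    y = ds.labels
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")

    units, flags = _units(ds, plan.group_by_matched_set)
    race = ds.meta["race"].to_numpy(dtype=int)
    rows = []
    for trial in range(plan.n_trials):
        seed_t = (plan.seed * 1_000_003 + trial) % (2**31)
        folds = None
        for attempt in range(2):
            rng = np.random.default_rng(seed_t + attempt * 7_919)
            cand = _deal_folds(units, flags, plan.k, rng)
            roles = rng.permutation(plan.k)
            val_f, test_f = int(roles[0]), int(roles[1])
            idx_test = cand[test_f]
            if len(np.unique(y[idx_test])) == 2:
                folds = cand
                break
            logger.warning("trial %d: single-class test fold, resampling once",
                           trial)
        if folds is None:
            raise ValueError(f"trial {trial}: test fold single-class twice")
        idx_val = folds[val_f]
        idx_train = np.concatenate(
            [folds[f] for f in range(plan.k) if f not in (val_f, test_f)])

        stats = FoldStats.fit(ds, idx_train)
        Xz = stats.transform(ds)

        for name, spec in specs.items():
            model = _fit_kind(spec, ds, Xz, idx_train, idx_val, t_pre, seed_t)
            scores = _score_kind(model, ds, Xz, idx_test, t_pre)
            yt = y[idx_test]
            row = {
                "model": name,
                "trial": trial,
                "auroc": auroc(yt, scores),
                "auprc": auprc(yt, scores),
                "mcc": mcc(yt, scores),
                "n_test_cases": int((yt == 1).sum()),
                "n_test_controls": int((yt == 0).sum()),
            }
            for code, rname in RACE_NAMES.items():
                sel = race[idx_test] == code
                if sel.sum() and len(np.unique(yt[sel])) == 2:
                    row[f"auroc_{rname}"] = auroc(yt[sel], scores[sel])
                else:
                    row[f"auroc_{rname}"] = np.nan
                    logger.info("trial %d model %s: race stratum %s skipped",
                                trial, name, rname)
            rows.append(row)

    results = pd.DataFrame(rows)
    metrics = ["auroc", "auprc", "mcc"]
    summary = results.groupby("model")[metrics].agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return results, summary.reset_index()


def race_stratified(results: pd.DataFrame) -> pd.DataFrame:
    """Per-race mean (sd) AUROC per model plus the max pairwise difference.

    Trials where a race stratum was skipped (single class) are excluded
    from that race's mean.
    """
    rows = []
    for model, grp in results.groupby("model"):
        row = {"model": model}
        means = []
        for rname in RACE_NAMES.values():
            col = grp[f"auroc_{rname}"]
            row[f"auroc_{rname}_mean"] = float(col.mean())
            row[f"auroc_{rname}_sd"] = float(col.std())
            row[f"auroc_{rname}_n_trials"] = int(col.notna().sum())
            means.append(float(col.mean()))
        means = [m for m in means if np.isfinite(m)]
        row["max_difference"] = (
            float(max(means) - min(means)) if len(means) >= 2 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def permute_labels(ds: SequenceDataset, seed: int = 0) -> SequenceDataset:
    """Null dataset: labels randomly permuted across samples."""
    rng = np.random.default_rng(seed)
    return ds.with_labels(rng.permutation(ds.labels))
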