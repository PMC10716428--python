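"""Sequential forward variable selection with frequency reporting.

Starting from the time feature alone (always included), each step tries
every not-yet-selected variable inside every cross-validation trial and
adds the one maximizing test-fold AUROC for that trial.  Because trials
may choose different variables, the per-step report gives the selection
frequency of each candidate across trials and the modal choice.  Each
step's per-trial AUROC distribution is compared with the all-variables
model on the same trial partitions by a two-sided paired t-test,
Benjamini-Hochberg adjusted across steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .assemble import SequenceDataset
from .catalog import TIME_FEATURE
from .evaluation import CVPlan, ModelSpec, run_trials

logger = logging.getLogger(__name__)


def paired_compare(aurocs_a, aurocs_b) -> tuple[float, bool]:
    """Two-sided paired t-test p-value on per-trial AUROC differences.

    Returns (p_value, degenerate) where ``degenerate`` flags a zero-variance
    difference vector (identical vectors give p = 1).
    """
    a = np.asarray(aurocs_a, dtype=float)
    b = np.asarray(aurocs_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("AUROC vectors must be trial-aligned (equal length)")
    if len(a) < 3:
        raise ValueError("need at least 3 paired trials")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return (1.0 if np.allclose(d, 0.0) else 0.0), True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_rel(a, b)
    return float(res.pvalue), False


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SelectionPath:
    """Result of forward selection.

    ``steps``: one row per step with the modal variable, mean/sd of the
    per-trial winning AUROC, raw and BH-adjusted p-value vs the
    all-variables reference.  ``frequencies``: long table (step, variable,
    frequency) of per-trial choices; frequencies at each step sum to 1.
    ``trial_choices``: (n_trials, n_steps) chosen variable names.
    """

    steps: pd.DataFrame
    frequencies: pd.DataFrame
    trial_choices: list[list[str]]
    reference_aurocs: np.ndarray

    @property
    def variables(self) -> list[str]:
        return list(self.steps["variable"])


def forward_select(
    ds: SequenceDataset,
    spec: ModelSpec,
    plan: CVPlan,
    max_steps: int,
    t_pre: float = 365.0,
) -> SelectionPath:
    """Run sequential forward selection.

    ``ds`` must be assembled with all candidate variables; the time feature
    is always present and never a candidate.  ``plan.n_trials`` independent
    trials each maintain their own selected set; within a trial, every step
    reuses that trial's fold partition (seeded by plan.seed + trial) for
    every candidate, so candidate comparisons are paired.
    """
    candidates_all = [f for f in ds.feature_names if f != TIME_FEATURE]
    if max_steps > len(candidates_all):
        logger.warning("max_steps %d > %d variables; clipping",
                       max_steps, len(candidates_all))
        max_steps = len(candidates_all)

    n_trials = plan.n_trials

    # reference: all-variables model on each trial's partition
    ref = np.empty(n_trials)
    for t in range(n_trials):
        tp = CVPlan(plan.k, 1, plan.seed + t, plan.group_by_matched_set)
        res, _ = run_trials(ds, {"ref": spec}, tp, t_pre)
        ref[t] = res["auroc"].iloc[0]

    chosen: list[list[str]] = [[] for _ in range(n_trials)]
    step_auroc = np.full((n_trials, max_steps), np.nan)
    freq_rows = []
    step_rows = []
    for step in range(max_steps):
        for t in range(n_trials):
            tp = CVPlan(plan.k, 1, plan.seed + t, plan.group_by_matched_set)
            best_v, best_a = None, -np.inf
            for v in candidates_all:
                if v in chosen[t]:
                    continue
                sub = ds.select_features(chosen[t] + [v, TIME_FEATURE])
                res, _ = run_trials(sub, {"cand": spec}, tp, t_pre)
                a = float(res["auroc"].iloc[0])
                if a > best_a:
                    best_v, best_a = v, a
            chosen[t].append(best_v)
            step_auroc[t, step] = best_a

        picks = pd.Series([chosen[t][step] for t in range(n_trials)])
        freqs = picks.value_counts(normalize=True)
        for v, f in freqs.items():
            freq_rows.append({"step": step + 1, "variable": v,
                              "frequency": float(f)})
        p, _ = paired_compare(step_auroc[:, step], ref)
        step_rows.append({
            "step": step + 1,
            "variable": freqs.index[0],
            "auroc_mean": float(step_auroc[:, step].mean()),
            "auroc_sd": float(step_auroc[:, step].std(ddof=1)),
            "pvalue": p,
        })

    steps = pd.DataFrame(step_rows)
    steps["pvalue_adj"] = bh_adjust(steps["pvalue"].to_numpy())
    return SelectionPath(steps, pd.DataFrame(freq_rows), chosen, ref)


def plot_selection_path(path: SelectionPath, out_file: str,
                        alpha: float = 0.05) -> None:
    """AUROC vs number of selected variables, colored by BH significance.

    Green dots mark steps whose performance still differs significantly
    from the all-variables reference (adjusted p <= alpha); red dots mark
    non-significant differences.  The reference mean is a horizontal line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = path.steps["step"]
    y = path.steps["auroc_mean"]
    sig = path.steps["pvalue_adj"] <= alpha
    ax.errorbar(x, y, yerr=path.steps["auroc_sd"], fmt="none",
                ecolor="gray", alpha=0.6)
    ax.scatter(x[sig], y[sig], color="green", zorder=3,
               label=f"adj. p <= {alpha}")
    ax.scatter(x[~sig], y[~sig], color="red", zorder=3,
               label=f"adj. p > {alpha}")
    ax.axhline(path.reference_aurocs.mean(), color="blue",
               label="all variables")
    ax.set_xlabel("number of selected variables")
    ax.set_ylabel("mean AUROC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_file, dpi=150)
    plt.close(fig)
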