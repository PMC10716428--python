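"""Case-control matching on race, sex, age, and time-series length.

Each valid case is matched with up to ``ratio`` (default four) controls that
agree exactly on race, sex, and sequence length and whose age is within a
tolerance, without replacement.  The default algorithm is greedy in a
seeded random case order, taking the smallest age gaps first; an optimal
variant (maximum-cardinality bipartite b-matching via min-cost max-flow) is
available behind a flag and serves as the oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .assemble import SequenceDataset

EXACT_KEYS = ("race", "sex", "seq_len")


@dataclass(frozen=True)
class MatchSpec:
    """Matching parameters: controls per case, age tolerance (years), seed."""

    ratio: int = 4
    age_tolerance: float = 5.0
    method: str = "greedy"  # or "optimal"
    seed: int = 0

    def validate(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.age_tolerance < 0:
            raise ValueError("age_tolerance must be >= 0")
        if self.method not in ("greedy", "optimal"):
            raise ValueError("method must be 'greedy' or 'optimal'")


@dataclass
class MatchedDataset:
    """Result of matching.

    ``match_table`` has one row per (case_id, control_id) pair with the age
    gap; ``diagnostics`` one row per case with its achieved ratio.  When
    built from a :class:`SequenceDataset`, ``dataset`` holds the matched
    samples with ``set_id`` linking each control to its case.
    """

    match_table: pd.DataFrame
    diagnostics: pd.DataFrame
    dataset: SequenceDataset | None = None


def _eligible(case: pd.Series, controls: pd.DataFrame, spec: MatchSpec) -> pd.DataFrame:
    m = np.ones(len(controls), dtype=bool)
    for k in EXACT_KEYS:
        m &= controls[k].to_numpy() == case[k]
    m &= np.abs(controls["age"].to_numpy() - case["age"]) <= spec.age_tolerance
    return controls[m]


def match_controls(
    cases: pd.DataFrame, controls: pd.DataFrame, spec: MatchSpec = MatchSpec()
) -> MatchedDataset:
    """Match cases to controls on (race, sex, seq_len) exactly and age within
    tolerance.

    ``cases`` and ``controls`` need columns patient_id, race, sex, seq_len,
    age.  Controls are used at most once.  Cases with zero eligible controls
    are retained and flagged in the diagnostics.
    """
    spec.validate()
    dup = set(cases["patient_id"]) & set(controls["patient_id"])
    if dup:
        raise ValueError(f"duplicate patient ids across pools: {sorted(dup)[:5]}")
    # canonical order first: the seeded shuffle then decides case priority,
    # making the result invariant to input row order
    cases = cases.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    controls = controls.sort_values("patient_id", kind="mergesort").reset_index(drop=True)

    if spec.method == "optimal":
        pairs = _optimal_pairs(cases, controls, spec)
    else:
        pairs = _greedy_pairs(cases, controls, spec)

    match_table = pd.DataFrame(pairs, columns=["case_id", "control_id", "age_gap"])
    counts = match_table.groupby("case_id").size() if len(match_table) else pd.Series(dtype=int)
    diagnostics = pd.DataFrame(
        {
            "case_id": cases["patient_id"].to_numpy(),
            "achieved_ratio": [
                int(counts.get(pid, 0)) for pid in cases["patient_id"]
            ],
        }
    )
    diagnostics["unmatched"] = diagnostics["achieved_ratio"] == 0
    return MatchedDataset(match_table, diagnostics)


def _greedy_pairs(cases, controls, spec):
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(cases))
    used: set[str] = set()
    pairs = []
    for i in order:
        case = cases.iloc[i]
        elig = _eligible(case, controls, spec)
        elig = elig[~elig["patient_id"].isin(used)]
        if len(elig) == 0:
            continue
        gaps = np.abs(elig["age"].to_numpy() - case["age"])
        sub = elig.assign(_gap=gaps).sort_values(
            ["_gap", "patient_id"], kind="mergesort"
        )
        for _, ctl in sub.head(spec.ratio).iterrows():
            used.add(ctl["patient_id"])
            pairs.append((case["patient_id"], ctl["patient_id"], float(ctl["_gap"])))
    return pairs


def _optimal_pairs(cases, controls, spec):
    """Maximum total matches; among maxima, minimal total age gap."""
    G = nx.DiGraph()
    G.add_node("s")
    G.add_node("t")
    scale = 1000  # integer costs for min_cost_flow
    for _, case in cases.iterrows():
        cid = ("c", case["patient_id"])
        G.add_edge("s", cid, capacity=spec.ratio, weight=0)
        elig = _eligible(case, controls, spec)
        for _, ctl in elig.iterrows():
            gap = abs(float(ctl["age"]) - float(case["age"]))
            G.add_edge(cid, ("k", ctl["patient_id"]), capacity=1,
                       weight=int(round(gap * scale)))
    for _, ctl in controls.iterrows():
        kid = ("k", ctl["patient_id"])
        if kid in G:
            G.add_edge(kid, "t", capacity=1, weight=0)
    # maximize cardinality first: large negative reward per matched unit
    R = 10_000_000
    H = nx.DiGraph()
    for u, v, d in G.edges(data=True):
        w = d["weight"] - (R if u == "s" else 0)
        H.add_edge(u, v, capacity=d["capacity"], weight=w)
    flow = nx.max_flow_min_cost(H, "s", "t")
    pairs = []
    for _, case in cases.iterrows():
        cid = ("c", case["patient_id"])
        for v, f in flow.get(cid, {}).items():
            if f > 0 and isinstance(v, tuple) and v[0] == "k":
                ctl_age = float(controls.loc[controls["patient_id"] == v[1], "age"].iloc[0])
                pairs.append((case["patient_id"], v[1], abs(ctl_age - float(case["age"]))))
    return pairs


def build_matched_dataset(
    ds: SequenceDataset, spec: MatchSpec = MatchSpec()
) -> MatchedDataset:
    """Match within an assembled dataset and return the modeling subset.

    Keeps every case (matched or not) plus its matched controls; ``set_id``
    in the returned dataset's meta groups each case with its controls so
    cross-validation can keep matched sets in one fold.
    """
    meta = ds.meta
    cases = meta[meta["label"] == 1]
    controls = meta[meta["label"] == 0]
    res = match_controls(cases, controls, spec)

    set_of: dict[str, int] = {}
    for s, pid in enumerate(cases["patient_id"]):
        set_of[pid] = s
    for _, row in res.match_table.iterrows():
        set_of[row["control_id"]] = set_of[row["case_id"]]

    keep_ids = set(cases["patient_id"]) | set(res.match_table["control_id"])
    idx = np.nonzero(meta["patient_id"].isin(keep_ids).to_numpy())[0]
    sub = ds.subset(idx)
    sub.meta["set_id"] = [set_of[p] for p in sub.meta["patient_id"]]
    res.dataset = sub
    return res
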