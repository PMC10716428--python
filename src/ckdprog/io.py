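"""On-disk formats for pipeline stages.

Long observations, static fields, ground truth, and cohort assignments are
plain CSV.  Assembled datasets are a metadata CSV plus one ``.npz`` holding
the padded value array, observation mask, and sequence mask; the pair
round-trips exactly and is byte-deterministic for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assemble import SequenceDataset
from .synthetic import Cohort

OBS_FILE = "observations.csv"
STATIC_FILE = "static.csv"
TRUTH_FILE = "ground_truth.csv"
META_FILE = "meta.csv"
ARRAYS_FILE = "sequences.npz"
FEATURES_FILE = "features.json"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.observations.to_csv(out / OBS_FILE, index=False, float_format="%.6g")
    cohort.static.to_csv(out / STATIC_FILE, index=False)
    # ground truth lives beside the data but is never read by the pipeline
    cohort.ground_truth.to_csv(out / TRUTH_FILE, index=False)


def read_observations(in_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    p = Path(in_dir)
    obs = pd.read_csv(p / OBS_FILE)
    static = pd.read_csv(p / STATIC_FILE)
    return obs, static


def write_dataset(ds: SequenceDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.meta.to_csv(out / META_FILE, index=False, float_format="%.10g")
    np.savez(out / ARRAYS_FILE, X=ds.X, observed=ds.observed,
             seq_mask=ds.seq_mask)
    (out / FEATURES_FILE).write_text(json.dumps(ds.feature_names))


def read_dataset(in_dir: str | Path) -> SequenceDataset:
    p = Path(in_dir)
    meta = pd.read_csv(p / META_FILE)
    arrays = np.load(p / ARRAYS_FILE)
    feature_names = json.loads((p / FEATURES_FILE).read_text())
    return SequenceDataset(arrays["X"], arrays["observed"],
                           arrays["seq_mask"], meta, feature_names)
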