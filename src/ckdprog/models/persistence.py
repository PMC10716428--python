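"""Save/load of trained models as on-disk bundles.

A bundle directory holds ``bundle.json`` (kind + config), the model state
(``weights.npz`` for the LSTM, ``model.joblib`` otherwise), and the
fold statistics used to impute/standardize inputs (``stats.npz``), so a
saved model can score new assembled data.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from ..assemble import FoldStats
from .lstm import LSTMClassifier, LSTMConfig, _Params


def save_model(model, stats: FoldStats, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"kind": model.kind}
    if model.kind == "lstm":
        meta["config"] = {**model.config.__dict__}
        meta["selected_dropout"] = model.selected_dropout
        meta["epochs_run"] = model.epochs_run
        np.savez(out / "weights.npz", **model.params)
    else:
        joblib.dump(model, out / "model.joblib")
    np.savez(out / "stats.npz", medians=stats.medians, means=stats.means,
             sds=stats.sds)
    meta["feature_names"] = list(stats.feature_names)
    (out / "bundle.json").write_text(json.dumps(meta, indent=2))


def load_model(in_dir: str | Path):
    """Returns (model, stats)."""
    p = Path(in_dir)
    meta = json.loads((p / "bundle.json").read_text())
    arrays = np.load(p / "stats.npz")
    stats = FoldStats(arrays["medians"], arrays["means"], arrays["sds"],
                      list(meta["feature_names"]))
    if meta["kind"] == "lstm":
        cfg = dict(meta["config"])
        for key in ("dense_layer_sizes", "dropout_grid"):
            cfg[key] = tuple(cfg[key])
        model = LSTMClassifier(LSTMConfig(**cfg))
        weights = np.load(p / "weights.npz")
        model.params = _Params({k: weights[k] for k in weights.files})
        model.selected_dropout = meta["selected_dropout"]
        model.epochs_run = meta["epochs_run"]
    else:
        model = joblib.load(p / "model.joblib")
    return model, stats
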