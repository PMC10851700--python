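"""CSV/JSON readers and writers for stimuli, sessions, and fit objects.

All tables are UTF-8 CSV with a header row and '.' decimal separator;
fitted objects serialize to JSON with sorted keys so that identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import EncodingFit, ReadoutFit
from .types import StimulusSet


def write_stimuli(stimuli: StimulusSet, path: str | Path) -> None:
    stimuli.to_frame().to_csv(path, index=False)


def read_stimuli(path: str | Path,
                 size_effect: np.ndarray | None = None) -> StimulusSet:
    return StimulusSet.from_frame(pd.read_csv(path), size_effect=size_effect)


def write_sessions(sessions: pd.DataFrame, path: str | Path) -> None:
    sessions.to_csv(path, index=False)


def read_sessions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("chose_small_first", "correct"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        df[col] = df[col].astype(bool)
    return df


def _clean(obj):
    """Make numpy scalars/arrays and NaN JSON-safe."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_clean(obj), fh, sort_keys=True, indent=1)
        fh.write("\n")


def encoding_fit_record(fit: EncodingFit) -> dict:
    return {
        "occlusion_level": fit.occlusion_level,
        "feature_names": list(fit.feature_names),
        "beta": fit.beta,
        "intercept": fit.intercept,
        "penalty": fit.penalty,
        "cv_accuracy": fit.cv_accuracy,
        "cv_sem": fit.cv_sem,
    }


def readout_fit_record(fit: ReadoutFit) -> dict:
    return {
        "observer_id": fit.observer_id,
        "occlusion_level": fit.occlusion_level,
        "beta": fit.beta,
        "intercept": fit.intercept,
        "penalty": fit.penalty,
        "cv_accuracy": fit.cv_accuracy,
        "cv_sem": fit.cv_sem,
        "degenerate": fit.degenerate,
        "chance_level": fit.chance_level,
        "null_quantiles": fit.null_quantiles,
        "bias_fraction": fit.bias_fraction,
    }
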