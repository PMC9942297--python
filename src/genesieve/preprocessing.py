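"""Missing-value imputation and min-max normalization.

Both transforms are fitted on the training partition only and replayed on
validation/test data: missing slots are filled with the training-set slot
mean, then every slot is rescaled to [0, 1] by the training minimum and
maximum (out-of-range values on later data are clipped; a constant training
slot maps to 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import feature_columns


@dataclass
class NormalizationParams:
    """Per-slot training-set statistics: (min, max, mean)."""

    x_min: dict[str, float] = field(default_factory=dict)
    x_max: dict[str, float] = field(default_factory=dict)
    train_mean: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"x_min": self.x_min, "x_max": self.x_max, "train_mean": self.train_mean}, indent=1
        ))

    @classmethod
    def load(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(d["x_min"], d["x_max"], d["train_mean"])


def fit_params(train: pd.DataFrame) -> NormalizationParams:
    """Fit imputation means and min-max bounds on a training feature matrix.

    A slot with no observed value at all in the training data is a hard
    error — there is nothing to impute it from.
    """
    params = NormalizationParams()
    for col in feature_columns(train):
        values = train[col].to_numpy(dtype=float)
        observed = values[~np.isnan(values)]
        if observed.size == 0:
            raise ValueError(f"feature slot {col!r} has no observed value in the training data")
        params.train_mean[col] = float(observed.mean())
        params.x_min[col] = float(observed.min())
        params.x_max[col] = float(observed.max())
    return params


def impute(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Replace NaNs with the fitted training-set slot means."""
    out = matrix.copy()
    for col in feature_columns(out):
        out[col] = out[col].fillna(params.train_mean[col])
    out.attrs.update(matrix.attrs)
    return out


def minmax(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Min-max rescale to [0, 1] with the fitted bounds; degenerate slots
    (min == max) map to 0 and out-of-range values are clipped."""
    out = matrix.copy()
    for col in feature_columns(out):
        lo, hi = params.x_min[col], params.x_max[col]
        if hi > lo:
            out[col] = ((out[col] - lo) / (hi - lo)).clip(0.0, 1.0)
        else:
            out[col] = 0.0
    out.attrs.update(matrix.attrs)
    return out


def fit_transform(train: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationParams]:
    params = fit_params(train)
    return minmax(impute(train, params), params), params


def transform(matrix: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Apply a fitted impute+minmax pipeline to new data (no refitting)."""
    return minmax(impute(matrix, params), params)
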