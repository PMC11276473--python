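"""Tabular input handling, standardization, and result serialization.

Indicator variables are z-scored columns of a participants x indicators
table; outcome variables are z-scored over their observed entries only and
may be missing for individual participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class ZeroVarianceError(ValueError):
    """A column has zero sample variance and cannot be z-scored."""


class MissingColumnError(KeyError):
    """A requested column is absent from the input table."""


class MissingIndicatorError(ValueError):
    """An indicator column contains missing values (complete cases required)."""


@dataclass
class IndicatorMatrix:
    """Standardized participants x indicators score matrix.

    ``values`` holds z-scored scores (column mean 0, sample SD 1);
    ``participant_ids`` and ``indicator_names`` label the axes.
    """

    values: np.ndarray
    participant_ids: list = field(default_factory=list)
    indicator_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError(f"need n >= 2 participants and m >= 1 indicators, got {n} x {m}")
        if not np.all(np.isfinite(self.values)):
            raise MissingIndicatorError(
                "indicator matrix contains missing or non-finite entries; "
                "filter to complete cases before loading"
            )
        if not self.participant_ids:
            self.participant_ids = list(range(n))
        if not self.indicator_names:
            self.indicator_names = [f"x{j + 1}" for j in range(m)]
        if len(self.participant_ids) != n or len(self.indicator_names) != m:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class OutcomeVector:
    """One outcome per participant, z-scored over observed entries.

    ``missing_mask[i]`` is True where participant i lacks this outcome;
    masked entries of ``values`` are NaN and excluded from all analysis.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    name: str = "y"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape or self.values.ndim != 1:
            raise ValueError("values and missing_mask must be matching 1-D arrays")
        if int((~self.missing_mask).sum()) < 2:
            raise ValueError(f"outcome {self.name!r} has fewer than 2 observed values")

    @property
    def observed(self) -> np.ndarray:
        return self.values[~self.missing_mask]


def standardize_columns(raw: np.ndarray) -> np.ndarray:
    """Z-score each column: subtract the mean, divide by the sample SD (n-1).

    Raises :class:`ZeroVarianceError` naming the first constant column.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sd = raw.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ZeroVarianceError(f"column {bad[0]} has zero sample variance; cannot z-score")
    return (raw - raw.mean(axis=0)) / sd


def _standardize_outcome(col: pd.Series, name: str) -> OutcomeVector:
    values = col.to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    obs = values[~mask]
    if obs.size < 2:
        raise ValueError(f"outcome {name!r} has fewer than 2 observed values")
    sd = obs.std(ddof=1)
    if not sd > 0:
        raise ZeroVarianceError(f"outcome column {name!r} has zero sample variance")
    z = np.full_like(values, np.nan)
    z[~mask] = (obs - obs.mean()) / sd
    return OutcomeVector(values=z, missing_mask=mask, name=name)


def load_table(
    path,
    indicator_columns: Sequence[str],
    outcome_columns: Sequence[str] = (),
) -> tuple[IndicatorMatrix, list[OutcomeVector]]:
    """Load a CSV of participants, z-scoring indicators and outcomes.

    Indicators must be fully observed (complete cases); outcomes may be
    missing per participant and are standardized over observed entries only.
    Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in list(indicator_columns) + list(outcome_columns):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} not found in {path.name}")
    raw = df[list(indicator_columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(raw)):
        raise MissingIndicatorError(
            "missing value in an indicator column; drop incomplete cases before loading"
        )
    id_col = df.columns[0] if df.columns[0] not in indicator_columns else None
    ids = df[id_col].tolist() if id_col and id_col not in outcome_columns else list(df.index)
    data = IndicatorMatrix(
        values=standardize_columns(raw),
        participant_ids=ids,
        indicator_names=list(indicator_columns),
    )
    outcomes = [_standardize_outcome(df[c], c) for c in outcome_columns]
    return data, outcomes


def load_config(path) -> dict:
    """Read a YAML/key-value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(obj: dict, path) -> None:
    """Serialize a result dictionary (arrays become lists) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
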