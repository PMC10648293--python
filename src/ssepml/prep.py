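"""IQR normalization and reverse-regression framing.

Features are rescaled robustly, ``x' = (x - median) / (Q3 - Q1)``, with
quartiles estimated by linear interpolation between order statistics.
The anesthetic concentration — the physical *input* of the experiment —
is framed as the regression *output* (reverse regression): models predict
the end-tidal sevoflurane concentration from waveform features. The target
is left in physical vol% units, not normalized.

Leakage control: when a patient-level holdout is declared, normalization
statistics are fitted on training-patient rows only and merely applied to
test rows. A ``fit_on_all`` switch reproduces the alternative in which the
whole consolidated cohort defines the statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import META_COLUMNS, TARGET_COLUMN, nerve_columns, all_feature_columns
from .session import NERVE_MONTAGES


def feature_columns_of(table: pd.DataFrame) -> list[str]:
    """The qualified feature columns present in a table, in canonical order."""
    return [c for c in table.columns if c not in META_COLUMNS and c != TARGET_COLUMN]


@dataclass
class NormalizationParams:
    """Per-feature median and interquartile range fitted on designated rows."""

    median: dict[str, float]
    iqr: dict[str, float]
    zero_iqr: list[str] = field(default_factory=list)  # flagged for exclusion

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"median": self.median, "iqr": self.iqr, "zero_iqr": self.zero_iqr},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(median=d["median"], iqr=d["iqr"], zero_iqr=list(d["zero_iqr"]))


def fit_iqr_normalizer(
    table: pd.DataFrame,
    fit_rows: pd.Series | np.ndarray | None = None,
    columns: list[str] | None = None,
) -> NormalizationParams:
    """Fit per-feature median and IQR (Q3 - Q1, interpolated quartiles).

    ``fit_rows`` is a boolean mask selecting the rows whose statistics are
    used (default: all rows). Features with zero IQR are flagged for
    exclusion rather than producing divide-by-zero transforms.
    """
    cols = columns if columns is not None else feature_columns_of(table)
    sub = table.loc[fit_rows, cols] if fit_rows is not None else table[cols]
    median: dict[str, float] = {}
    iqr: dict[str, float] = {}
    zero: list[str] = []
    for c in cols:
        x = sub[c].dropna().to_numpy(float)
        if x.size == 0:
            raise ValueError(f"feature {c!r} has no values in the fitting rows")
        if x.size < 4:
            raise ValueError(f"feature {c!r}: need >= 4 fitting rows, got {x.size}")
        q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])  # linear interpolation
        median[c] = float(med)
        width = float(q3 - q1)
        iqr[c] = width
        if width == 0.0:
            zero.append(c)
    return NormalizationParams(median=median, iqr=iqr, zero_iqr=zero)


def apply_normalizer(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Return a copy with each feature mapped to ``(x - median)/IQR``.

    Flagged zero-IQR features are dropped; metadata and the target column
    pass through untouched.
    """
    cols = feature_columns_of(table)
    unknown = [c for c in cols if c not in params.median and c not in params.zero_iqr]
    if unknown:
        raise ValueError(f"normalizer has no parameters for column(s) {unknown}")
    out = table.drop(columns=[c for c in params.zero_iqr if c in table.columns])
    out = out.copy()
    for c in feature_columns_of(out):
        out[c] = (out[c] - params.median[c]) / params.iqr[c]
    return out


def invert_normalizer(values: pd.Series | np.ndarray, column: str, params: NormalizationParams):
    """Map normalized values of one feature back to physical units."""
    return np.asarray(values, float) * params.iqr[column] + params.median[column]


def make_regression_problem(
    table: pd.DataFrame, nerve: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor matrix and concentration target for one nerve (or all four).

    For a single nerve the predictors are its 33 qualified features (rows
    restricted to that nerve's trials); with ``nerve=None`` the 132-column
    universe is returned. The target ``y`` is the synchronized end-tidal
    sevoflurane concentration, untouched.
    """
    if TARGET_COLUMN not in table.columns:
        raise ValueError(f"table has no target column {TARGET_COLUMN!r}")
    if nerve is None:
        cols = [c for c in all_feature_columns() if c in table.columns]
        rows = table
    else:
        if nerve not in NERVE_MONTAGES:
            raise ValueError(f"unknown nerve {nerve!r}")
        if "nerve" in table.columns:
            rows = table[table["nerve"] == nerve]
            if rows.empty:
                raise ValueError(f"no rows for nerve {nerve!r}")
        else:
            rows = table
        cols = [c for c in nerve_columns(nerve) if c in rows.columns]
        if not cols:
            raise ValueError(f"no feature columns for nerve {nerve!r} in the table")
    X = rows[cols].copy()
    y = rows[TARGET_COLUMN].copy()
    if y.isna().any():
        raise ValueError("target column contains missing values")
    return X, y
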