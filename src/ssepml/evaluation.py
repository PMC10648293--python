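"""Cross-validated training, patient-level holdout, and the model tournament.

The evaluation protocol mirrors a small-cohort clinical study: a fixed
number of patients (default 2 of 10) is set aside untouched for testing;
the remaining patients' synchronized trials are cross-validated (default
5-fold) to pick a winner by validation RMSE; only the winner is then
refitted on all training rows and scored once on the held-out patients.

Validation metrics (RMSE, MSE, MAE, R^2) are computed on the *pooled*
out-of-fold predictions, so R^2 can be negative for models worse than the
training mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

from .features import META_COLUMNS, TARGET_COLUMN
from .models import PRESET_ORDER, ModelSpec, TrainedModel, predict, train
from .prep import (
    NormalizationParams,
    apply_normalizer,
    fit_iqr_normalizer,
    make_regression_problem,
)
from .mrmr import MRMRResult, mrmr_rank, select_features


@dataclass
class SplitPlan:
    """Patient-level holdout plus fold assignment for the training rows."""

    train_patients: list[str]
    test_patients: list[str]
    cv_folds: int = 5
    seed: int = 0
    grouped_cv: bool = False  # patient-grouped folds instead of trial-level folds

    def __post_init__(self) -> None:
        overlap = set(self.train_patients) & set(self.test_patients)
        if overlap:
            raise ValueError(f"patients in both train and test sets: {sorted(overlap)}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def make_split_plan(
    patient_ids: list[str],
    n_test: int = 2,
    cv_folds: int = 5,
    seed: int = 0,
    grouped_cv: bool = False,
) -> SplitPlan:
    """Seeded random patient-level split (``n_test`` held-out patients)."""
    ids = sorted(set(patient_ids))
    if n_test < 1 or n_test >= len(ids):
        raise ValueError("n_test must leave at least one training patient")
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(ids, size=n_test, replace=False).tolist())
    train_ids = [p for p in ids if p not in test]
    return SplitPlan(train_ids, test, cv_folds=cv_folds, seed=seed, grouped_cv=grouped_cv)


def _fold_indices(
    n_rows: int, plan: SplitPlan, groups: np.ndarray | None
) -> list[tuple[np.ndarray, np.ndarray]]:
    if plan.grouped_cv:
        if groups is None:
            raise ValueError("grouped CV requires patient groups")
        splitter = GroupKFold(n_splits=plan.cv_folds)
        return list(splitter.split(np.zeros(n_rows), groups=groups))
    splitter = KFold(n_splits=plan.cv_folds, shuffle=True, random_state=plan.seed)
    return list(splitter.split(np.zeros(n_rows)))


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    return {
        "rmse": float(np.sqrt(mse)),
        "mse": mse,
        "mae": float(np.mean(np.abs(err))),
        "r2": 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("nan"),
    }


def crossvalidate(
    spec: ModelSpec | str,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    plan: SplitPlan,
    groups: np.ndarray | None = None,
) -> dict:
    """Pooled out-of-fold validation metrics for one preset.

    Every training row is predicted exactly once by a model that never saw
    it; RMSE/MSE/MAE/R^2 are computed on that pooled prediction vector.
    """
    yv = np.asarray(y, float).ravel()
    folds = _fold_indices(len(X), plan, groups)
    for _, va in folds:
        if va.size < 2:
            raise ValueError("a fold has fewer than 2 validation rows")
    oof = np.full(yv.size, np.nan)
    per_fold: list[dict[str, float]] = []
    for tr, va in folds:
        model = train(spec, X.iloc[tr], yv[tr], seed=plan.seed)
        pred = predict(model, X.iloc[va])
        oof[va] = pred
        per_fold.append(_metrics(yv[va], pred))
    assert not np.isnan(oof).any(), "folds must cover every training row once"
    out = _metrics(yv, oof)
    out["per_fold"] = per_fold
    out["oof_predictions"] = oof
    return out


def holdout_test(
    model: TrainedModel, X_test: pd.DataFrame, y_test: pd.Series | np.ndarray
) -> float:
    """RMSE of a fitted model over all synchronized trials of the test patients."""
    yv = np.asarray(y_test, float).ravel()
    if yv.size == 0:
        raise ValueError("holdout test set is empty")
    pred = predict(model, X_test)
    return float(np.sqrt(np.mean((yv - pred) ** 2)))


@dataclass
class EvalReport:
    """Tournament report card for one nerve."""

    nerve: str | None
    selected_features: list[str]
    mrmr: MRMRResult
    normalizer: NormalizationParams
    validation: dict[str, dict]  # preset -> pooled CV metrics
    winner: str
    rmse_test: float
    test_predictions: np.ndarray
    test_truth: np.ndarray
    plan: SplitPlan = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """One row per preset: validation RMSE/R^2/MSE/MAE (+ test RMSE for the winner)."""
        rows = []
        for name in self.validation:
            m = self.validation[name]
            rows.append(
                {
                    "model": name,
                    "rmse_validation": m["rmse"],
                    "r2_validation": m["r2"],
                    "mse_validation": m["mse"],
                    "mae_validation": m["mae"],
                    "rmse_test": self.rmse_test if name == self.winner else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("model")


def model_tournament(
    table: pd.DataFrame,
    nerve: str | None,
    plan: SplitPlan,
    presets: tuple[str, ...] = PRESET_ORDER,
    k: int = 10,
    fit_normalizer_on_all: bool = False,
    mrmr_bins: int | None = None,
) -> EvalReport:
    """Full per-nerve pipeline: normalize, rank, cross-validate, test the winner.

    Normalization and MRMR are fitted on training-patient rows only (unless
    ``fit_normalizer_on_all``); all presets are cross-validated on the
    training rows; the winner (lowest validation RMSE, ties to the earlier
    preset in listing order) is refitted on all training rows and scored on
    the held-out patients.
    """
    if len(presets) < 2:
        raise ValueError("a tournament needs at least 2 presets")
    if "patient_id" not in table.columns:
        raise ValueError("table must carry a patient_id column")
    known = set(table["patient_id"])
    for pid in plan.train_patients + plan.test_patients:
        if pid not in known:
            raise ValueError(f"plan references unknown patient {pid!r}")

    is_train = table["patient_id"].isin(plan.train_patients)
    is_test = table["patient_id"].isin(plan.test_patients)
    if nerve is not None:
        in_nerve = table["nerve"] == nerve
        is_train &= in_nerve
        is_test &= in_nerve

    # restrict to metadata + this nerve's features + target before normalizing
    feature_cols = list(make_regression_problem(table, nerve)[0].columns)
    keep = [c for c in table.columns if c in META_COLUMNS or c == TARGET_COLUMN]
    sub = table.loc[is_train | is_test, keep + feature_cols].reset_index(drop=True)
    fit_mask = (
        np.ones(len(sub), bool)
        if fit_normalizer_on_all
        else sub["patient_id"].isin(plan.train_patients).to_numpy()
    )
    norm = fit_iqr_normalizer(sub, fit_rows=fit_mask, columns=feature_cols)
    normalized = apply_normalizer(sub, norm)

    train_rows = normalized[normalized["patient_id"].isin(plan.train_patients)]
    test_rows = normalized[normalized["patient_id"].isin(plan.test_patients)]
    X_tr, y_tr = make_regression_problem(train_rows, nerve)
    X_te, y_te = make_regression_problem(test_rows, nerve)

    ranking = mrmr_rank(X_tr, y_tr, k=min(k, X_tr.shape[1]), bins=mrmr_bins)
    X_tr_sel = select_features(ranking, X_tr)
    X_te_sel = select_features(ranking, X_te)

    groups = train_rows["patient_id"].to_numpy() if plan.grouped_cv else None
    validation: dict[str, dict] = {}
    for preset in presets:
        validation[preset] = crossvalidate(preset, X_tr_sel, y_tr, plan, groups)

    winner = min(presets, key=lambda p: (validation[p]["rmse"], presets.index(p)))
    final = train(winner, X_tr_sel, y_tr, seed=plan.seed)
    rmse_test = holdout_test(final, X_te_sel, y_te)
    return EvalReport(
        nerve=nerve,
        selected_features=ranking.order,
        mrmr=ranking,
        normalizer=norm,
        validation=validation,
        winner=winner,
        rmse_test=rmse_test,
        test_predictions=predict(final, X_te_sel),
        test_truth=np.asarray(y_te, float),
        plan=plan,
    )
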