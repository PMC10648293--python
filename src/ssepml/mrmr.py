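"""Minimum-redundancy maximum-relevance (MRMR) feature ranking.

Greedy forward selection on a plug-in mutual-information (MI) estimate:
the first pick maximizes relevance MI(feature; target); each subsequent pick
maximizes the quotient score

    relevance / (mean MI with already-selected features + eps)

MI is estimated on a joint histogram with *equal-frequency* bin edges per
variable (bins = min(10, ceil(sqrt(n)))), which makes the estimator
deterministic and invariant to monotone rescaling of either variable.
Features whose relevance does not exceed a configurable threshold (default
0) are reported as insignificant; selection retains at most the significant
ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to an equal-frequency bin (0..n_bins-1)."""
    # rank-based binning: ties share the bin of their average rank
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return np.minimum((ranks * n_bins) // x.size, n_bins - 1).astype(np.intp)


def default_bins(n: int) -> int:
    return min(10, math.ceil(math.sqrt(n)))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) on equal-frequency binned marginals.

    Symmetric and non-negative; a constant vector has MI 0 by convention.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    n_bins = bins if bins is not None else default_bins(x.size)
    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (bx, by), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


@dataclass
class MRMRResult:
    """Greedy selection order with per-feature scores.

    ``order`` is the greedy selection order (not score-sorted — greedy
    quotient scores may fluctuate); ``n_significant`` counts features whose
    relevance exceeded the significance threshold.
    """

    order: list[str]
    scores: dict[str, float]
    relevance: dict[str, float]
    n_significant: int


def mrmr_rank(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 10,
    bins: int | None = None,
    significance_threshold: float = 0.0,
) -> MRMRResult:
    """Rank up to ``k`` features by greedy quotient MRMR.

    Deterministic: exact score ties break toward the earlier column. Features
    whose relevance MI is <= ``significance_threshold`` are insignificant and
    never enter the ranking (mirroring datasets where fewer than ``k``
    features receive an importance score).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    cols = list(X.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the {len(cols)} available features")
    yv = np.asarray(y, float).ravel()
    relevance = {c: mutual_information(X[c].to_numpy(float), yv, bins) for c in cols}
    significant = [c for c in cols if relevance[c] > significance_threshold]
    n_sig = len(significant)
    if n_sig == 0:
        logger.warning("mrmr_rank: no feature has relevance above the threshold")
        return MRMRResult(order=[], scores={}, relevance=relevance, n_significant=0)

    mi_cache: dict[tuple[str, str], float] = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mutual_information(
                X[a].to_numpy(float), X[b].to_numpy(float), bins
            )
        return mi_cache[key]

    order: list[str] = []
    scores: dict[str, float] = {}
    remaining = list(significant)
    while remaining and len(order) < min(k, n_sig):
        best_col, best_score = None, -np.inf
        for c in remaining:  # column order is the deterministic tie-break
            if order:
                redundancy = float(np.mean([pair_mi(c, s) for s in order]))
                score = relevance[c] / (redundancy + _EPS)
            else:
                score = relevance[c]
            if score > best_score:
                best_col, best_score = c, score
        order.append(best_col)
        scores[best_col] = float(best_score)
        remaining.remove(best_col)
    return MRMRResult(order=order, scores=scores, relevance=relevance, n_significant=n_sig)


def select_features(result: MRMRResult, X: pd.DataFrame) -> pd.DataFrame:
    """Reduce ``X`` to the ranked features, in selection order.

    Retains ``min(k, n_significant)`` columns — i.e. exactly the columns in
    ``result.order``. An empty ranking yields an empty table with a warning.
    """
    missing = [c for c in result.order if c not in X.columns]
    if missing:
        raise ValueError(f"ranking refers to columns absent from X: {missing}")
    if not result.order:
        logger.warning("select_features: empty ranking, returning no columns")
    return X[result.order].copy()
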