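"""Independent brute-force oracles shared by the test modules."""

import numpy as np
import pandas as pd


def oracle_mi(x, y, bins):
    """Histogram MI via marginal/joint entropies on quantile bin edges."""

    def edges(v):
        return np.quantile(v, np.linspace(0, 1, bins + 1))

    h, _, _ = np.histogram2d(x, y, bins=[edges(x), edges(y)])
    p = h / h.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    return entropy(px) + entropy(py) - entropy(p.ravel())


def oracle_greedy_mrmr(X: pd.DataFrame, y, k, bins):
    """Exhaustive greedy quotient-MRMR with explicit loops."""
    cols = list(X.columns)
    rel = {c: oracle_mi(X[c].to_numpy(), np.asarray(y), bins) for c in cols}
    chosen = []
    while len(chosen) < k and len(chosen) < len(cols):
        best, best_score = None, -np.inf
        for c in cols:
            if c in chosen:
                continue
            if chosen:
                red = np.mean(
                    [oracle_mi(X[c].to_numpy(), X[s].to_numpy(), bins) for s in chosen]
                )
                score = rel[c] / (red + 1e-12)
            else:
                score = rel[c]
            if score > best_score:
                best, best_score = c, score
        chosen.append(best)
    return chosen


def oracle_polygon_area(points: np.ndarray) -> float:
    """Absolute signed area of a closed polygon as a fan of origin triangles."""
    signed = 0.0
    n = len(points)
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        signed += 0.5 * (x1 * y2 - x2 * y1)
    return abs(signed)
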