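"""Independent brute-force oracles for the spline engine.

These deliberately share no code path with the engine: candidate
enumeration plus plain least squares, nothing incremental.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def candidate_grid(x: np.ndarray, min_span: int) -> np.ndarray:
    xs = np.sort(np.asarray(x, dtype=float))
    if min_span > 0:
        if xs.size <= 2 * min_span:
            return xs[:0]
        xs = xs[min_span : xs.size - min_span]
    return np.unique(xs)


def ols_rss(B: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    r = y - B @ coef
    return float(r @ r)


def best_single_pair(X: pd.DataFrame, y: np.ndarray, min_span: int):
    """Exhaustive search over (variable, knot) for one reflected hinge pair."""
    n = len(y)
    best = None
    for var in X.columns:
        x = X[var].to_numpy(dtype=float)
        for t in candidate_grid(x, min_span):
            B = np.column_stack(
                [np.ones(n), np.maximum(x - t, 0.0), np.maximum(t - x, 0.0)]
            )
            rss = ols_rss(B, y)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, var, float(t))
    return best


def best_subset_gcv(model, X: pd.DataFrame, y: np.ndarray, config):
    """Exhaustive minimum-GCV subset of a fitted model's basis terms."""
    from heatthresh.mars import gcv_score

    n = len(y)
    cols = [t.design_column(X) for t in model.terms]
    best = None
    for mask in itertools.product([0, 1], repeat=len(cols)):
        kept = [c for c, m in zip(cols, mask) if m]
        B = np.column_stack([np.ones(n)] + kept) if kept else np.ones((n, 1))
        rss = ols_rss(B, y)
        knots = {
            (f.variable, f.knot)
            for t, m in zip(model.terms, mask)
            if m
            for f in t.factors
        }
        g = gcv_score(rss, n, sum(mask), len(knots), config.penalty)
        if best is None or g < best[0] - 1e-12:
            best = (g, mask)
    return best
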