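"""Weighted k-nearest-neighbor firing-rate maps.

Nonparametric rate estimates over 2-D covariate spaces (hand position,
previous movement vector, upcoming movement vector). The estimate at a
query point averages the rates of its k Euclidean nearest training
points, each weighted by distance to the power d (d=0: unweighted mean;
d=-1: inverse-distance). Defaults follow the two canonical settings:
(k=20% of points, d=0) for GLM covariates and (k=30%, d=-1) for maps
used directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SmoothedMap", "SmoothParams", "select_smoothing_params",
           "GLM_SMOOTH", "MAP_SMOOTH"]

#: floor on distances before raising to a negative power (cm)
DIST_FLOOR = 1e-6


@dataclass(frozen=True)
class SmoothParams:
    k_fraction: float
    d: float

    def __post_init__(self):
        if not (0.0 < self.k_fraction <= 1.0):
            raise ValueError("k_fraction must be in (0, 1]")


GLM_SMOOTH = SmoothParams(k_fraction=0.20, d=0.0)
MAP_SMOOTH = SmoothParams(k_fraction=0.30, d=-1.0)


class SmoothedMap:
    """k-NN rate map over a 2-D covariate.

    Parameters
    ----------
    points : (n, 2) training covariates (cm).
    rates : (n,) associated firing rates (or counts).
    params : SmoothParams with k as a fraction of n and decay exponent d.
    tag : which variable this map smooths over
        ("position", "upcoming_movement", "previous_movement").
    window : free-form label of the time window the rates came from.
    """

    def __init__(self, points, rates, params: SmoothParams = MAP_SMOOTH,
                 tag: str = "position", window: str = ""):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rates = np.asarray(rates, dtype=float)
        if points.shape[0] != rates.shape[0]:
            raise ValueError("points and rates must have equal length")
        if points.shape[0] == 0:
            raise ValueError("cannot fit a map on zero points")
        self.points = points
        self.rates = rates
        self.params = params
        self.tag = tag
        self.window = window
        self.n = points.shape[0]
        self.k = max(1, int(round(params.k_fraction * self.n)))
        if self.k > self.n:
            raise ValueError("k exceeds number of training points")
        self._tree = cKDTree(points)

    def predict(self, queries) -> np.ndarray:
        """Smoothed rate at each query point (vectorized)."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        if not np.all(np.isfinite(q)):
            raise ValueError("queries must be finite")
        dist, idx = self._tree.query(q, k=self.k)
        if self.k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        if self.params.d == 0.0:
            w = np.ones_like(dist)
        else:
            w = np.maximum(dist, DIST_FLOOR) ** self.params.d
        w = w / w.sum(axis=1, keepdims=True)
        return np.sum(w * self.rates[idx], axis=1)

    def predict_one(self, query) -> float:
        return float(self.predict(np.asarray(query, dtype=float)[None, :])[0])

    def grid(self, half_width: float, spacing: float = 0.5):
        """Evaluate on a square grid (for position-activity maps).

        Returns (xs, ys, Z) with Z[i, j] the rate at (xs[j], ys[i])."""
        xs = np.arange(-half_width, half_width + spacing / 2, spacing)
        ys = xs.copy()
        gx, gy = np.meshgrid(xs, ys)
        z = self.predict(np.column_stack([gx.ravel(), gy.ravel()]))
        return xs, ys, z.reshape(gy.shape)


def select_smoothing_params(points, rates, candidates=None, n_folds: int = 5,
                            rng=None):
    """Choose (k_fraction, d) by 5-fold cross-validated squared error.

    Held-out points are smoothed using neighbors from the training fold
    only. Ties break toward larger k (the smoother map). Returns the
    chosen SmoothParams and the CV curve as a list of
    (params, mean_squared_error).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rates = np.asarray(rates, dtype=float)
    n = points.shape[0]
    if n < 50:
        raise ValueError("need at least 50 points for CV selection")
    if candidates is None:
        candidates = [SmoothParams(kf, d)
                      for kf in (0.05, 0.1, 0.2, 0.3, 0.5)
                      for d in (0.0, -1.0)]
    rng = rng or np.random.default_rng(0)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    curve = []
    for cand in candidates:
        sse, cnt = 0.0, 0
        for f in folds:
            train = np.setdiff1d(order, f, assume_unique=False)
            m = SmoothedMap(points[train], rates[train], cand)
            pred = m.predict(points[f])
            sse += float(np.sum((pred - rates[f]) ** 2))
            cnt += len(f)
        curve.append((cand, sse / cnt))
    best_err = min(e for _, e in curve)
    # tie-break toward larger k among near-minimal candidates
    best = max((c for c, e in curve if e <= best_err * (1 + 1e-12)),
               key=lambda c: c.k_fraction)
    return best, curve
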