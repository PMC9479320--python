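"""scikit-learn transformer wrappers around the topological stages.

Each estimator operates on a *collection* of samples (a list or 3D array of
image patches, a list of point clouds, or a list of persistence diagrams) and
composes with :class:`sklearn.pipeline.Pipeline`::

    Pipeline([
        ("ph", CubicalPersistence()),
        ("curve", BettiCurveTransformer(k=0, n_bins=64)),
    ]).fit_transform(patches)

Fitting is stateless except for :class:`BettiCurveTransformer`, which learns
the threshold range of the training diagrams so transformed curves share a
common grid (a fixed-width feature matrix usable by downstream sklearn
models).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError
from .filtration import vietoris_rips
from .persistence import (
    cubical_persistence,
    diagram_to_betti_curve,
    reduce_complex,
)
from .preprocess import HuWindow, mask_hu, points_from_mask
from .summaries import diagonal_stats

__all__ = [
    "HuMasker",
    "MaskToPointCloud",
    "VietorisRipsPersistence",
    "CubicalPersistence",
    "BettiCurveTransformer",
    "DiagramSummaryTransformer",
]


class HuMasker(TransformerMixin, BaseEstimator):
    """Threshold each HU patch to a boolean window mask."""

    def __init__(self, lo: float = -190.0, hi: float = -30.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y=None):
        HuWindow(self.lo, self.hi)  # validates
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        window = HuWindow(self.lo, self.hi)
        return [mask_hu(x, window) for x in X]


class MaskToPointCloud(TransformerMixin, BaseEstimator):
    """Convert boolean masks to (n, 2) planar point clouds."""

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [points_from_mask(m) for m in X]


class VietorisRipsPersistence(TransformerMixin, BaseEstimator):
    """Persistence diagrams of point clouds via the Rips filtration."""

    def __init__(self, eps_max: float = 10.0, max_dim: int = 2,
                 keep_zero: bool = False):
        self.eps_max = eps_max
        self.max_dim = max_dim
        self.keep_zero = keep_zero

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [
            reduce_complex(
                vietoris_rips(pts, eps_max=self.eps_max, max_dim=self.max_dim),
                keep_zero=self.keep_zero,
                validate=False,
            )
            for pts in X
        ]


class CubicalPersistence(TransformerMixin, BaseEstimator):
    """Persistence diagrams of grayscale patches via the sublevel cubical
    filtration (fast union-find path)."""

    def __init__(self, keep_zero: bool = False, apply_shift: bool = True):
        self.keep_zero = keep_zero
        self.apply_shift = apply_shift

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        return [
            cubical_persistence(
                x, keep_zero=self.keep_zero, apply_shift=self.apply_shift
            )
            for x in X
        ]


class BettiCurveTransformer(TransformerMixin, BaseEstimator):
    """Sample dim-k Betti curves of diagrams on a shared threshold grid.

    The grid is learned from the training diagrams' finite critical values
    (padded one step below the minimum so every curve starts at 0) and stored
    in ``grid_``; ``transform`` returns an (n_samples, n_bins) integer matrix.
    """

    def __init__(self, k: int = 0, n_bins: int = 100):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y=None):
        vals = []
        for dg in X:
            finite = dg.deaths[np.isfinite(dg.deaths)]
            vals.append(dg.births)
            vals.append(finite)
        vals = np.concatenate(vals) if vals else np.empty(0)
        if len(vals) == 0:
            raise InputError("cannot fit a threshold grid on empty diagrams")
        lo, hi = float(vals.min()), float(vals.max())
        span = (hi - lo) or 1.0
        self.grid_ = np.linspace(lo - 0.05 * span, hi, self.n_bins)
        return self

    def transform(self, X):
        if not hasattr(self, "grid_"):
            raise InputError("BettiCurveTransformer is not fitted")
        return np.vstack(
            [diagram_to_betti_curve(dg, self.k, self.grid_).values for dg in X]
        )


class DiagramSummaryTransformer(TransformerMixin, BaseEstimator):
    """Per-diagram features: [mean persistence, median diagonal distance,
    interval count] of dimension ``k`` (NaN when no finite interval)."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        rows = []
        for dg in X:
            stats = diagonal_stats(dg, self.k)
            if stats is None:
                rows.append([np.nan, np.nan, 0.0])
            else:
                rows.append(
                    [stats.mean_persistence, stats.median_diagonal_distance,
                     float(stats.n_intervals)]
                )
        return np.asarray(rows)
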