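"""scikit-learn style estimators wrapping the pipeline primitives.

These compose with sklearn pipelines and model selection; the
module-level functions (`enhanced_lee_filter`, `classify_cv`, `sieve`,
`roc_sweep`, ...) remain thin functional surfaces over the same code.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import BinaryCropMap, CVRaster
from .grid import SceneGrid
from .lee import enhanced_lee_filter
from .sieve import sieve as _sieve

__all__ = ["EnhancedLeeFilter", "CVThresholdClassifier", "SieveFilter"]


def _dummy_grid(height: int, width: int) -> SceneGrid:
    return SceneGrid(0.0, 0.0, 1.0, -1.0, width, height, "EPSG:0")


class EnhancedLeeFilter(TransformerMixin, BaseEstimator):
    """Adaptive enhanced Lee despeckling as a stateless transformer.

    ``transform`` accepts a single 2-D intensity image or a
    ``(n_images, height, width)`` stack and filters each image
    independently (the filter is per-date; nothing is shared in time).
    """

    def __init__(self, window_size: int = 7, looks_L: float = 9.0, damping: float = 1.0):
        self.window_size = window_size
        self.looks_L = looks_L
        self.damping = damping

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0  # stateless; nothing learned
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return enhanced_lee_filter(X, self.window_size, self.looks_L, self.damping)
        if X.ndim == 3:
            return np.stack(
                [
                    enhanced_lee_filter(img, self.window_size, self.looks_L, self.damping)
                    for img in X
                ]
            )
        raise ValueError("expected a 2-D image or a (n, h, w) stack")


class CVThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Crop/non-crop classifier thresholding per-pixel temporal CV values.

    With ``cv_thr`` set, ``fit`` only records it.  With ``cv_thr=None``,
    ``fit(X, y)`` sweeps thresholds from ``thr_min`` to ``thr_max`` in
    ``step`` increments against binary labels ``y`` and selects the
    threshold maximizing the Youden J statistic (ties toward the smallest
    threshold), mirroring the ROC selection procedure.

    Attributes
    ----------
    threshold_ : float
        The operating CV threshold after fitting.
    roc_table_ : pandas.DataFrame
        Per-threshold metrics (only when the sweep ran).
    """

    def __init__(
        self,
        cv_thr: float | None = None,
        thr_min: float = 0.0,
        thr_max: float = 1.0,
        step: float = 0.01,
    ):
        self.cv_thr = cv_thr
        self.thr_min = thr_min
        self.thr_max = thr_max
        self.step = step

    def fit(self, X, y=None):
        from .assessment import roc_sweep

        self.classes_ = np.array([0, 1])
        if self.cv_thr is not None:
            if not self.cv_thr > 0:
                raise ValueError("cv_thr must be positive")
            self.threshold_ = float(self.cv_thr)
            return self
        if y is None:
            raise ValueError("fitting without cv_thr requires labels y")
        cv = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y).reshape(-1)
        if cv.shape != y.shape:
            raise ValueError("X and y must have the same length")
        # package the samples as a 1-row raster so one sweep code path exists
        grid = _dummy_grid(1, cv.size)
        cvr = CVRaster(
            grid,
            cv=cv[None, :],
            sigma=np.zeros_like(cv)[None, :],
            mu=np.ones_like(cv)[None, :],
            n_valid_dates=np.full((1, cv.size), 2),
        )
        truth = BinaryCropMap(grid, y.astype(np.uint8)[None, :])
        self.roc_table_, self.threshold_ = roc_sweep(
            cvr, truth, self.thr_min, self.thr_max, self.step
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        cv = np.asarray(X, dtype=float)
        shape = cv.shape if cv.ndim != 2 or cv.shape[1] != 1 else (cv.shape[0],)
        return (cv.reshape(shape) >= self.threshold_).astype(int)


class SieveFilter(TransformerMixin, BaseEstimator):
    """Small-component removal as a stateless transformer on label rasters."""

    def __init__(self, min_size: int = 20, connectivity: int = 4):
        self.min_size = min_size
        self.connectivity = connectivity

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.uint8)
        if X.ndim != 2:
            raise ValueError("expected a 2-D label raster")
        cmap = BinaryCropMap(_dummy_grid(*X.shape), X)
        return _sieve(cmap, self.min_size, self.connectivity).labels
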