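"""End-to-end AIF detection as a scikit-learn-style estimator."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .cluster import (
    AgglomerativeCurveCluster,
    ClusterAssignment,
    CurveKMeans,
    FuzzyCMeans,
)
from .select import select_aif, shape_metrics
from .simulate import TimeGrid

__all__ = ["AifDetector"]


class AifDetector(BaseEstimator):
    """Detect the arterial input function from a set of concentration curves.

    Clusters the curves into ``n_clusters`` groups with the chosen back-end,
    scores every cluster mean by M = H_P/(T_P·FWHM) and keeps the mean curve
    of the maximal-M cluster as the AIF.

    Parameters
    ----------
    method : {'ah', 'kmeans', 'fcm'}
        Clustering back-end. 'ah' (agglomerative hierarchy, average linkage)
        is deterministic; the other two depend on ``random_state``.
    n_clusters : int, default 5
    random_state : int or None
        Seed for the iterative back-ends; ignored by 'ah'.
    dt, t_start : float
        Time axis of the input curves (uniform sampling).
    upsample_dt : float, default 0.01
        Interpolation step for the shape metrics.

    Attributes (after ``fit``)
    --------------------------
    labels_ : (n_curves,) cluster index per curve
    cluster_means_ : (k, n_times)
    metrics_ : per-cluster :class:`~dscaif.select.ShapeMetrics` (None where
        invalid)
    selected_cluster_ : int — index of the maximal-M cluster
    selected_mask_ : boolean mask of curves in the selected cluster
    aif_ : (n_times,) the detected AIF curve
    """

    def __init__(self, method: str = "ah", n_clusters: int = 5,
                 random_state: int | None = None, dt: float = 1.0,
                 t_start: float = 0.0, upsample_dt: float = 0.01,
                 fcm_m: float = 2.0):
        self.method = method
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.dt = dt
        self.t_start = t_start
        self.upsample_dt = upsample_dt
        self.fcm_m = fcm_m

    def _make_backend(self):
        if self.method == "ah":
            return AgglomerativeCurveCluster(n_clusters=self.n_clusters)
        if self.method == "kmeans":
            return CurveKMeans(n_clusters=self.n_clusters,
                               random_state=self.random_state)
        if self.method == "fcm":
            return FuzzyCMeans(n_clusters=self.n_clusters, m=self.fcm_m,
                               random_state=self.random_state)
        raise ValueError("method must be 'ah', 'kmeans' or 'fcm'")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (curves by time points)")
        grid = TimeGrid(self.t_start, X.shape[1] * self.dt, self.dt)
        backend = self._make_backend().fit(X)
        assignment = ClusterAssignment(
            backend.labels_, self.n_clusters, backend.cluster_means_, self.method
        )
        selected, aif, metrics = select_aif(assignment, grid, self.upsample_dt)
        self.grid_ = grid
        self.labels_ = backend.labels_
        self.cluster_means_ = backend.cluster_means_
        self.metrics_ = metrics
        self.selected_cluster_ = selected
        self.selected_mask_ = backend.labels_ == selected
        self.aif_ = aif
        self.aif_metrics_ = shape_metrics(aif, grid, self.upsample_dt)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_detect(self, X) -> np.ndarray:
        """Fit and return the detected AIF curve."""
        return self.fit(X).aif_
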