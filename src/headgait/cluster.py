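"""Deterministic 1-D two-cluster k-means used by the posture detectors."""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans


def kmeans_two(values: np.ndarray, iters: int = 10, seed: int = 0):
    """Two-cluster k-means on a 1-D value vector.

    Centers are initialized at the minimum and maximum of the data, which
    makes the labelling reproducible without randomness (the ``seed`` is kept
    for API symmetry only).  Lloyd iterations are capped at ``iters``.

    Returns ``(labels, centers)`` with ``centers[0] <= centers[1]`` and labels
    0 = lower cluster, 1 = upper cluster, or ``(None, None)`` when the data
    are degenerate (all values identical).
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-9 or len(v) < 2:
        return None, None
    km = KMeans(n_clusters=2, init=np.array([[lo], [hi]]), n_init=1,
                max_iter=iters, random_state=seed)
    labels = km.fit_predict(v)
    centers = km.cluster_centers_.ravel()
    if centers[0] > centers[1]:  # keep 0 = lower
        centers = centers[::-1]
        labels = 1 - labels
    if abs(centers[1] - centers[0]) < 1e-9:
        return None, None
    return labels, centers
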