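"""K-means partitioning of in-mask elements into phenotypic subregions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from ithkit.errors import DegenerateInputError
from ithkit.local_features import FeatureMatrix

DEFAULT_K = 6

_KMEANS_PARAMS = dict(init="k-means++", n_init=10, max_iter=300, tol=1e-4)


@dataclass(frozen=True)
class ClusterMap:
    """Integer subregion labels on the grid: 1..K in-mask, 0 outside."""

    labels: np.ndarray  # integer grid
    K: int
    seed: int
    mode: str  # {"2d", "3d"}

    def __post_init__(self):
        lab = np.asarray(self.labels)
        distinct = np.unique(lab[lab != 0])
        if distinct.size and (distinct.min() < 1 or distinct.max() > self.K):
            raise ValueError(f"labels outside 1..{self.K}: {distinct[:8]}")

    @property
    def in_mask_count(self) -> int:
        return int((np.asarray(self.labels) != 0).sum())


def cluster_subregions(fm: FeatureMatrix, K: int = DEFAULT_K, seed: int = 0) -> ClusterMap:
    """Seeded k-means++ over feature rows; labels mapped back to coordinates.

    Uses 10 restarts (lowest inertia wins), tolerance 1e-4, max 300
    iterations.  Same features and seed always yield the same map.
    """
    if K < 2:
        raise DegenerateInputError(f"K must be >= 2, got {K}")
    if fm.n_elements < K:
        raise DegenerateInputError(
            f"mask has {fm.n_elements} elements, need at least K={K} for clustering"
        )
    if not np.all(np.isfinite(fm.values)):
        raise ValueError("feature matrix contains non-finite values")

    km = KMeans(n_clusters=K, random_state=seed, **_KMEANS_PARAMS)
    with warnings.catch_warnings():
        # duplicate feature rows (e.g. constant regions) legitimately yield
        # fewer than K distinct clusters; downstream handles empty labels
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        assignments = km.fit_predict(fm.values)

    labels = np.zeros(fm.grid_shape, dtype=np.int32)
    labels[tuple(fm.coords.T)] = assignments + 1
    return ClusterMap(labels=labels, K=K, seed=seed, mode=fm.mode)


def export_cluster_map(cmap: ClusterMap, path, spacing=None) -> None:
    """Write the label grid as a NIfTI/NRRD integer image for inspection.

    2D maps are written as single-slice volumes.
    """
    from ithkit.image_io import _write_grid

    labels = np.asarray(cmap.labels, dtype=np.int16)
    if labels.ndim == 2:
        labels = labels[None, ...]
    if spacing is None:
        spacing = (1.0,) * labels.ndim
    _write_grid(path, labels, spacing)
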