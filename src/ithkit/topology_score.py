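"""Topology-aware fragmentation scoring of clustered subregions.

For each cluster ``i`` the binary subregion is decomposed into connected
components under the mode-specific adjacency (8-connectivity in 2D,
26-connectivity in 3D).  The heterogeneity score is

    score = 1 - (1/total) * sum_i largest_i / count_i

where ``largest_i`` is the element count of the cluster's largest component,
``count_i`` its number of components and ``total`` the in-mask element
count.  The score is 0 exactly when every non-empty cluster is a single
connected blob and approaches 1 under extreme fragmentation.  Areas and
volumes are element counts, so the score is dimensionless and independent
of voxel-spacing metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ithkit.errors import DegenerateInputError, StageError
from ithkit.image_io import NoduleImage, largest_axial_section
from ithkit.local_features import FeatureBankSpec, extract_local_features, standardize_features
from ithkit.subregion_clustering import DEFAULT_K, ClusterMap, cluster_subregions

#: adjacency per mode; not configurable in the public scoring API
MODE_CONNECTIVITY = {"2d": 8, "3d": 26}


@dataclass(frozen=True)
class TopologySummary:
    """Per-cluster component statistics under a fixed adjacency."""

    cluster_sizes: tuple  # total elements per cluster, index i-1 -> cluster i
    component_counts: tuple  # n_i (2D) / m_i (3D); 0 for empty clusters
    largest_sizes: tuple  # S_i,max / V_i,max in elements; 0 for empty clusters
    total: int  # S_total / V_total
    connectivity: int  # 8 or 26

    def __post_init__(self):
        if sum(self.cluster_sizes) != self.total:
            raise ValueError("cluster sizes do not sum to total")
        for size, count, largest in zip(self.cluster_sizes, self.component_counts,
                                        self.largest_sizes):
            if size == 0:
                if count != 0 or largest != 0:
                    raise ValueError("empty cluster must have zero count/largest")
            elif not (1 <= largest <= size and count >= 1):
                raise ValueError("component stats violate cluster size bounds")

    @property
    def sigma(self) -> float:
        """Accumulator sum_i largest_i / count_i over non-empty clusters."""
        return float(sum(l / c for l, c in zip(self.largest_sizes, self.component_counts)
                         if c > 0))


@dataclass(frozen=True)
class IthResult:
    """A heterogeneity score with full provenance."""

    mode: str  # {"2d", "3d"}
    score: float  # in [0, 1)
    K: int
    N: int  # feature count
    seed: int
    connectivity: int
    summary: TopologySummary
    slice_index: int | None = None  # 2D mode only

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "score": self.score,
            "K": self.K,
            "N": self.N,
            "seed": self.seed,
            "connectivity": self.connectivity,
            "slice_index": self.slice_index,
            "per_cluster": [
                {"size": s, "components": c, "largest": l}
                for s, c, l in zip(self.summary.cluster_sizes,
                                   self.summary.component_counts,
                                   self.summary.largest_sizes)
            ],
        }


def _structure(connectivity: int, ndim: int) -> np.ndarray:
    if ndim == 2 and connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if ndim == 3 and connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    raise ValueError(
        f"connectivity {connectivity} does not match dimensionality {ndim} "
        "(use 8 for 2D, 26 for 3D)"
    )


def label_components(cmap: ClusterMap, connectivity: int | None = None) -> TopologySummary:
    """Connected-component statistics for every cluster of ``cmap``.

    Empty clusters (k-means may leave labels unused) are recorded with
    count 0 and size 0.
    """
    labels = np.asarray(cmap.labels)
    if connectivity is None:
        connectivity = MODE_CONNECTIVITY[cmap.mode]
    structure = _structure(connectivity, labels.ndim)

    sizes, counts, largests = [], [], []
    for i in range(1, cmap.K + 1):
        binary = labels == i
        size = int(binary.sum())
        if size == 0:
            sizes.append(0)
            counts.append(0)
            largests.append(0)
            continue
        comp, n_comp = ndimage.label(binary, structure=structure)
        comp_sizes = np.bincount(comp.ravel())[1:]
        sizes.append(size)
        counts.append(int(n_comp))
        largests.append(int(comp_sizes.max()))
    return TopologySummary(
        cluster_sizes=tuple(sizes),
        component_counts=tuple(counts),
        largest_sizes=tuple(largests),
        total=int((labels != 0).sum()),
        connectivity=connectivity,
    )


def ith_score(summary: TopologySummary, *, mode: str | None = None, K: int | None = None,
              N: int = 0, seed: int = 0, slice_index: int | None = None) -> IthResult:
    """Derive the heterogeneity score ``1 - sigma/total`` from a summary."""
    if summary.total <= 0:
        raise DegenerateInputError("total element count is zero")
    if all(c == 0 for c in summary.component_counts):
        raise DegenerateInputError("no non-empty cluster present")
    if mode is None:
        mode = "2d" if summary.connectivity == 8 else "3d"
    score = 1.0 - summary.sigma / summary.total
    # sigma <= total always; clip away float round-off only
    score = min(max(score, 0.0), np.nextafter(1.0, 0.0))
    return IthResult(mode=mode, score=float(score),
                     K=K if K is not None else len(summary.cluster_sizes),
                     N=N, seed=seed, connectivity=summary.connectivity,
                     summary=summary, slice_index=slice_index)


def compute_ith(img: NoduleImage, mode: str, spec: FeatureBankSpec | None = None,
                K: int = DEFAULT_K, seed: int = 0) -> IthResult:
    """End-to-end scoring: section extraction (2D) -> features -> clustering
    -> component topology -> score.  Failures name the responsible stage."""
    if mode not in MODE_CONNECTIVITY:
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    if spec is None:
        spec = FeatureBankSpec(mode=mode)
    if spec.mode != mode:
        raise ValueError(f"feature spec mode {spec.mode!r} != requested mode {mode!r}")

    slice_index = None
    try:
        if mode == "2d":
            region = largest_axial_section(img)
            slice_index = region.slice_index
        else:
            region = img
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("image_io", exc) from exc

    try:
        fm = extract_local_features(region, spec)
        if spec.standardize:
            fm = standardize_features(fm)
    except Exception as exc:
        raise StageError("local_features", exc) from exc

    try:
        cmap = cluster_subregions(fm, K=K, seed=seed)
    except Exception as exc:
        raise StageError("subregion_clustering", exc) from exc

    try:
        summary = label_components(cmap)
        return ith_score(summary, mode=mode, K=K, N=fm.n_features, seed=seed,
                         slice_index=slice_index)
    except Exception as exc:
        raise StageError("topology_score", exc) from exc
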