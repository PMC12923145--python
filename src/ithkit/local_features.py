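"""Per-element local feature extraction with a mode-specific sliding kernel.

Every in-mask element receives a fixed bank of ``N`` (default 104) generic
local features computed from its intensity neighbourhood: the anchored
2x2 / 2x2x2 kernel, concentric box neighbourhoods (3/5/7 elements per axis),
finite-difference gradients, Gaussian-derivative responses and small
separable (Laws-style) filter responses.

The bank (version "v1") is a documented stand-in: it is rich, strictly
local, deterministic and mode-agnostic in count, which is what the
downstream clustering/topology stages require.  Feature names are stable
and each carries a shift-behaviour category:

* ``location``   -- adding a constant ``c`` to all intensities adds ``c``
* ``dispersion`` -- invariant under adding a constant
* ``other``      -- neither (e.g. features of HU-window-clipped intensity)

The anchored even kernel covers element ``x`` and its positive-direction
neighbours.  Out-of-grid neighbours are edge-replicated; in-grid neighbours
outside the mask keep their real intensities (only the anchor must be
in-mask).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ithkit.errors import DegenerateInputError
from ithkit.image_io import NoduleImage, PlanarSection

FEATURE_BANK_VERSION = "v1"
DEFAULT_FEATURE_COUNT = 104

#: lung-window display range used during segmentation: level -600 HU, width 1500 HU
DEFAULT_HU_WINDOW = (-1350.0, 150.0)

_N_LEVELS = 16  # quantization levels for local entropy
_GAUSS_SIGMAS = (0.5, 1.0, 2.0)
_BOX_SIZES = (3, 5, 7)

# separable 1D kernels (smoothing / edge / spot)
_L3 = np.array([1.0, 2.0, 1.0]) / 4.0
_E3 = np.array([-1.0, 0.0, 1.0]) / 2.0
_S3 = np.array([-1.0, 2.0, -1.0]) / 4.0


@dataclass(frozen=True)
class FeatureBankSpec:
    """Configuration of the per-element feature bank."""

    mode: str = "3d"  # {"2d", "3d"}
    feature_count: int = DEFAULT_FEATURE_COUNT
    hu_window: tuple = DEFAULT_HU_WINDOW
    standardize: bool = True
    pad: bool = True  # edge-replicate out-of-grid kernel neighbours

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if not 2 <= self.feature_count <= DEFAULT_FEATURE_COUNT:
            raise ValueError(
                f"feature_count must be in [2, {DEFAULT_FEATURE_COUNT}], "
                f"got {self.feature_count}"
            )
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError("hu_window lower bound must be below upper bound")

    @property
    def window_extent(self) -> tuple:
        """Sliding kernel extent: 2x2 in 2D mode, 2x2x2 in 3D mode."""
        return (2, 2) if self.mode == "2d" else (2, 2, 2)

    @property
    def ndim(self) -> int:
        return 2 if self.mode == "2d" else 3


@dataclass(frozen=True)
class FeatureMatrix:
    """One feature row per in-mask element, plus its grid coordinates."""

    values: np.ndarray  # (n_elements, n_features)
    coords: np.ndarray  # (n_elements, ndim) integer grid coordinates
    names: tuple
    grid_shape: tuple
    mode: str

    def __post_init__(self):
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("values and coords row counts differ")
        if self.values.shape[1] != len(self.names):
            raise ValueError("values column count != number of feature names")

    @property
    def n_elements(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self):
        """Coordinate columns first, then feature columns, stable order."""
        import pandas as pd

        axes = ("slice", "row", "col")[-self.coords.shape[1]:]
        data = {f"coord_{a}": self.coords[:, i] for i, a in enumerate(axes)}
        for j, name in enumerate(self.names):
            data[name] = self.values[:, j]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# bank construction
# ---------------------------------------------------------------------------

def _shifted(arr, offset):
    """arr sampled at x+offset with edge replication."""
    pad = [(max(0, -o), max(0, o)) for o in offset]
    padded = np.pad(arr, pad, mode="edge")
    slices = tuple(
        slice(p[0] + o, p[0] + o + n) for p, o, n in zip(pad, offset, arr.shape)
    )
    return padded[slices]


def _kernel_stack(arr):
    """(2^d, *shape) stack of the anchored even kernel covering x..x+1 per axis."""
    offsets = list(itertools.product((0, 1), repeat=arr.ndim))
    return np.stack([_shifted(arr, o) for o in offsets])


def _quantize(arr, lo, hi):
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.int16)
    q = np.floor((np.clip(arr, lo, hi) - lo) / (hi - lo) * _N_LEVELS).astype(np.int16)
    return np.minimum(q, _N_LEVELS - 1)


def _stack_entropy(qstack):
    n = qstack.shape[0]
    ent = np.zeros(qstack.shape[1:], dtype=np.float64)
    for level in range(_N_LEVELS):
        p = (qstack == level).sum(axis=0) / n
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    return ent


def _box_entropy(qarr, size):
    ent = np.zeros(qarr.shape, dtype=np.float64)
    for level in range(_N_LEVELS):
        p = ndimage.uniform_filter((qarr == level).astype(np.float64), size=size,
                                   mode="nearest")
        p = np.clip(p, 0.0, 1.0)
        nz = p > 1e-12
        ent[nz] -= p[nz] * np.log2(p[nz])
    return ent


def _rank_for_percentile(pct, n):
    return int(round(pct / 100.0 * (n - 1)))


def _box_percentile(arr, size, pct):
    n = size ** arr.ndim
    return ndimage.rank_filter(arr, rank=_rank_for_percentile(pct, n), size=size,
                               mode="nearest")


def _kernel_stats(arr, qarr):
    """The 8 first-order stats of the anchored 2^d kernel."""
    stack = _kernel_stack(arr)
    out = {
        "mean": stack.mean(axis=0),
        "min": stack.min(axis=0),
        "max": stack.max(axis=0),
        "median": np.median(stack, axis=0),
        "var": stack.var(axis=0),
    }
    out["range"] = out["max"] - out["min"]
    p25, p75 = np.percentile(stack, (25, 75), axis=0)
    out["iqr"] = p75 - p25
    out["entropy"] = _stack_entropy(_kernel_stack(qarr))
    return out


def _box_stats(arr, qarr, size):
    mean = ndimage.uniform_filter(arr, size=size, mode="nearest")
    sq = ndimage.uniform_filter(arr * arr, size=size, mode="nearest")
    out = {
        "mean": mean,
        "min": ndimage.minimum_filter(arr, size=size, mode="nearest"),
        "max": ndimage.maximum_filter(arr, size=size, mode="nearest"),
        "median": _box_percentile(arr, size, 50),
        "var": np.clip(sq - mean * mean, 0.0, None),
    }
    out["range"] = out["max"] - out["min"]
    out["iqr"] = _box_percentile(arr, size, 75) - _box_percentile(arr, size, 25)
    out["entropy"] = _box_entropy(qarr, size)
    return out


_STAT_ORDER = ("mean", "min", "max", "median", "var", "range", "iqr", "entropy")
_STAT_CATEGORY = {
    "mean": "location", "min": "location", "max": "location", "median": "location",
    "var": "dispersion", "range": "dispersion", "iqr": "dispersion",
    "entropy": "dispersion",
}


def _laws_response(arr, axis_kernels):
    """Sequentially correlate 1D kernels along the array axes."""
    out = arr
    for axis, kernel in enumerate(axis_kernels):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="nearest")
    return out


def _triple_axis_to_array_axis(triple_axis, ndim):
    """Map a canonical (slice,row,col) axis index onto the array axis.

    Returns None when the axis does not exist (slice axis in 2D mode).
    """
    if ndim == 3:
        return triple_axis
    return None if triple_axis == 0 else triple_axis - 1


def _build_bank(arr, spec: FeatureBankSpec):
    """Return (names, categories, grids) for the full 104-feature bank."""
    ndim = arr.ndim
    lo, hi = spec.hu_window
    windowed = np.clip(arr, lo, hi)
    img_lo, img_hi = float(arr.min()), float(arr.max())
    q_raw = _quantize(arr, img_lo, img_hi)  # per-image range, shift-invariant
    q_win = _quantize(arr, lo, hi)

    names, cats, grids = [], [], []

    def add(name, cat, grid):
        names.append(name)
        cats.append(cat)
        grids.append(np.asarray(grid, dtype=np.float64))

    zeros = np.zeros(arr.shape, dtype=np.float64)

    # A: center intensities
    add("raw.center", "location", arr)
    add("win.center", "other", windowed)

    # B/C: first-order stats over the anchored kernel and box neighbourhoods
    for basis, source, qsource, cat_of in (
        ("raw", arr, q_raw, lambda s: _STAT_CATEGORY[s]),
        ("win", windowed, q_win, lambda s: "other"),
    ):
        stats = {"k2": _kernel_stats(source, qsource)}
        for size in _BOX_SIZES:
            stats[f"b{size}"] = _box_stats(source, qsource, size)
        for nb in ("k2", "b3", "b5", "b7"):
            for stat in _STAT_ORDER:
                add(f"{basis}.{nb}.{stat}", cat_of(stat), stats[nb][stat])

    # D: finite-difference gradients (unit element spacing)
    gradients = np.gradient(arr)
    if ndim == 2:
        gradients = [zeros] + list(gradients)
    for axis, g in enumerate(gradients):
        add(f"grad.ax{axis}", "dispersion", g)
    add("grad.mag", "dispersion", np.sqrt(sum(g * g for g in gradients)))

    # E: Gaussian-derivative responses.  The discrete second-derivative
    # kernel does not sum exactly to zero at small sigma, so the DC response
    # (measured on a constant image) is subtracted to keep the Laplacian
    # feature shift-invariant.
    for sigma in _GAUSS_SIGMAS:
        add(f"gauss{sigma}.smooth", "location",
            ndimage.gaussian_filter(arr, sigma, mode="nearest"))
        dc = ndimage.gaussian_laplace(np.ones((9,) * ndim), sigma,
                                      mode="nearest")[(4,) * ndim]
        add(f"gauss{sigma}.log", "dispersion",
            ndimage.gaussian_laplace(arr, sigma, mode="nearest") - dc * arr)
        add(f"gauss{sigma}.gradmag", "dispersion",
            ndimage.gaussian_gradient_magnitude(arr, sigma, mode="nearest"))

    # F: box-5 percentiles
    for pct in (10, 25, 75, 90):
        add(f"raw.b5.p{pct}", "location", _box_percentile(arr, 5, pct))

    # G: separable Laws-style responses (E=edge, S=spot, L=smooth elsewhere)
    def laws_single(triple_axis, kernel):
        a = _triple_axis_to_array_axis(triple_axis, ndim)
        if a is None:
            return zeros
        kernels = [_L3] * ndim
        kernels[a] = kernel
        return _laws_response(arr, kernels)

    def laws_pair(pair, kernel):
        axes = [_triple_axis_to_array_axis(t, ndim) for t in pair]
        if any(a is None for a in axes):
            return zeros
        kernels = [_L3] * ndim
        for a in axes:
            kernels[a] = kernel
        return _laws_response(arr, kernels)

    e_responses = {}
    for t in (0, 1, 2):
        resp = laws_single(t, _E3)
        e_responses[t] = resp
        add(f"laws.E{t}", "dispersion", resp)
    for t in (0, 1, 2):
        add(f"laws.S{t}", "dispersion", laws_single(t, _S3))
    for pair in ((0, 1), (0, 2), (1, 2)):
        add(f"laws.EE{pair[0]}{pair[1]}", "dispersion", laws_pair(pair, _E3))
    for pair in ((0, 1), (0, 2), (1, 2)):
        add(f"laws.SS{pair[0]}{pair[1]}", "dispersion", laws_pair(pair, _S3))

    # H: local energy of the edge responses
    for t in (0, 1, 2):
        add(f"laws.absE{t}.b3", "dispersion",
            ndimage.uniform_filter(np.abs(e_responses[t]), size=3, mode="nearest"))

    # I: neighbour-vs-center comparisons and local contrasts
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=ndim)
               if any(v != 0 for v in o)]
    gt = np.zeros(arr.shape, dtype=np.float64)
    gt25 = np.zeros(arr.shape, dtype=np.float64)
    for o in offsets:
        nb = _shifted(arr, o)
        gt += nb > arr
        gt25 += nb > arr + 25.0
    add("nbh.frac_gt", "dispersion", gt / len(offsets))
    add("nbh.frac_gt25", "dispersion", gt25 / len(offsets))
    for size in _BOX_SIZES:
        add(f"nbh.contrast.b{size}", "dispersion",
            arr - ndimage.uniform_filter(arr, size=size, mode="nearest"))

    # J: local standard deviation
    mean3 = ndimage.uniform_filter(arr, size=3, mode="nearest")
    sq3 = ndimage.uniform_filter(arr * arr, size=3, mode="nearest")
    add("raw.b3.std", "dispersion", np.sqrt(np.clip(sq3 - mean3 * mean3, 0.0, None)))

    assert len(names) == DEFAULT_FEATURE_COUNT, f"bank size {len(names)} != 104"
    return names, cats, grids


def feature_categories(spec: FeatureBankSpec = FeatureBankSpec()) -> dict:
    """Map feature name -> shift-behaviour category for the configured bank."""
    probe = np.zeros((4,) * spec.ndim)
    names, cats, _ = _build_bank(probe, spec)
    return dict(zip(names[: spec.feature_count], cats[: spec.feature_count]))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def extract_local_features(region, spec: FeatureBankSpec | None = None) -> FeatureMatrix:
    """Compute the feature bank for every in-mask element of ``region``."""
    if spec is None:
        spec = FeatureBankSpec(mode="2d" if isinstance(region, PlanarSection) else "3d")
    if isinstance(region, PlanarSection):
        region_ndim = 2
    elif isinstance(region, NoduleImage):
        region_ndim = 3
    else:
        raise TypeError(f"unsupported region type {type(region).__name__}")
    if spec.ndim != region_ndim:
        raise ValueError(
            f"spec mode {spec.mode!r} does not match region dimensionality {region_ndim}"
        )

    mask = np.asarray(region.mask)
    if not mask.any():
        raise DegenerateInputError("region mask is empty")
    if not spec.pad:
        coords_fg = np.argwhere(mask > 0)
        extents = coords_fg.max(axis=0) - coords_fg.min(axis=0) + 1
        if np.any(extents < max(spec.window_extent)):
            raise DegenerateInputError(
                f"mask extent {tuple(extents)} smaller than kernel "
                f"{spec.window_extent} and padding is disabled"
            )

    arr = np.asarray(region.intensities, dtype=np.float64)
    names, _, grids = _build_bank(arr, spec)
    coords = np.argwhere(mask > 0)
    idx = tuple(coords.T)
    values = np.stack([g[idx] for g in grids], axis=1)
    values = values[:, : spec.feature_count]
    names = tuple(names[: spec.feature_count])
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values produced")
    return FeatureMatrix(values=values, coords=coords, names=names,
                         grid_shape=arr.shape, mode=spec.mode)


def standardize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Population z-scoring per column; zero-variance columns map to zeros."""
    if fm.n_elements < 2:
        raise DegenerateInputError("standardization requires at least 2 rows")
    mean = fm.values.mean(axis=0)
    std = fm.values.std(axis=0)  # population standard deviation
    out = np.zeros_like(fm.values)
    nz = std > 1e-12
    out[:, nz] = (fm.values[:, nz] - mean[nz]) / std[nz]
    return FeatureMatrix(values=out, coords=fm.coords, names=fm.names,
                         grid_shape=fm.grid_shape, mode=fm.mode)
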