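"""Synthetic CT nodule phantoms and clinicoradiologic cohort tables.

Phantoms are ellipsoidal nodules whose interior is partitioned into a
requested number of phenotypes, each fragmented into a requested number of
26-connected blobs, with controllable intensity contrast and additive
Gaussian noise.  Ground-truth phenotype labels are returned so recovery of
the fragmentation structure can be tested.

Cohort tables emulate the variable types and approximate marginals of an
early-stage lung adenocarcinoma cohort (two classes, 0 = AIS/MIA,
1 = IAC at roughly 2:1 IAC prevalence).  A single ``effect`` knob scales
every label association through a latent-invasiveness logistic link, with
the 3D heterogeneity score carrying the dominant effect; ``effect=0``
renders every column independent of the label.  The marginals are loosely
modelled defaults, not a claim of distributional fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ithkit.errors import DegenerateInputError, PackingError
from ithkit.image_io import NoduleImage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

DENSITY_LEVELS = ("pGGN", "PSN", "SN")
LOCATION_LEVELS = ("RUL", "RML", "RLL", "LUL", "LLL")
SEX_LEVELS = ("F", "M")

#: binary morphological signs carried by the cohort table
SIGN_COLUMNS = ("margin_ill_defined", "lobulation", "spiculation",
                "vascular_convergence", "vacuole", "pleural_indentation",
                "shape_irregular")

COHORT_COLUMNS = ("label", "sex", "age", "size_mm", "density", "location",
                  *SIGN_COLUMNS, "ith2d", "ith3d")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic nodule phantom."""

    grid_shape: tuple = (32, 40, 40)
    radius_range: tuple = (7.0, 12.0)  # in elements (in-plane)
    phenotype_count: int = 1  # 1..6 internal phenotypes
    fragmentation: int = 1  # disconnected blobs per phenotype
    contrast: float = 150.0  # HU step between phenotype means
    noise_sd: float = 10.0  # additive Gaussian noise, HU
    base_hu: float = -300.0
    #: intensity outside the mask; None = same as base_hu.  The score only
    #: sees out-of-mask intensities through kernel neighbourhoods of boundary
    #: elements, and a large air-like contrast there makes the clustering
    #: probe the mask boundary instead of the internal topology under test,
    #: so the neutral default keeps phantoms a clean probe of fragmentation.
    background_hu: float | None = None
    spacing: tuple = (1.0, 0.7, 0.7)
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.phenotype_count <= 6:
            raise ValueError("phenotype_count must be in 1..6")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (low, high)")
        margin = 2
        if 2 * self.radius_range[1] + 2 * margin > min(self.grid_shape):
            raise ValueError(
                f"radius up to {self.radius_range[1]} does not fit grid "
                f"{self.grid_shape}"
            )


def _ellipsoid_mask(shape, center, radii):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (dist <= 1.0).astype(np.uint8)


def _place_seeds(rng, coords, n_seeds, min_dist):
    """Pick n_seeds mask coordinates pairwise at least min_dist apart."""
    chosen = []
    order = rng.permutation(len(coords))
    for idx in order:
        p = coords[idx]
        if all(np.linalg.norm(p - q) >= min_dist for q in chosen):
            chosen.append(p)
            if len(chosen) == n_seeds:
                return np.array(chosen)
    return None


def _cell_adjacency(cellmap, mask, n_cells):
    """Pairs of nearest-seed cells that touch under 26-connectivity."""
    ndim = cellmap.ndim
    adj = [set() for _ in range(n_cells)]
    import itertools as _it

    for offset in _it.product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in offset) or offset < tuple(-o for o in offset):
            continue  # half the directions suffice
        a_sl = tuple(slice(max(0, o), c + min(0, o)) for o, c in zip(offset, cellmap.shape))
        b_sl = tuple(slice(max(0, -o), c + min(0, -o)) for o, c in zip(offset, cellmap.shape))
        a, b = cellmap[a_sl], cellmap[b_sl]
        valid = (mask[a_sl] > 0) & (mask[b_sl] > 0) & (a != b)
        for u, v in set(zip(a[valid].tolist(), b[valid].tolist())):
            adj[u].add(v)
            adj[v].add(u)
    return adj


def _grow_components(rng, adj, n_phenotypes, frag):
    """Partition cells into phenotype classes so each class induces exactly
    ``frag`` connected components on the cell-adjacency graph.

    Seeds ``n_phenotypes * frag`` pairwise non-adjacent root cells and grows
    each component by absorbing unassigned neighbouring cells, never letting
    two same-phenotype components touch.  Returns a color array or None.
    """
    n_cells = len(adj)
    n_roots = n_phenotypes * frag
    cells = list(range(n_cells))
    rng.shuffle(cells)
    color = np.zeros(n_cells, dtype=np.int64)
    comp = np.full(n_cells, -1, dtype=np.int64)
    placed = 0
    for c in cells:
        col = placed % n_phenotypes + 1  # only same-color roots must be apart
        if all(color[v] != col for v in adj[c]) and color[c] == 0:
            color[c] = col
            comp[c] = placed
            placed += 1
            if placed == n_roots:
                break
    if placed < n_roots:
        return None
    unassigned = [c for c in cells if color[c] == 0]
    while unassigned:
        progress = False
        rest = []
        rng.shuffle(unassigned)
        for c in unassigned:
            # a color is viable iff c touches exactly one of its components
            options = []
            for col in range(1, n_phenotypes + 1):
                touched = {comp[v] for v in adj[c] if color[v] == col}
                if len(touched) == 1:
                    options.append((col, touched.pop()))
            if options:
                col, k = options[int(rng.integers(len(options)))]
                color[c] = col
                comp[c] = k
                progress = True
            else:
                rest.append(c)
        unassigned = rest
        if not progress:
            return None
    return color


def generate_phantom(spec: PhantomSpec):
    """Return ``(NoduleImage, truth)`` where ``truth`` is the phenotype label
    grid (1..phenotype_count inside the mask, 0 outside).

    Phenotype regions are nearest-seed cells inside the ellipsoid; seed
    placement is resampled until every phenotype decomposes into exactly
    ``fragmentation`` 26-connected components.  Raises :class:`PackingError`
    when the requested topology cannot be packed into the grid.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    r_inplane = rng.uniform(*spec.radius_range)
    # slice-axis radius shrunk by the anisotropy of the default spacing
    r_axial = max(3.0, r_inplane * spec.spacing[1] / spec.spacing[0])
    radii = (min(r_axial, shape[0] / 2 - 2), r_inplane, r_inplane)
    mask = _ellipsoid_mask(shape, center, radii)
    coords = np.argwhere(mask > 0)

    n_seeds = spec.phenotype_count * spec.fragmentation
    if spec.phenotype_count == 1 and spec.fragmentation > 1:
        raise PackingError(
            "a single phenotype fills the whole (connected) mask and cannot "
            "be split into disconnected blobs; add phenotypes"
        )
    if len(coords) < 8 * n_seeds:
        raise PackingError(
            f"mask of {len(coords)} elements is too small for {n_seeds} blobs; "
            "use a larger grid or radius"
        )

    truth = np.zeros(shape, dtype=np.int32)
    if n_seeds == 1:
        truth[mask > 0] = 1
    else:
        placed = False
        for attempt in range(300):
            # a finer cell partition than strictly needed gives the component
            # grower room to route around adjacency conflicts; refine further
            # if early attempts deadlock
            factor = 2 + attempt // 40
            n_cells = min(factor * n_seeds, len(coords) // 10)
            n_cells = max(n_cells, n_seeds)
            min_dist = max(1.5, 0.45 * r_inplane * (8.0 / n_cells) ** (1 / 3))
            seeds = _place_seeds(rng, coords, n_cells, min_dist)
            if seeds is None:
                continue
            d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
            cell_of_voxel = np.argmin(d2, axis=1)
            cellmap = np.zeros(shape, dtype=np.int32)
            cellmap[tuple(coords.T)] = cell_of_voxel
            adj = _cell_adjacency(cellmap, mask, n_cells)
            color = None
            for _ in range(20):
                color = _grow_components(rng, adj, spec.phenotype_count,
                                         spec.fragmentation)
                if color is not None:
                    break
            if color is None:
                continue
            truth[:] = 0
            truth[tuple(coords.T)] = color[cell_of_voxel]
            # discrete Voronoi cells are occasionally disconnected; verify
            ok = all(
                ndimage.label(truth == p, structure=_STRUCT26)[1] == spec.fragmentation
                for p in range(1, spec.phenotype_count + 1)
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not pack {spec.phenotype_count} phenotypes x "
                f"{spec.fragmentation} blobs into the mask; suggest a larger grid"
            )

    offsets = (np.arange(1, spec.phenotype_count + 1)
               - (spec.phenotype_count + 1) / 2.0)
    background = spec.base_hu if spec.background_hu is None else spec.background_hu
    intensities = np.full(shape, background, dtype=np.float64)
    for p in range(1, spec.phenotype_count + 1):
        intensities[truth == p] = spec.base_hu + offsets[p - 1] * spec.contrast
    if spec.noise_sd > 0:
        intensities += rng.normal(0.0, spec.noise_sd, size=shape)

    img = NoduleImage(intensities=intensities, mask=mask, spacing=spec.spacing)
    return img, truth


# ---------------------------------------------------------------------------
# synthetic clinicoradiologic cohorts
# ---------------------------------------------------------------------------

_IAC_PREVALENCE = 0.66
_DENSITY_P0 = (0.75, 0.18, 0.07)  # AIS/MIA density mix
_DENSITY_P1 = (0.43, 0.30, 0.27)  # IAC density mix (denser)
_LOCATION_P = (0.354, 0.068, 0.169, 0.275, 0.134)
_SIGN_PREVALENCE = {
    "margin_ill_defined": 0.249,
    "lobulation": 0.537,
    "spiculation": 0.456,
    "vascular_convergence": 0.773,
    "vacuole": 0.189,
    "pleural_indentation": 0.577,
    "shape_irregular": 0.459,
}
_SIGN_SHIFT = 0.35  # logit shift per unit effect for IAC rows


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(n: int, effect: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic cohort table of ``n`` rows.

    ``effect`` scales every association between the class label and the
    covariates; the 3D heterogeneity column carries the strongest one.
    """
    if n < 20:
        raise DegenerateInputError(f"cohort size must be >= 20, got {n}")
    rng = np.random.default_rng(seed)
    label = (rng.random(n) < _IAC_PREVALENCE).astype(int)
    lab_eff = effect * label

    # latent invasiveness drives both heterogeneity scores (logistic link)
    latent = lab_eff + rng.normal(0.0, 1.0, n)
    ith3d = _sigmoid(-1.0 + 1.2 * latent + rng.normal(0.0, 0.5, n))
    ith2d = _sigmoid(-1.0 + 0.45 * latent + rng.normal(0.0, 0.8, n))

    age = np.clip(np.round(rng.normal(57.0 + 1.5 * lab_eff, 10.0)), 25, 92).astype(int)
    sex = np.where(rng.random(n) < 0.663, SEX_LEVELS[0], SEX_LEVELS[1])
    size_mm = np.clip(np.exp(rng.normal(np.log(13.0) + 0.18 * lab_eff, 0.35)), 5.0, 30.0)
    size_mm = np.round(size_mm, 1)

    # density mix interpolates between the class-conditional mixes with effect
    p0, p1 = np.array(_DENSITY_P0), np.array(_DENSITY_P1)
    w = np.clip(effect, 0.0, 1.0) * label
    probs = (1 - w[:, None]) * p0[None, :] + w[:, None] * p1[None, :]
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    density_idx = (u[:, None] > cum).sum(axis=1)
    density = np.array(DENSITY_LEVELS)[density_idx]

    location = rng.choice(LOCATION_LEVELS, size=n, p=np.array(_LOCATION_P) / sum(_LOCATION_P))

    data = {
        "label": label,
        "sex": sex,
        "age": age,
        "size_mm": size_mm,
        "density": density,
        "location": location,
    }
    for sign, prev in _SIGN_PREVALENCE.items():
        logit = np.log(prev / (1 - prev)) + _SIGN_SHIFT * lab_eff
        data[sign] = (rng.random(n) < _sigmoid(logit)).astype(int)
    data["ith2d"] = np.round(ith2d, 6)
    data["ith3d"] = np.round(ith3d, 6)

    df = pd.DataFrame(data, columns=list(COHORT_COLUMNS))
    assert ((df["ith2d"] >= 0) & (df["ith2d"] < 1)).all()
    assert ((df["ith3d"] >= 0) & (df["ith3d"] < 1)).all()
    return df
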