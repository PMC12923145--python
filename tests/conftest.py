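"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np
import pytest

from ithkit.image_io import NoduleImage
from ithkit.phantom_generator import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# independent flood-fill oracle (breadth-first search, no scipy)
# ---------------------------------------------------------------------------

def flood_fill_components(binary, connectivity):
    """Component sizes of a binary grid under 8/26-connectivity via BFS.

    Deliberately independent of scipy.ndimage so it can serve as an oracle.
    """
    binary = np.asarray(binary, dtype=bool)
    ndim = binary.ndim
    if (ndim, connectivity) not in ((2, 8), (3, 26)):
        raise ValueError("use 8-connectivity in 2D, 26-connectivity in 3D")
    offsets = [o for o in product((-1, 0, 1), repeat=ndim) if any(o)]
    seen = np.zeros_like(binary, dtype=bool)
    sizes = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            pos = queue.popleft()
            size += 1
            for off in offsets:
                nxt = tuple(p + o for p, o in zip(pos, off))
                if any(c < 0 or c >= s for c, s in zip(nxt, binary.shape)):
                    continue
                if binary[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        sizes.append(size)
    return sizes


def oracle_cluster_stats(labels, K, connectivity):
    """Per-cluster (size, component count, largest component) via the oracle."""
    stats = []
    for i in range(1, K + 1):
        sizes = flood_fill_components(labels == i, connectivity)
        stats.append((int(np.sum(labels == i)), len(sizes),
                      max(sizes) if sizes else 0))
    return stats


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic 3-phenotype phantom for pipeline tests."""
    spec = PhantomSpec(grid_shape=(24, 30, 30), radius_range=(6.0, 8.0),
                       phenotype_count=3, fragmentation=1, seed=7)
    img, truth = generate_phantom(spec)
    return img, truth, spec


@pytest.fixture
def ball_image():
    """A small noisy two-level nodule on a 3D grid, built directly."""
    rs = np.random.default_rng(5)
    shape = (12, 16, 16)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    center = [(s - 1) / 2 for s in shape]
    dist = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = (dist <= 5.5 ** 2).astype(np.uint8)
    intensities = np.where(grids[2] < 8, -200.0, 50.0) + rs.normal(0, 5, shape)
    return NoduleImage(intensities=intensities.astype(float), mask=mask)


@pytest.fixture(scope="session")
def cohort_small():
    from ithkit.phantom_generator import generate_cohort

    return generate_cohort(240, effect=1.2, seed=11)
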