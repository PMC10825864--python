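"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
point-in-polygon by ray casting, nearest neighbours and emission partners
by O(n^2) scans, segment intersection by brute force.
"""

import numpy as np
import pytest

from aieclust import sample_cell_footprint


def ray_cast_inside(ring: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-polygon test, independent of shapely."""
    ring = np.asarray(ring, dtype=float)
    pts = np.atleast_2d(points)
    n = len(ring)
    inside = np.zeros(len(pts), dtype=bool)
    for k, (x, y) in enumerate(pts):
        c = False
        for i in range(n):
            x1, y1 = ring[i]
            x2, y2 = ring[(i + 1) % n]
            if (y1 > y) != (y2 > y):
                xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x < xc:
                    c = not c
        inside[k] = c
    return inside


def segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection of open segments (p1,p2) and (p3,p4)."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4


def brute_force_nn(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_emissive(positions, labeled, d_min, d_max) -> np.ndarray:
    """Exhaustive-pair evaluation of the AIE turn-on rule."""
    pos = np.asarray(positions, dtype=float)
    lab = np.asarray(labeled, dtype=bool)
    n = len(pos)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        if not lab[i]:
            continue
        for j in range(n):
            if j == i or not lab[j]:
                continue
            d = float(np.hypot(*(pos[i] - pos[j])))
            if d_min <= d <= d_max:
                out[i] = True
                break
    return out


@pytest.fixture(scope="session")
def circle_footprint():
    """A nearly circular 5 um-radius footprint (irregularity 0)."""
    return sample_cell_footprint(123, mean_radius=5000.0, irregularity=0.0)


@pytest.fixture(scope="session")
def bumpy_footprint():
    return sample_cell_footprint(7, mean_radius=5000.0, irregularity=0.25)
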