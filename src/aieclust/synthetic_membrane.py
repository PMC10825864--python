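"""Synthetic membrane receptor fields.

Generates planar point patterns of membrane receptors inside a synthetic
cell footprint, either dispersed (complete spatial randomness, the null
model for a low-expressing cell line such as MCF7) or clustered (a Thomas
process, modelling the clustered organisation of HER2 on high-expressing
lines such as SKBR3), and applies a dose/time-dependent cluster-disruption
process that relocates receptors without changing their number — mimicking
an antibody therapeutic that dissolves clusters but leaves total surface
receptor content unchanged.

Units: all coordinates and distances are nanometres; point-process
intensities are per square micrometre (1 um^2 = 1e6 nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from ._rng import as_generator

NM2_PER_UM2 = 1.0e6

__all__ = [
    "CellFootprint",
    "ReceptorField",
    "ClusterParams",
    "DisruptionParams",
    "sample_cell_footprint",
    "sample_receptors_csr",
    "sample_receptors_clustered",
    "apply_disruption",
    "disruption_probability",
    "nearest_neighbor_distances",
]


@dataclass(frozen=True)
class CellFootprint:
    """A simple (non-self-intersecting) closed polygon standing in for one
    cell's membrane area, in nm, with its bounding-box lower-left at the
    origin."""

    boundary: np.ndarray  # (n, 2) vertex ring, not repeated at the end

    def __post_init__(self):
        ring = np.asarray(self.boundary, dtype=float)
        if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
            raise ValueError("boundary must be an (n>=3, 2) vertex array")
        poly = Polygon(ring)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("boundary must form a simple polygon with area > 0")
        object.__setattr__(self, "boundary", ring)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        """Enclosed area in nm^2."""
        return self._polygon.area

    @property
    def bounding_box(self) -> tuple[float, float]:
        """(width, height) of the axis-aligned bounding box, nm."""
        minx, miny, maxx, maxy = self._polygon.bounds
        return (maxx - minx, maxy - miny)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return shapely.intersects_xy(self._polygon, pts[:, 0], pts[:, 1])


@dataclass
class ClusterParams:
    """Thomas-process parameters for clustered receptor fields.

    parent_intensity : cluster centres per um^2
    mean_offspring   : mean receptors per cluster (Poisson)
    cluster_sd       : isotropic Gaussian scatter of offspring, nm
    hardcore         : minimum pairwise separation, nm (steric exclusion of
                       antibody-bound receptors)
    """

    parent_intensity: float = 0.4
    mean_offspring: float = 25.0
    cluster_sd: float = 30.0
    hardcore: float = 2.0

    def __post_init__(self):
        if self.parent_intensity < 0:
            raise ValueError("parent_intensity must be >= 0")
        if self.mean_offspring <= 0:
            raise ValueError("mean_offspring must be > 0")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0")
        if self.hardcore < 0:
            raise ValueError("hardcore must be >= 0")


@dataclass
class DisruptionParams:
    """Dose/time response of the cluster-disruption process.

    The per-receptor relocation probability is separable:

        p(dose, t) = p_max * (1 - exp(-t / tau)) * dose^hill / (dose^hill + ec50^hill)

    a Hill curve in dose and a saturating exponential in time.
    """

    p_max: float = 0.8
    ec50: float = 1.0  # ug/mL
    hill: float = 1.0
    time_scale: float = 8.0  # h

    def __post_init__(self):
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be > 0")


@dataclass
class ReceptorField:
    """A planar receptor point set with cluster-membership labels.

    cluster_id is -1 for dispersed points and the parent index for
    points born from a cluster.
    """

    positions: np.ndarray  # (n, 2) float nm
    cluster_id: np.ndarray  # (n,) int
    footprint: CellFootprint

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.cluster_id = np.asarray(self.cluster_id, dtype=int).reshape(-1)
        if len(self.positions) != len(self.cluster_id):
            raise ValueError("positions and cluster_id lengths differ")

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path) -> None:
        """Write positions as CSV columns x_nm, y_nm, cluster_id (lossless floats)."""
        df = pd.DataFrame(
            {
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
                "cluster_id": self.cluster_id,
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, footprint: CellFootprint) -> "ReceptorField":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            positions=df[["x_nm", "y_nm"]].to_numpy(dtype=float),
            cluster_id=df["cluster_id"].to_numpy(dtype=int),
            footprint=footprint,
        )


def sample_cell_footprint(
    rng_seed,
    mean_radius: float = 5000.0,
    irregularity: float = 0.25,
    n_vertices: int = 48,
) -> CellFootprint:
    """Sample a star-shaped cell footprint as a radially perturbed circle.

    Vertex radii are mean_radius * (1 + irregularity * U) with U ~ U(-1, 1)
    at equally spaced angles; irregularity < 1 keeps every radius positive,
    so the polygon is star-shaped about the centre and therefore simple.
    The result is translated so its bounding box's lower-left is the origin.
    """
    if mean_radius <= 0:
        raise ValueError("mean_radius must be > 0")
    if not 0.0 <= irregularity < 1.0:
        raise ValueError("irregularity must be in [0, 1)")
    rng = as_generator(rng_seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = mean_radius * (1.0 + irregularity * rng.uniform(-1.0, 1.0, size=n_vertices))
    ring = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    ring -= ring.min(axis=0)  # origin at bounding-box lower-left
    return CellFootprint(boundary=ring)


def _uniform_in_footprint(footprint: CellFootprint, n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform points inside the footprint by rejection from the bbox."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = footprint.polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        cand = cand[footprint.contains(cand)]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out


def _hardcore_thin(positions: np.ndarray, labels: np.ndarray, h: float):
    """Sequential hard-core rejection: keep a point iff no earlier *kept*
    point lies strictly closer than h. O(pairs) via a KD-tree."""
    n = len(positions)
    if h <= 0 or n < 2:
        return positions, labels
    pairs = cKDTree(positions).query_pairs(h, output_type="ndarray")
    if len(pairs) == 0:
        return positions, labels
    # only points involved in a conflict need sequential treatment
    keep = np.ones(n, dtype=bool)
    conflicts: dict[int, list[int]] = {}
    for i, j in np.sort(pairs, axis=1):  # i < j
        conflicts.setdefault(int(j), []).append(int(i))
    for j in sorted(conflicts):
        if any(keep[i] for i in conflicts[j]):
            keep[j] = False
    return positions[keep], labels[keep]


def sample_receptors_csr(
    footprint: CellFootprint,
    intensity: float,
    rng_seed,
    hardcore: float = 2.0,
) -> ReceptorField:
    """Homogeneous Poisson (CSR) receptor field at `intensity` receptors/um^2,
    thinned to respect the hard-core distance. All cluster_id are -1."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    rng = as_generator(rng_seed)
    n = rng.poisson(intensity * footprint.area / NM2_PER_UM2)
    pos = _uniform_in_footprint(footprint, int(n), rng)
    labels = np.full(len(pos), -1, dtype=int)
    pos, labels = _hardcore_thin(pos, labels, hardcore)
    return ReceptorField(positions=pos, cluster_id=labels, footprint=footprint)


def sample_receptors_clustered(
    footprint: CellFootprint,
    params: ClusterParams,
    rng_seed,
) -> ReceptorField:
    """Thomas-process receptor field: Poisson parents inside the footprint,
    Poisson(mean_offspring) offspring per parent with isotropic Gaussian
    scatter, offspring outside the footprint discarded, then sequential
    hard-core rejection. cluster_id is the parent index."""
    rng = as_generator(rng_seed)
    n_parents = rng.poisson(params.parent_intensity * footprint.area / NM2_PER_UM2)
    parents = _uniform_in_footprint(footprint, int(n_parents), rng)
    if len(parents):
        counts = rng.poisson(params.mean_offspring, size=len(parents))
        labels = np.repeat(np.arange(len(parents)), counts)
        pos = np.repeat(parents, counts, axis=0) + rng.normal(
            0.0, params.cluster_sd, size=(int(counts.sum()), 2)
        )
        inside = footprint.contains(pos) if len(pos) else np.zeros(0, dtype=bool)
        pos, labels = pos[inside], labels[inside]
    else:
        pos = np.empty((0, 2))
        labels = np.empty(0, dtype=int)
    pos, labels = _hardcore_thin(pos, labels, params.hardcore)
    return ReceptorField(positions=pos, cluster_id=labels, footprint=footprint)


def disruption_probability(dose: float, time: float, params: DisruptionParams) -> float:
    """Per-receptor relocation probability p(dose, time) in [0, p_max]."""
    if dose < 0 or time < 0:
        raise ValueError("dose and time must be >= 0")
    if dose == 0.0 or time == 0.0:
        return 0.0
    dh = dose**params.hill
    return params.p_max * (1.0 - np.exp(-time / params.time_scale)) * dh / (dh + params.ec50**params.hill)


def apply_disruption(
    field: ReceptorField,
    dose: float,
    time: float,
    params: DisruptionParams,
    rng_seed,
) -> ReceptorField:
    """Relocate each clustered receptor independently, with probability
    p(dose, time), to a uniform position inside the footprint, resetting its
    cluster_id to -1. The total receptor count is conserved exactly; dose or
    time of zero returns the field unchanged."""
    p = disruption_probability(dose, time, params)
    if p == 0.0:
        return replace(field)  # shallow copy, positions identical
    rng = as_generator(rng_seed)
    clustered = field.cluster_id != -1
    move = clustered & (rng.random(len(field)) < p)
    new_pos = field.positions.copy()
    new_lab = field.cluster_id.copy()
    n_move = int(move.sum())
    if n_move:
        new_pos[move] = _uniform_in_footprint(field.footprint, n_move, rng)
        new_lab[move] = -1
    return ReceptorField(positions=new_pos, cluster_id=new_lab, footprint=field.footprint)


def nearest_neighbor_distances(field_or_positions) -> np.ndarray:
    """Per-point distance to its nearest other point, nm."""
    if isinstance(field_or_positions, ReceptorField):
        pos = field_or_positions.positions
    else:
        pos = np.asarray(field_or_positions, dtype=float).reshape(-1, 2)
    if len(pos) < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    d, _ = cKDTree(pos).query(pos, k=2)
    return d[:, 1]
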