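"""Hard-sphere geometry: sphere sets, rigid placements, clearance queries.

A molecule (or any test geometry) is a union of balls: atomic centers plus
van der Waals radii. A rigid placement of a guest is a translation of its
reference point plus a rotation about that point. The two queries that
everything else is built on are ``min_clearance`` (smallest signed gap over
all host-guest sphere pairs) and ``max_penetration`` (deepest signed overlap).
Both are exact: the grouped nearest-neighbour acceleration returns the same
value as an all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "SphereSet",
    "Configuration",
    "ShapeSummary",
    "perturb_radii",
    "transform",
    "min_clearance",
    "max_penetration",
    "shape_summary",
]

#: default geometric comparison tolerance (angstrom)
GEOM_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid sphere-set or configuration input."""


@dataclass(frozen=True)
class SphereSet:
    """A union of balls: centers (N,3) and radii (N,), both in angstrom.

    The reference point is the centroid of the centers and is recomputed on
    construction; it is the point about which guest rotations are applied and
    whose position a translation grid discretizes.
    """

    centers: np.ndarray
    radii: np.ndarray
    elements: tuple[str, ...] = ()
    reference: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.asarray(self.radii, dtype=float).ravel()
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise GeometryError("centers must have shape (N, 3)")
        if centers.shape[0] == 0:
            raise GeometryError("a SphereSet must contain at least one sphere")
        if radii.shape[0] != centers.shape[0]:
            raise GeometryError("centers and radii length mismatch")
        if not np.all(np.isfinite(centers)):
            raise GeometryError("sphere centers must be finite")
        if not np.all(radii > 0):
            raise GeometryError("all sphere radii must be positive")
        elements = tuple(self.elements) if self.elements else ("X",) * len(radii)
        if len(elements) != len(radii):
            raise GeometryError("elements length mismatch")
        centers.setflags(write=False)
        radii.setflags(write=False)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "elements", elements)
        ref = centers.mean(axis=0)
        ref.setflags(write=False)
        object.__setattr__(self, "reference", ref)

    def __len__(self) -> int:
        return self.centers.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SphereSet):
            return NotImplemented
        return (
            self.centers.shape == other.centers.shape
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.radii, other.radii)
            and self.elements == other.elements
        )


@dataclass(frozen=True)
class Configuration:
    """Rigid placement: translation ``t`` of the guest reference point plus a
    unit quaternion ``q`` (scalar-last, scipy convention) rotating the guest
    about its reference point."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        q = np.asarray(self.q, dtype=float).ravel()
        if t.shape != (3,):
            raise GeometryError("translation must be a 3-vector")
        if q.shape != (4,):
            raise GeometryError("quaternion must be a 4-vector")
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise GeometryError("quaternion must be unit length (|q| = 1 within 1e-9)")
        t.setflags(write=False)
        q.setflags(write=False)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)

    @classmethod
    def identity(cls) -> "Configuration":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]))

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.q)


@dataclass(frozen=True)
class ShapeSummary:
    """Bounding box of centers, circumradius about the reference point, and
    maximum sphere radius (all angstrom)."""

    box_lower: np.ndarray
    box_upper: np.ndarray
    circumradius: float
    max_radius: float


def perturb_radii(g: SphereSet, delta_r: float) -> SphereSet:
    """Add ``delta_r`` to every radius; centers are unchanged.

    Raises if any resulting radius would be non-positive, naming the
    smallest-radius atom.
    """
    new_radii = g.radii + float(delta_r)
    if np.any(new_radii <= 0):
        i = int(np.argmin(g.radii))
        raise GeometryError(
            f"radius perturbation {delta_r:+g} A drives atom {i} "
            f"({g.elements[i]}, r={g.radii[i]:g} A) to a non-positive radius"
        )
    return SphereSet(g.centers, new_radii, g.elements)


def transform(g: SphereSet, c: Configuration) -> SphereSet:
    """Rotate ``g`` by ``c.q`` about its reference point, then translate the
    reference point by ``c.t``; radii unchanged."""
    centers = c.rotation.apply(g.centers - g.reference) + g.reference + c.t
    return SphereSet(centers, g.radii, g.elements)


def placed_centers(g: SphereSet, c: Configuration) -> np.ndarray:
    """Centers of ``g`` under configuration ``c`` (no SphereSet allocation)."""
    return c.rotation.apply(g.centers - g.reference) + g.reference + c.t


class HostIndex:
    """Exact nearest-pair acceleration over a host sphere set.

    Host spheres are grouped by radius; within a group the sphere minimising
    ``d - r`` (or maximising ``r - d``) is exactly the nearest center, so a
    per-group k-d tree query returns the exact all-pairs extremum.
    """

    def __init__(self, host: SphereSet):
        self.host = host
        self._groups: list[tuple[float, cKDTree]] = []
        for r in np.unique(host.radii):
            mask = host.radii == r
            self._groups.append((float(r), cKDTree(host.centers[mask])))

    def min_clearance_points(self, points: np.ndarray, point_radii: np.ndarray) -> np.ndarray:
        """For each query sphere (center, radius): min over host spheres of
        ``|p - c_i| - r_i - r_p``. Vectorized over query spheres."""
        points = np.atleast_2d(points)
        best = np.full(points.shape[0], np.inf)
        for r, tree in self._groups:
            d, _ = tree.query(points)
            np.minimum(best, d - r, out=best)
        return best - np.asarray(point_radii, dtype=float)

    def max_penetration_points(self, points: np.ndarray, point_radii: np.ndarray) -> np.ndarray:
        """For each query sphere: max over host spheres of ``r_i + r_p - d``."""
        points = np.atleast_2d(points)
        best = np.full(points.shape[0], -np.inf)
        for r, tree in self._groups:
            d, _ = tree.query(points)
            np.maximum(best, r - d, out=best)
        return best + np.asarray(point_radii, dtype=float)


def min_clearance(
    host: SphereSet,
    guest: SphereSet,
    c: Configuration | None = None,
    index: HostIndex | None = None,
) -> float:
    """Minimum over all host-guest sphere pairs of ``d - r_host - r_guest``
    at placement ``c`` (identity if omitted). Negative means collision."""
    pts = guest.centers if c is None else placed_centers(guest, c)
    idx = index if index is not None else HostIndex(host)
    return float(idx.min_clearance_points(pts, guest.radii).min())


def max_penetration(
    host: SphereSet,
    guest: SphereSet,
    c: Configuration | None = None,
    index: HostIndex | None = None,
) -> float:
    """Maximum over all host-guest sphere pairs of ``r_host + r_guest - d``
    at placement ``c``. A value <= 0 means the placement is collision-free.

    Computed as an independent maximum, not by negating ``min_clearance``:
    the deepest-overlap pair need not be the smallest-gap pair.
    """
    pts = guest.centers if c is None else placed_centers(guest, c)
    idx = index if index is not None else HostIndex(host)
    return float(idx.max_penetration_points(pts, guest.radii).max())


def shape_summary(g: SphereSet) -> ShapeSummary:
    dist = np.linalg.norm(g.centers - g.reference, axis=1)
    return ShapeSummary(
        box_lower=g.centers.min(axis=0),
        box_upper=g.centers.max(axis=0),
        circumradius=float(dist.max()),
        max_radius=float(g.radii.max()),
    )
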