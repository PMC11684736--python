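"""Analytic cage/guest families with certified ground truth, plus
brute-force oracles used to anchor testing without external data.

The workhorse geometry is a spherical shell cage: ``n_s`` spheres of radius
``r_s`` placed quasi-uniformly on a sphere of radius ``R`` around the
origin, optionally with a polar aperture (all spheres within half-angle
``alpha`` of +z removed). Its cavity clearance is exactly ``R - r_s``; its
straight-ray passage bound is computed by :func:`passage_oracle`. These are
not chemically realistic cages — chemical realism is irrelevant to geometric
correctness testing — but they exercise every code path of the verifier,
including file parsing when emitted as xyz.

The escape oracle is an exhaustive fine-grid flood fill over strictly
collision-free configurations. Note the asymmetry: ``escape_found`` is a
certificate (a concrete validated exit path); ``no_escape_at_resolution``
is not a proof.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cspace import build_orientation_set, build_translation_grid
from .geometry import (
    Configuration,
    GeometryError,
    HostIndex,
    SphereSet,
    min_clearance,
)

__all__ = [
    "ShellCageSpec",
    "OracleReport",
    "make_shell_cage",
    "make_guest_ball",
    "make_dumbbell_guest",
    "passage_oracle",
    "escape_oracle",
    "jittered_ensemble",
    "emit_fixture_files",
]


@dataclass(frozen=True)
class ShellCageSpec:
    """A shell cage request plus its certified geometry facts."""

    shell_radius: float  # R, angstrom
    sphere_radius: float  # r_s, angstrom
    n_spheres: int  # spheres requested on the shell
    aperture: float  # polar aperture half-angle, radians (0 = closed)
    cavity_clearance: float | None = None  # R - r_s, exact
    passage_bound: float | None = None  # straight-ray bound, oracle-computed


@dataclass(frozen=True)
class OracleReport:
    """Result of the brute-force escape search."""

    outcome: str  # escape_found | no_escape_at_resolution
    path: tuple[Configuration, ...] | None
    params: dict


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_shell_cage(
    shell_radius: float,
    sphere_radius: float,
    n_spheres: int,
    aperture: float = 0.0,
    target_passage: float | None = None,
    probe_directions: int = 2048,
    element: str = "X",
) -> tuple[SphereSet, ShellCageSpec]:
    """Build a shell cage and certify its cavity clearance and passage bound.

    For a closed shell (aperture 0) with a ``target_passage``, the oracle
    bound must come out strictly below the target, otherwise the request is
    infeasible at this ``n_spheres`` and an error suggests increasing it.
    """
    if not shell_radius > sphere_radius > 0:
        raise ValueError("need shell_radius > sphere_radius > 0")
    if n_spheres < 12:
        raise ValueError("need at least 12 shell spheres")
    dirs = fibonacci_sphere(n_spheres)
    if aperture > 0:
        polar = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
        dirs = dirs[polar > aperture]
        if dirs.shape[0] == 0:
            raise ValueError(f"aperture half-angle {aperture:g} rad removes every shell sphere")
    centers = shell_radius * dirs
    host = SphereSet(centers, np.full(len(centers), float(sphere_radius)), (element,) * len(centers))
    bound = passage_oracle(host, probe_directions, center=np.zeros(3))
    if aperture == 0.0 and target_passage is not None and bound >= target_passage:
        raise ValueError(
            f"closed shell with n_spheres={n_spheres} has straight-ray passage bound "
            f"{bound:.3f} A >= target {target_passage:g} A; increase n_spheres"
        )
    spec = ShellCageSpec(
        shell_radius=float(shell_radius),
        sphere_radius=float(sphere_radius),
        n_spheres=int(n_spheres),
        aperture=float(aperture),
        cavity_clearance=float(shell_radius - sphere_radius),
        passage_bound=float(bound),
    )
    return host, spec


def make_guest_ball(r: float, element: str = "X") -> SphereSet:
    """Single-ball guest at the origin (circumradius 0)."""
    if r <= 0:
        raise ValueError("guest ball radius must be positive")
    return SphereSet(np.zeros((1, 3)), np.array([float(r)]), (element,))


def make_dumbbell_guest(r: float, half_separation: float, element: str = "X") -> SphereSet:
    """Two-ball guest along x at (+/- half_separation, 0, 0) — the smallest
    guest whose placements genuinely depend on orientation."""
    if r <= 0 or half_separation <= 0:
        raise ValueError("dumbbell radius and separation must be positive")
    centers = np.array([[-half_separation, 0.0, 0.0], [half_separation, 0.0, 0.0]])
    return SphereSet(centers, np.full(2, float(r)), (element, element))


def passage_oracle(
    host: SphereSet,
    probe_directions: int = 2048,
    center: np.ndarray | None = None,
) -> float:
    """Straight-ray passage bound: max over exit rays from the cage center of
    min over host spheres of (distance from sphere center to the ray - r).

    This is the largest ball radius that could slide out of the cage along a
    straight ray — a lower-bound certificate of escapability, and (for closed
    quasi-uniform shells, with margin) a construction target for caged
    fixtures. Probe directions are a Fibonacci lattice plus the six axis
    directions, so axis-aligned openings are probed exactly.
    """
    c0 = host.reference if center is None else np.asarray(center, dtype=float)
    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    dirs = np.vstack([fibonacci_sphere(probe_directions), axes])
    rel = host.centers - c0  # (n, 3)
    dots = rel @ dirs.T  # (n, d)
    t = np.clip(dots, 0.0, None)
    d2 = (rel * rel).sum(axis=1)[:, None] - 2.0 * t * dots + t * t
    dist = np.sqrt(np.clip(d2, 0.0, None))
    clearances = dist - host.radii[:, None]  # (n, d)
    return float(clearances.min(axis=0).max())


def escape_oracle(
    host: SphereSet,
    guest: SphereSet,
    start: Configuration,
    h: float = 0.5,
    n_orientations: int = 1,
    clearance_tol: float = 0.0,
) -> OracleReport:
    """Exhaustive strict-free flood fill over a fine configuration grid.

    Nodes are (orientation sample, translation node) with the node placement
    required to be strictly collision-free (min_clearance > clearance_tol).
    Breadth-first search starts from the node nearest ``start`` and succeeds
    when it reaches the outermost translation layer, returning the concrete
    path (including ``start``); every reported path is re-validated step by
    step by the caller via per-configuration clearance checks.
    """
    if min_clearance(host, guest, start) <= 0:
        raise GeometryError("escape oracle start configuration is in collision")
    grid = build_translation_grid(host, guest, h)
    oset = build_orientation_set(max(1, n_orientations), "full")
    index = HostIndex(host)
    cells = grid.cell_centers()
    rel = guest.centers - guest.reference
    n_o = len(oset)

    free = np.empty((n_o, grid.n_cells), dtype=bool)
    for o in range(n_o):
        offs = Configuration(np.zeros(3), oset.quats[o]).rotation.apply(rel)
        clear = np.full(grid.n_cells, np.inf)
        for j in range(len(guest)):
            np.minimum(
                clear, index.min_clearance_points(cells + offs[j], guest.radii[j]), out=clear
            )
        free[o] = clear > clearance_tol
    free = free.reshape((n_o,) + grid.shape)

    start_ref = guest.reference + start.t
    start_cell = tuple(grid.cell_of(start_ref)[0])
    start_o = oset.nearest(start.q)
    if not free[start_o][start_cell]:
        return OracleReport(
            "no_escape_at_resolution",
            None,
            {"h": h, "n_orientations": n_o, "note": "start node not strictly free at this resolution"},
        )

    boundary = grid.boundary_mask()
    shape = grid.shape
    steps = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    onbr: list[list[int]] = [[] for _ in range(n_o)]
    for a, b in oset.adjacency:
        onbr[a].append(b)
        onbr[b].append(a)

    first = (start_o,) + start_cell
    parent: dict[tuple, tuple | None] = {first: None}
    queue = deque([first])
    goal = None
    while queue:
        node = queue.popleft()
        o, i, j, k = node
        if boundary[i, j, k]:
            goal = node
            break
        for dx, dy, dz in steps:
            ni, nj, nk = i + dx, j + dy, k + dz
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                nxt = (o, ni, nj, nk)
                if nxt not in parent and free[o, ni, nj, nk]:
                    parent[nxt] = node
                    queue.append(nxt)
        for no in onbr[o]:
            nxt = (no, i, j, k)
            if nxt not in parent and free[no, i, j, k]:
                parent[nxt] = node
                queue.append(nxt)

    params = {"h": h, "n_orientations": n_o, "grid_shape": list(shape)}
    if goal is None:
        return OracleReport("no_escape_at_resolution", None, params)
    path_nodes = []
    node = goal
    while node is not None:
        path_nodes.append(node)
        node = parent[node]
    path_nodes.reverse()
    flat = np.ravel_multi_index(np.array([n[1:] for n in path_nodes]).T, shape)
    configs = [start] + [
        Configuration(cells[f] - guest.reference, oset.quats[n[0]])
        for n, f in zip(path_nodes, flat)
    ]
    return OracleReport("escape_found", tuple(configs), params)


def validate_escape_path(
    host: SphereSet,
    guest: SphereSet,
    report: OracleReport,
    step_bound: float | None = None,
) -> bool:
    """Independently re-validate an oracle escape path: every configuration
    strictly free, consecutive translation steps bounded, and the final
    reference point outside the host center box inflated by the grid margin."""
    if report.outcome != "escape_found" or not report.path:
        return False
    h = report.params["h"]
    bound = step_bound if step_bound is not None else np.sqrt(3.0) * h + 1e-9
    pts = [guest.reference + c.t for c in report.path]
    for c in report.path:
        if min_clearance(host, guest, c) <= 0:
            return False
    for a, b in zip(pts[1:-1], pts[2:]):  # first hop is the start snap
        if np.linalg.norm(b - a) > bound:
            return False
    grid = build_translation_grid(host, guest, h)
    end = pts[-1]
    inner_lo = grid.lower + grid.h
    inner_hi = grid.upper - grid.h
    return bool(np.any(end < inner_lo + 1e-9) or np.any(end > inner_hi - 1e-9))


def make_screening_hosts(
    n: int = 38, seed: int = 1, n_spheres: int = 40
) -> list[tuple[str, SphereSet]]:
    """A varied family of shell cages mimicking the shape of a real host
    screen: randomized shell radius, sphere radius and (for half of them)
    polar apertures, so a screen against a ball series produces all three
    classes. Deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    hosts = []
    for i in range(n):
        shell_r = float(rng.uniform(2.2, 3.2))
        sphere_r = float(rng.uniform(0.7, 1.0))
        aperture = float(rng.uniform(0.6, 1.1)) if i % 2 else 0.0
        host, _ = make_shell_cage(
            shell_r, sphere_r, n_spheres, aperture,
            probe_directions=256, element=f"Ca{i:02d}",
        )
        hosts.append((f"host{i:02d}", host))
    return hosts


def make_screening_guests(radii=(0.8, 1.1, 1.4, 1.8)) -> list[tuple[str, SphereSet]]:
    """Ball-guest series of increasing size (analogue of a homologous guest
    set: same shape, growing volume). Each size gets its own element tag so
    emitted files carry unambiguous radii entries."""
    return [
        (f"guest_r{r:g}", make_guest_ball(float(r), element=f"Gu{i}"))
        for i, r in enumerate(radii)
    ]


def random_escapable_case(rng: np.random.Generator, dumbbell: bool = False):
    """One randomized apertured-shell case built to be escapable: the guest
    is sized well below the shell's certified straight-ray passage bound, so
    the escape oracle can certify an exit path through the aperture.

    Returns (host, guest, start configuration at the cage center).
    """
    shell_r = float(rng.uniform(2.4, 3.4))
    sphere_r = float(rng.uniform(0.6, 0.9))
    n_s = int(rng.integers(40, 80))
    aperture = float(rng.uniform(0.8, 1.2))
    host, spec = make_shell_cage(
        shell_r, sphere_r, n_s, aperture=aperture, probe_directions=256
    )
    cap = min(spec.passage_bound - 0.3, spec.cavity_clearance - 0.4)
    r_guest = float(rng.uniform(0.3, max(0.31, cap)))
    if dumbbell:
        half = min(0.3, 0.5 * r_guest)
        guest = make_dumbbell_guest(max(0.25, r_guest - half), half)
    else:
        guest = make_guest_ball(r_guest)
    return host, guest, Configuration.identity()


def make_ensemble_guests(radii=(1.0, 1.6, 2.2)) -> list[tuple[str, SphereSet]]:
    """Three ball guests spanning the caging regimes of the default ensemble
    host (cavity clearance 2.0 A): well below threshold, near threshold, and
    cavity overflow."""
    return [
        (f"guest_r{r:g}", make_guest_ball(float(r), element=f"Ge{i}"))
        for i, r in enumerate(radii)
    ]


def jittered_ensemble(
    base: SphereSet, count: int, sigma: float = 0.1, seed: int = 0
) -> list[SphereSet]:
    """Gaussian coordinate jitter around one geometry: emulates the *shape*
    of a conformational ensemble (many near-identical conformations), not
    its physics."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        noise = rng.normal(scale=sigma, size=base.centers.shape)
        out.append(SphereSet(base.centers + noise, base.radii, base.elements))
    return out


def emit_fixture_files(
    fixtures: dict[str, SphereSet], directory: str | Path
) -> tuple[list[Path], Path]:
    """Write each fixture as an xyz file plus one radii override table
    covering the fixture element tags, so the full pipeline — including file
    parsing — can be exercised end to end.

    All spheres sharing an element tag must share a radius (one table entry
    per tag); violations raise.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    radii: dict[str, float] = {}
    paths = []
    for label, g in fixtures.items():
        for el, r in zip(g.elements, g.radii):
            if el in radii and abs(radii[el] - r) > 1e-12:
                raise ValueError(
                    f"fixture element tag {el!r} used with conflicting radii "
                    f"({radii[el]:g} and {r:g}); use distinct tags"
                )
            radii[el] = float(r)
        lines = [str(len(g)), label]
        for el, (x, y, z) in zip(g.elements, g.centers):
            lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
        p = directory / f"{label}.xyz"
        p.write_text("\n".join(lines) + "\n")
        paths.append(p)
    table = directory / "radii.txt"
    table.write_text(
        "\n".join(f"{el} {r:.8f}" for el, r in sorted(radii.items())) + "\n"
    )
    return paths, table
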