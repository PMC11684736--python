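"""Configuration-space discretization, flood fill, and caging verification."""

from collections import deque

import numpy as np
import pytest

from molcage.cspace import (
    CSpaceMap,
    OrientationSet,
    TranslationGrid,
    VerifyParams,
    build_orientation_set,
    build_translation_grid,
    compute_margin,
    escape_reachable,
    find_witness,
    label_cells,
    quat_geodesic,
    verify_caging,
)
from molcage.fixtures import make_guest_ball
from molcage.geometry import Configuration, SphereSet, min_clearance

from conftest import random_configuration


class TestOrientationSet:
    def test_fixed_mode_is_single_identity(self):
        oset = build_orientation_set(1, "fixed")
        assert len(oset) == 1
        assert oset.theta_cov == 0.0
        assert np.allclose(oset.quats[0], [0, 0, 0, 1])

    def test_full_mode_count_and_connectivity(self):
        oset = build_orientation_set(60)
        assert len(oset) == 60
        assert oset.theta_cov > 0
        assert oset.is_connected()

    def test_covering_radius_validated_by_sampling(self, rng):
        """Random orientations all lie within theta_cov of some sample."""
        oset = build_orientation_set(24)
        probes = rng.standard_normal((2000, 4))
        probes /= np.linalg.norm(probes, axis=1, keepdims=True)
        nearest = quat_geodesic(probes, oset.quats).min(axis=1)
        assert nearest.max() <= oset.theta_cov

    def test_doubling_never_increases_covering_radius(self):
        for n in (16, 30, 60):
            assert build_orientation_set(2 * n).theta_cov <= build_orientation_set(n).theta_cov

    def test_invalid_requests(self):
        with pytest.raises(ValueError):
            build_orientation_set(0)
        with pytest.raises(ValueError):
            build_orientation_set(2, "fixed")


class TestTranslationGrid:
    def test_box_inflation_formula(self):
        host = SphereSet(np.array([[-5.0, -5, -5], [5.0, 5, 5]]), np.array([1.5, 1.5]))
        guest = SphereSet(np.array([[-2.0, 0, 0], [2.0, 0, 0]]), np.array([1.0, 1.0]))
        # rho_guest = 2.0, max radii 1.5 and 1.0, h = 0.5 -> inflate by 5.5
        grid = build_translation_grid(host, guest, 0.5)
        assert np.allclose(grid.lower, -10.5)
        assert np.allclose(grid.upper, 10.5)

    def test_minimum_three_cells_per_axis(self):
        host = SphereSet(np.zeros((1, 3)), np.array([0.1]))
        guest = SphereSet(np.zeros((1, 3)), np.array([0.1]))
        grid = build_translation_grid(host, guest, 5.0)
        assert min(grid.shape) >= 3

    def test_boundary_layer_placements_are_free(self, apertured_shell, dumbbell_guest, rng):
        """1,000 random placements with the reference point anywhere in the
        outermost cell layer are collision-free at any orientation."""
        host, _ = apertured_shell
        grid = build_translation_grid(host, dumbbell_guest, 0.5)
        bmask = grid.boundary_mask()
        cells = grid.cell_centers()[bmask.ravel()]
        picks = rng.integers(0, len(cells), 1000)
        jitter = rng.uniform(-grid.h / 2, grid.h / 2, (1000, 3))
        for point, dx in zip(cells[picks], jitter):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            c = Configuration(point + dx - dumbbell_guest.reference, q)
            assert min_clearance(host, dumbbell_guest, c) > 0

    def test_nonpositive_h_rejected(self, small_shell, ball_guest):
        with pytest.raises(ValueError):
            build_translation_grid(small_shell[0], ball_guest, 0.0)


class TestMargin:
    def test_margin_formula(self):
        # h 0.5, theta_cov 0.2, rho 2.0 -> sqrt(3)/2*0.5 + 2*2*sin(0.1)
        expect = np.sqrt(3) / 2 * 0.5 + 2 * 2.0 * np.sin(0.1)
        assert compute_margin(0.5, 0.2, 2.0) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.8323, abs=1e-4)

    def test_fixed_mode_margin_has_no_rotation_term(self):
        assert compute_margin(0.5, 0.0, 2.0) == pytest.approx(np.sqrt(3) / 4)


class TestLabelCells:
    def test_tiny_pair_blocks_only_a_bounded_blob(self):
        host = SphereSet(np.zeros((1, 3)), np.array([0.4]))
        guest = make_guest_ball(0.4)
        oset = build_orientation_set(1, "fixed")
        grid = TranslationGrid(np.full(3, -5.25), 0.5, (21, 21, 21))
        cmap = label_cells(host, guest, oset, grid)
        blocked = ~cmap.free[0]
        assert 0 < blocked.sum() < 30  # a small blob near the origin
        centers = grid.cell_centers()[blocked.ravel()]
        assert np.linalg.norm(centers, axis=1).max() < 1.5

    def test_strictly_free_configurations_land_in_free_cells(
        self, apertured_shell, dumbbell_guest, rng
    ):
        """Over-approximation: 1,000 random strictly-free placements are all
        labeled FREE_POSSIBLE at their (cell, nearest-orientation) index."""
        host, _ = apertured_shell
        oset = build_orientation_set(20)
        grid = build_translation_grid(host, dumbbell_guest, 0.5)
        cmap = label_cells(host, dumbbell_guest, oset, grid)
        span = grid.upper - grid.lower
        found = 0
        while found < 1000:
            point = grid.lower + rng.uniform(0, 1, 3) * span
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            c = Configuration(point - dumbbell_guest.reference, q)
            if min_clearance(host, dumbbell_guest, c) > 0:
                found += 1
                assert cmap.label_at(q, point)

    def test_blocked_cells_contain_only_collisions(self, small_shell, dumbbell_guest, rng):
        """The certainty direction: random placements indexed to a
        BLOCKED_CERTAIN cell are never strictly free."""
        host, _ = small_shell
        oset = build_orientation_set(12)
        grid = build_translation_grid(host, dumbbell_guest, 0.5)
        cmap = label_cells(host, dumbbell_guest, oset, grid)
        span = grid.upper - grid.lower
        checked = 0
        for _ in range(20000):
            if checked >= 300:
                break
            point = grid.lower + rng.uniform(0, 1, 3) * span
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            if not cmap.label_at(q, point):
                checked += 1
                c = Configuration(point - dumbbell_guest.reference, q)
                assert min_clearance(host, dumbbell_guest, c) <= 1e-9
        assert checked > 0


def bfs_reachable(free: np.ndarray, adjacency, boundary: np.ndarray) -> np.ndarray:
    """Independent breadth-first flood fill over (orientation, cell) nodes."""
    n_o, nx, ny, nz = free.shape
    nbrs = [[] for _ in range(n_o)]
    for a, b in adjacency:
        nbrs[a].append(b)
        nbrs[b].append(a)
    seen = np.zeros_like(free)
    queue = deque()
    for o in range(n_o):
        for i, j, k in zip(*np.nonzero(boundary & free[o])):
            if not seen[o, i, j, k]:
                seen[o, i, j, k] = True
                queue.append((o, i, j, k))
    while queue:
        o, i, j, k = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (di or dj or dk) and 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz:
                        if free[o, ni, nj, nk] and not seen[o, ni, nj, nk]:
                            seen[o, ni, nj, nk] = True
                            queue.append((o, ni, nj, nk))
        for no in nbrs[o]:
            if free[no, i, j, k] and not seen[no, i, j, k]:
                seen[no, i, j, k] = True
                queue.append((no, i, j, k))
    return seen


def toy_map(free, adjacency=()):
    n_o = free.shape[0]
    qs = np.tile([0.0, 0.0, 0.0, 1.0], (n_o, 1))
    oset = OrientationSet(qs, 0.5, tuple(adjacency), "full" if n_o > 1 else "fixed")
    grid = TranslationGrid(np.zeros(3), 1.0, free.shape[1:])
    return CSpaceMap(free=free, grid=grid, oset=oset, margin=0.5)


class TestEscapeReachable:
    def test_all_free_map_fully_reached(self):
        cmap = toy_map(np.ones((2, 5, 5, 5), dtype=bool), [(0, 1)])
        assert escape_reachable(cmap).all()

    def test_closed_blocked_shell_shields_interior(self):
        free = np.ones((1, 7, 7, 7), dtype=bool)
        free[0, 1:6, 1:6, 1:6] = False  # blocked box shell...
        free[0, 2:5, 2:5, 2:5] = True  # ...with a free interior
        reached = escape_reachable(toy_map(free))
        assert reached[0, 0, 0, 0]
        assert not reached[0, 3, 3, 3]
        assert not reached[0][2:5, 2:5, 2:5].any()

    def test_orientation_adjacency_can_open_a_path(self):
        """A cell blocked at one orientation but free at an adjacent one lets
        the fill pass through by rotating in place."""
        free = np.ones((2, 5, 5, 5), dtype=bool)
        free[0, 2, :, :] = False  # orientation 0 is walled
        free[0, 2, 2, 2] = True  # except one cell
        free[1, :, :, :] = False  # orientation 1 exists only at that cell
        free[1, 2, 2, 2] = True
        connected = escape_reachable(toy_map(free, [(0, 1)]))
        isolated = escape_reachable(toy_map(free, []))
        assert connected[1, 2, 2, 2]
        assert not isolated[1, 2, 2, 2]

    def test_agreement_with_independent_bfs(self, rng):
        for _ in range(10):
            n_o = int(rng.integers(1, 4))
            free = rng.uniform(size=(n_o, 8, 8, 8)) < 0.55
            adjacency = [(a, b) for a in range(n_o) for b in range(a + 1, n_o)
                         if rng.uniform() < 0.7]
            cmap = toy_map(free, adjacency)
            expect = bfs_reachable(free, adjacency, cmap.grid.boundary_mask())
            assert np.array_equal(escape_reachable(cmap), expect)


class TestFindWitness:
    def test_absent_when_everything_reachable(self, small_shell, ball_guest):
        host, _ = small_shell
        oset = build_orientation_set(1, "fixed")
        grid = build_translation_grid(host, ball_guest, 0.6)
        cmap = label_cells(host, ball_guest, oset, grid)
        everything = np.ones_like(cmap.free)
        assert find_witness(host, ball_guest, cmap, everything) is None

    def test_returns_first_strictly_free_nonreachable_center(self):
        host = SphereSet(np.zeros((1, 3)), np.array([0.5]))
        guest = make_guest_ball(0.5)
        oset = build_orientation_set(1, "fixed")
        grid = TranslationGrid(np.full(3, -4.0), 1.0, (8, 8, 8))
        cmap = label_cells(host, guest, oset, grid)
        reachable = np.ones_like(cmap.free)
        reachable[0, 6, 6, 6] = False  # far corner cell: strictly free
        reachable[0, 7, 7, 7] = False
        w = find_witness(host, guest, cmap, reachable)
        assert w is not None
        assert np.allclose(w.t + guest.reference, grid.cell_centers()[6 * 64 + 6 * 8 + 6])
        assert min_clearance(host, guest, w) > 0


class TestVerifyCaging:
    def test_closed_shell_proven_caged(self, closed_shell, ball_guest):
        host, spec = closed_shell
        assert spec.passage_bound < 0.5
        v = verify_caging(host, ball_guest, VerifyParams(h=0.5, refine_levels=2))
        assert v.outcome == "PROVEN_CAGED"
        assert v.diagnostic == "witness_found"
        assert min_clearance(host, ball_guest, v.witness) > 0

    def test_apertured_shell_not_proven(self, apertured_shell, ball_guest):
        host, spec = apertured_shell
        assert spec.passage_bound > ball_guest.radii[0]
        v = verify_caging(host, ball_guest, VerifyParams(h=0.5, refine_levels=1))
        assert v.outcome == "NOT_PROVEN"
        assert v.diagnostic == "escape_not_excluded"
        assert v.witness is None

    def test_oversized_guest_cannot_fit(self, closed_shell):
        host, spec = closed_shell
        big = make_guest_ball(spec.cavity_clearance + 0.8)
        v = verify_caging(host, big, VerifyParams(h=0.5, refine_levels=1))
        assert v.outcome == "NOT_PROVEN"
        assert v.diagnostic == "no_interior_free_cell"

    def test_dumbbell_guest_proven_caged(self, closed_shell, dumbbell_guest):
        v = verify_caging(closed_shell[0], dumbbell_guest,
                          VerifyParams(h=0.5, n_orientations=60, refine_levels=1))
        assert v.outcome == "PROVEN_CAGED"

    def test_proof_persists_under_refinement(self, closed_shell, ball_guest):
        """Once proven at resolution h, halving h (one refinement level)
        still proves caging."""
        host, _ = closed_shell
        v0 = verify_caging(host, ball_guest, VerifyParams(h=0.5, refine_levels=0))
        v1 = verify_caging(host, ball_guest, VerifyParams(h=0.25, refine_levels=0))
        assert v0.outcome == v1.outcome == "PROVEN_CAGED"

    def test_blocked_set_grows_with_guest_radius(self, small_shell):
        """On a fixed grid, inflating the ball guest only adds blocked cells."""
        host, _ = small_shell
        oset = build_orientation_set(1, "fixed")
        grid = build_translation_grid(host, make_guest_ball(2.0), 0.5)
        prev_blocked = None
        for r in (0.6, 1.0, 1.4, 1.8):
            cmap = label_cells(host, make_guest_ball(r), oset, grid)
            blocked = ~cmap.free
            if prev_blocked is not None:
                assert (blocked | prev_blocked).sum() == blocked.sum()
            prev_blocked = blocked

    def test_verdict_is_deterministic(self, closed_shell, dumbbell_guest):
        p = VerifyParams(h=0.5, n_orientations=20, refine_levels=0)
        a = verify_caging(closed_shell[0], dumbbell_guest, p)
        b = verify_caging(closed_shell[0], dumbbell_guest, p)
        assert a.outcome == b.outcome
        assert np.array_equal(a.witness.t, b.witness.t)
        assert np.array_equal(a.witness.q, b.witness.q)
        assert a.params == b.params
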