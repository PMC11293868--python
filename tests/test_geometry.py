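"""Gyration-tensor machinery: closed forms, invariances, and oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

from dropletkit import geometry
from dropletkit.aggregates import assign_all_frames
from dropletkit.geometry import (
    EllipsoidAxes,
    axes_series,
    axis_angle_deg,
    chain_rg_by_phase,
    ellipsoid_axes,
    gyration_tensor,
    kabsch_rmsd,
    make_chain_whole,
    mean_droplet_radius,
    neighbour_orientation_angles,
)
from dropletkit.synthdata import gen_chain

from conftest import make_system


class TestGyrationTensor:
    def test_single_bead(self):
        res = gyration_tensor(np.array([[1.0, 2.0, 3.0]]))
        assert res.rg == 0.0
        np.testing.assert_allclose(res.eigenvalues, 0.0)

    def test_two_equal_mass_beads(self):
        res = gyration_tensor(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert res.rg == pytest.approx(0.5)
        np.testing.assert_allclose(res.eigenvalues, [0.25, 0.0, 0.0], atol=1e-12)

    def test_uniform_sphere_eigenvalues(self):
        # uniform ball of radius A: every eigenvalue = A^2 / 5
        rng = np.random.default_rng(0)
        g = rng.normal(size=(100_000, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        pts = 3.0 * g * (rng.random(100_000) ** (1 / 3))[:, None]
        res = gyration_tensor(pts)
        np.testing.assert_allclose(res.eigenvalues, 9.0 / 5.0, rtol=0.02)

    def test_mass_weighting_moves_com(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        res = gyration_tensor(coords, masses=np.array([3.0, 1.0]))
        # com at 0.25; rg^2 = (3*0.0625 + 1*0.5625)/4 = 0.1875
        assert res.rg == pytest.approx(np.sqrt(0.1875))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(50, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        a = gyration_tensor(coords)
        b = gyration_tensor(coords @ rot.T)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-10)
        assert a.rg == pytest.approx(b.rg)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            gyration_tensor(np.zeros((2, 3)), masses=np.zeros(2))

    def test_eigenvalue_invariants(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            res = gyration_tensor(rng.normal(size=(20, 3)), masses=rng.random(20) + 0.1)
            eig = res.eigenvalues
            assert eig[0] >= eig[1] >= eig[2] >= 0
            assert res.rg**2 == pytest.approx(eig.sum())
            np.testing.assert_allclose(
                res.eigenvectors.T @ res.eigenvectors, np.eye(3), atol=1e-8
            )


class TestEllipsoidAxes:
    def test_sphere(self):
        axes = ellipsoid_axes([1.0, 1.0, 1.0], R=2.0)
        assert (axes.a, axes.b, axes.c) == pytest.approx((2.0, 2.0, 2.0))
        assert axes.deltas == pytest.approx((0.0, 0.0, 0.0))

    def test_prolate_example(self):
        axes = ellipsoid_axes([4.0, 1.0, 1.0], R=1.0)
        assert axes.a == pytest.approx(4.0 ** (1 / 3))
        assert axes.b == pytest.approx(0.5 ** (1 / 3))
        assert axes.c == pytest.approx(0.5 ** (1 / 3))
        assert axes.a * axes.b * axes.c == pytest.approx(1.0)

    def test_scale_invariance(self):
        a1 = ellipsoid_axes([4.0, 2.0, 1.0], R=3.0)
        a2 = ellipsoid_axes([40.0, 20.0, 10.0], R=3.0)
        assert (a1.a, a1.b, a1.c) == pytest.approx((a2.a, a2.b, a2.c))

    def test_volume_conservation_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            eigs = np.sort(rng.random(3) * 10 + 0.01)[::-1]
            R = rng.random() * 5 + 0.1
            axes = ellipsoid_axes(eigs, R)
            assert axes.a * axes.b * axes.c == pytest.approx(R**3, rel=1e-9)
            assert axes.a >= axes.b >= axes.c

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(geometry.DegenerateShapeError):
            ellipsoid_axes([1.0, 1.0, 0.0], R=1.0)


class TestMeanDropletRadius:
    def test_uniform_sphere_recovers_radius(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=(50_000, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        pts = 3.0 * g * (rng.random(50_000) ** (1 / 3))[:, None]
        eigs = gyration_tensor(pts).eigenvalues
        assert mean_droplet_radius([eigs]) == pytest.approx(3.0, rel=0.02)

    def test_single_frame(self):
        eigs = np.array([2.0, 1.0, 0.5])
        expected = float(np.prod(np.sqrt(5 * eigs)) ** (1 / 3))
        assert mean_droplet_radius([eigs]) == pytest.approx(expected)

    def test_arithmetic_mean_of_frame_radii(self):
        # spheres of radius 2 and 4: eigenvalues r^2/5 each
        f1 = np.full(3, 4.0 / 5.0)
        f2 = np.full(3, 16.0 / 5.0)
        assert mean_droplet_radius([f1, f2]) == pytest.approx(3.0)


class TestKabschRMSD:
    def test_identity(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(10, 3))
        assert kabsch_rmsd(coords, coords) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(25, 3))
        rot = Rotation.random(random_state=8).as_matrix()
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        assert kabsch_rmsd(moved, coords) == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_minimization(self):
        # direct minimization over a dense rotation grid as oracle
        rng = np.random.default_rng(9)
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        best = np.inf
        for rot in Rotation.random(20_000, random_state=10):
            r = np.sqrt(((Pc @ rot.as_matrix().T - Qc) ** 2).sum(axis=1).mean())
            best = min(best, r)
        result = kabsch_rmsd(P, Q)
        # the analytic optimum can only undercut the grid search, and the
        # grid is dense enough to approach it
        assert result <= best + 1e-9
        assert best == pytest.approx(result, rel=0.05)

    def test_no_superposition(self):
        P = np.zeros((3, 3))
        Q = np.ones((3, 3))
        assert kabsch_rmsd(P, Q, superpose=False) == pytest.approx(np.sqrt(3.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestChainWholeAndRg:
    def test_make_chain_whole_across_boundary(self):
        box = np.array([10.0, 10.0, 10.0])
        # straight rod crossing the x boundary, wrapped
        x = np.array([9.5, 9.8, 0.1, 0.4])
        coords = np.c_[x, np.zeros(4), np.zeros(4)]
        whole = make_chain_whole(coords, box)
        steps = np.diff(whole[:, 0])
        np.testing.assert_allclose(steps, 0.3, atol=1e-12)

    def test_rg_by_phase_ground_truth(self):
        # extended rods in a droplet, compact blobs outside
        rod = gen_chain(20, bond_length=0.4, stiffness=np.inf, seed=0)
        blob = gen_chain(20, bond_length=0.15, stiffness=0.0, seed=1)
        chains = [rod + [0.05 * i, 0.0, 0.0] for i in range(6)]  # touching rods
        chains += [blob + [15.0, 15.0 * i % 30, 10.0] for i in range(2)]
        system = make_system(chains, box_edge=40.0)
        assignments = assign_all_frames(system)
        table = chain_rg_by_phase(system, assignments)
        dense_rg = table[table.phase == "dense"].rg_nm
        dilute_rg = table[table.phase == "dilute"].rg_nm
        rod_rg_expected = 0.4 * np.sqrt((20**2 - 1) / 12)
        assert dense_rg.mean() == pytest.approx(rod_rg_expected, rel=1e-6)
        assert dilute_rg.mean() < dense_rg.mean()
        assert len(table) == 8


class TestOrientationAngles:
    @staticmethod
    def _rod_pair_system(direction_b):
        rod = np.arange(8)[:, None] * np.array([0.3, 0.0, 0.0])
        rod_b = np.arange(8)[:, None] * (0.3 * np.asarray(direction_b))
        chains = [rod + [0, 0.5 * (i % 3), 0.4 * (i // 3)] for i in range(5)]
        chains.append(rod_b + [0.0, 1.0, 0.8])
        return make_system(chains, box_edge=20.0)

    def test_perpendicular_rods(self):
        system = self._rod_pair_system([0.0, 1.0, 0.0])
        assignments = assign_all_frames(system)
        table = neighbour_orientation_angles(system, assignments)
        pair_angles = table[(table.chain_i != 5) & (table.chain_j == 5)].angle_deg
        assert len(pair_angles) >= 1
        np.testing.assert_allclose(pair_angles.to_numpy(), 90.0, atol=1e-6)

    def test_parallel_rods(self):
        system = self._rod_pair_system([1.0, 0.0, 0.0])
        assignments = assign_all_frames(system)
        table = neighbour_orientation_angles(system, assignments)
        assert len(table) >= 1
        np.testing.assert_allclose(table.angle_deg.to_numpy(), 0.0, atol=1e-6)

    def test_each_unordered_pair_once(self):
        system = self._rod_pair_system([1.0, 0.0, 0.0])
        assignments = assign_all_frames(system)
        table = neighbour_orientation_angles(system, assignments)
        pairs = list(zip(table.chain_i, table.chain_j))
        assert len(pairs) == len(set(pairs))
        assert all(i < j for i, j in pairs)

    def test_isotropic_axes_follow_sine_density(self):
        # folded angle between two isotropic axes has density sin(theta) on [0, 90]
        rng = np.random.default_rng(11)
        n = 10_000
        u = rng.normal(size=(n, 3))
        v = rng.normal(size=(n, 3))
        angles = np.array([axis_angle_deg(a, b) for a, b in zip(u, v)])
        edges = np.linspace(0.0, 90.0, 10)
        observed, _ = np.histogram(angles, bins=edges)
        expected = n * np.diff(-np.cos(np.radians(edges)))
        assert chisquare(observed, expected).pvalue > 0.01


class TestAxesSeries:
    def test_rotation_invariant_axis_recovery(self):
        rng = np.random.default_rng(12)
        true_axes = np.array([5.2, 5.0, 4.8])
        g = rng.normal(size=(30_000, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        pts = g * (rng.random(30_000) ** (1 / 3))[:, None] * true_axes
        rot = Rotation.random(random_state=13).as_matrix()
        eigs_list = [
            gyration_tensor(pts).eigenvalues,
            gyration_tensor(pts @ rot.T).eigenvalues,
        ]
        R, axes = axes_series(eigs_list)
        for ax in axes:
            assert ax.a == pytest.approx(true_axes[0], rel=0.02)
            assert ax.c == pytest.approx(true_axes[2], rel=0.02)
        assert axes[0].a == pytest.approx(axes[1].a, rel=1e-6)
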