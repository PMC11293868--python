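"""Phase thermodynamics: volumes, concentrations, transfer free energy,
surface tension, steady state, and MSD."""

import numpy as np
import pytest

from dropletkit import thermo
from dropletkit.aggregates import assign_all_frames, assign_frame
from dropletkit.constants import DEFAULT_TEMPERATURE, K_BOLTZMANN
from dropletkit.geometry import DegenerateShapeError, EllipsoidAxes
from dropletkit.thermo import (
    delta_g_transfer,
    dilute_concentration_series,
    droplet_volume,
    fit_diffusion,
    msd,
    msd_system,
    phase_concentrations,
    surface_tension,
    track_droplets,
)

from conftest import make_system


class TestDropletVolume:
    def test_unit_eigenvalues(self):
        assert droplet_volume([1.0, 1.0, 1.0]) == pytest.approx(4 * np.pi / 3)

    def test_product_one(self):
        assert droplet_volume([4.0, 1.0, 0.25]) == pytest.approx(4 * np.pi / 3)

    def test_scaling_homogeneity(self):
        # scaling coordinates by s scales eigenvalues by s^2 and volume by s^3
        v1 = droplet_volume([2.0, 1.0, 0.5])
        v2 = droplet_volume([2.0 * 4, 1.0 * 4, 0.5 * 4])
        assert v2 == pytest.approx(8 * v1)

    def test_convention_factor(self):
        v = droplet_volume([1.0, 2.0, 3.0])
        v5 = droplet_volume([1.0, 2.0, 3.0], convention="sqrt-5-lambda")
        assert v5 == pytest.approx(v * 5**1.5)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateShapeError):
            droplet_volume([1.0, 1.0, 0.0])


class TestPhaseConcentrations:
    def test_unit_conversion_oracle(self):
        # 10 chains in 100 nm^3 is ~166 mM
        from dropletkit.constants import concentration_micromolar

        assert concentration_micromolar(10, 100.0) == pytest.approx(166_052, rel=1e-3)

    @staticmethod
    def _packed_positions():
        # seven single-bead chains forming one 3D droplet
        return [
            np.array([0.0, 0.0, 0.0]), np.array([0.6, 0.0, 0.0]),
            np.array([0.0, 0.6, 0.0]), np.array([0.0, 0.0, 0.6]),
            np.array([0.4, 0.4, 0.0]), np.array([0.0, 0.4, 0.4]),
            np.array([0.4, 0.0, 0.4]),
        ]

    def test_no_dilute_chains(self):
        chains = [p[None] for p in self._packed_positions()]
        system = make_system(chains, box_edge=20.0)
        pc = phase_concentrations(system, assign_frame(system, 0))
        assert pc.n_dilute == 0
        assert pc.c_dilute_uM == 0.0
        assert pc.c_dense_uM is not None and pc.c_dense_uM > 0

    def test_no_dense_cluster_reported_missing(self):
        chains = [np.array([[5.0 * i, 0.0, 0.0]]) for i in range(3)]
        system = make_system(chains, box_edge=30.0)
        pc = phase_concentrations(system, assign_frame(system, 0))
        assert pc.c_dense_uM is None
        assert pc.n_dense == 0

    def test_generator_ratio_within_construction(self):
        from dropletkit.synthdata import SynthSpec, gen_droplet_system

        spec = SynthSpec(n_chains_dense=20, n_chains_dilute=10, seed=7)
        system, truth = gen_droplet_system(spec)
        pc = phase_concentrations(
            system, assign_frame(system, 0), convention="sqrt-5-lambda"
        )
        a, b, c = truth.droplet_axes
        v_constructed = 4 * np.pi / 3 * a * b * c
        box_volume = float(np.prod(system.box[0]))
        constructed_ratio = (20 / v_constructed) / (10 / (box_volume - v_constructed))
        assert 0.5 < pc.ratio / constructed_ratio < 2.0


class TestDeltaG:
    def test_equal_concentrations(self):
        assert delta_g_transfer(5.0, 5.0) == 0.0

    def test_hundredfold_dilution(self):
        assert delta_g_transfer(1.0, 100.0, 310.15) == pytest.approx(-11.87, abs=0.01)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c1, c2 = rng.random(2) * 100 + 0.1
            assert delta_g_transfer(c1, c2) == pytest.approx(-delta_g_transfer(c2, c1))

    def test_negative_when_dense_favoured(self):
        assert delta_g_transfer(1.0, 50.0) < 0

    def test_invalid_concentrations(self):
        with pytest.raises(ValueError):
            delta_g_transfer(0.0, 1.0)


class TestSurfaceTension:
    def test_rigid_droplet_flags_infinity(self):
        frames = [EllipsoidAxes(2.0, 2.0, 2.0, 2.0)] * 5
        est = surface_tension(frames)
        assert est.rigid
        assert np.isinf(est.gamma20_mN_m)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            surface_tension([EllipsoidAxes(2.0, 2.0, 2.0, 2.0)])

    def test_iid_gaussian_closed_form(self):
        # i.i.d. deltas of variance v per axis: <(da+db)^2> -> 2v and
        # gamma20 -> 5 kB T / (32 pi v)
        rng = np.random.default_rng(1)
        R, sd = 5.0, 0.1
        deltas = rng.normal(0.0, sd, size=(10_000, 3))
        frames = [EllipsoidAxes(R + d[0], R + d[1], R + d[2], R) for d in deltas]
        est = surface_tension(frames, temperature=310.15)
        v = sd**2
        assert est.mean_sq_sum_nm2 == pytest.approx(2 * v, rel=0.05)
        assert est.mean_sq_diff_nm2 == pytest.approx(2 * v, rel=0.05)
        expected = 5 * K_BOLTZMANN * 310.15 / (32 * np.pi * v * 1e-18) * 1000
        assert est.gamma20_mN_m == pytest.approx(expected, rel=0.05)
        assert est.gamma22_mN_m == pytest.approx(3 * expected, rel=0.05)

    def test_linear_in_temperature(self):
        rng = np.random.default_rng(2)
        frames = [
            EllipsoidAxes(5 + a, 5 + b, 5 + c, 5.0)
            for a, b, c in rng.normal(0, 0.1, size=(100, 3))
        ]
        e1 = surface_tension(frames, temperature=300.0)
        e2 = surface_tension(frames, temperature=600.0)
        assert e2.gamma20_mN_m == pytest.approx(2 * e1.gamma20_mN_m)
        assert e2.gamma22_mN_m == pytest.approx(2 * e1.gamma22_mN_m)


class TestTrackDroplets:
    def test_persistent_droplet_single_segment(self, droplet_fixture):
        system, _ = droplet_fixture
        spec_frames = 3
        frames = np.repeat(system.coords, spec_frames, axis=0)
        multi = make_system(
            [frames[:, system.chain_indices(c)] for c in system.chain_ids],
            box_edge=system.box[0][0],
        )
        assignments = assign_all_frames(multi)
        segments = track_droplets(assignments, min_frames=2)
        assert len(segments) == 1
        assert len(segments[0]) == spec_frames

    def test_membership_swap_terminates_segment(self):
        # frame 0: cluster {0..5}; frame 1: completely different chains clustered
        rng = np.random.default_rng(3)
        far = [np.array([[4.0 * i + 40.0, 40.0, 40.0]]) for i in range(6)]
        near = [np.array([[0.5 * i, 0.0, 0.0]]) for i in range(6)]
        frame0 = near + far
        frame1 = far + near  # identities swapped
        chains = [np.stack([a[0:1], b[0:1]])[:, 0] for a, b in zip(frame0, frame1)]
        chains = [np.stack([a, b]) for a, b in zip(frame0, frame1)]
        system = make_system(chains, box_edge=100.0)
        assignments = assign_all_frames(system)
        segments = track_droplets(assignments, min_frames=1)
        assert len(segments) == 2


class TestDiluteSeries:
    def test_static_system_zero_drift(self, droplet_fixture):
        system, _ = droplet_fixture
        frames = np.repeat(system.coords, 4, axis=0)
        multi = make_system(
            [frames[:, system.chain_indices(c)] for c in system.chain_ids],
            box_edge=system.box[0][0],
        )
        out = dilute_concentration_series(multi, assign_all_frames(multi))
        assert out["relative_drift"] == pytest.approx(0.0, abs=1e-12)
        assert len(set(out["c_dilute_uM"])) == 1

    def test_chain_leaving_droplet_steps_concentration(self):
        # 7 tightly packed single-bead chains plus one dilute chain; after
        # frame 2 one chain leaves the droplet, doubling the dilute count
        box = 30.0
        packed = TestPhaseConcentrations._packed_positions()
        free = np.array([20.0, 20.0, 20.0])
        leaver_positions = [packed[6], packed[6], np.array([20.0, 5.0, 5.0]),
                            np.array([20.0, 5.0, 5.0])]
        chains = []
        for i in range(6):
            chains.append(np.tile(packed[i], (4, 1, 1)))
        chains.append(np.stack([p[None] for p in leaver_positions]))
        chains.append(np.tile(free, (4, 1, 1)))
        system = make_system(chains, box_edge=box)
        out = dilute_concentration_series(system, assign_all_frames(system), window=1)
        series = out["c_dilute_uM"]
        assert series[0] == pytest.approx(series[1])
        assert series[2] == pytest.approx(series[3])
        # droplet volume change is negligible next to the box volume
        assert series[2] / series[0] == pytest.approx(2.0, rel=0.01)


class TestMSD:
    def test_stationary_particles(self):
        coords = np.tile(np.random.default_rng(4).random((1, 10, 3)), (20, 1, 1))
        np.testing.assert_allclose(msd(coords), 0.0, atol=1e-12)

    def test_ballistic_motion(self):
        v = np.array([1.0, -2.0, 0.5])
        t = np.arange(50)[:, None, None]
        coords = np.tile(v, (50, 3, 1)) * t
        curve = msd(coords, max_lag=10)
        lags = np.arange(11)
        np.testing.assert_allclose(curve, (v @ v) * lags**2, rtol=1e-10)

    def test_brownian_diffusion_recovery(self):
        from dropletkit.synthdata import gen_brownian

        D, dt = 0.5, 1.0
        coords = gen_brownian(1000, D=D, dt=dt, n_steps=500, seed=5)
        curve = msd(coords, max_lag=50)
        assert fit_diffusion(curve, dt) == pytest.approx(D, rel=0.05)

    def test_wrapped_trajectory_refused(self):
        system = make_system([np.zeros((2, 1, 3))], wrapped=True)
        with pytest.raises(ValueError, match="unwrapped"):
            msd_system(system)
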