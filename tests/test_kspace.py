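"""Golden-angle trajectory, direct NUDFT operators and preprocessing."""

import numpy as np
import pytest

from cminr import kspace as ks
from cminr.metrics import relative_error
from cminr.synthetic import Ellipsoid, PhantomSpec, generate_phantom
from cminr.volumes import ComplexVolume


def brute_force_nudft(slice2d, traj):
    """Independent double-loop direct sum oracle (one slice)."""
    H, W = slice2d.shape
    cx, cy = H // 2, W // 2
    out = np.zeros(traj.n_samples, dtype=complex)
    for s in range(traj.n_samples):
        kx, ky = traj.sample_coords[s]
        acc = 0.0 + 0.0j
        for m in range(H):
            for n in range(W):
                acc += slice2d[m, n] * np.exp(
                    -1j * (kx * (m - cx) + ky * (n - cy))
                )
        out[s] = acc
    return out


class TestTrajectory:
    def test_golden_angle_increment(self):
        traj = ks.golden_angle_trajectory(3, 8, theta0_rad=0.0)
        assert np.isclose(np.rad2deg(traj.angles_rad[1]), 111.25)
        assert np.isclose(np.rad2deg(traj.angles_rad[2]), 222.5)

    def test_single_spoke_at_theta0(self):
        traj = ks.golden_angle_trajectory(1, 8, theta0_rad=0.3)
        assert traj.angles_rad.shape == (1,)
        assert np.isclose(traj.angles_rad[0], 0.3)

    def test_vertical_spoke_has_zero_x_coordinates(self):
        traj = ks.golden_angle_trajectory(1, 16, theta0_rad=np.pi / 2)
        assert np.abs(traj.sample_coords[:, 0]).max() < 1e-12

    def test_coords_bounded_and_radii_uniform(self):
        n = 32
        traj = ks.golden_angle_trajectory(5, n, theta0_rad=0.1)
        assert np.all(np.linalg.norm(traj.sample_coords, axis=1) <= np.pi + 1e-12)
        # consecutive samples along one spoke are equally spaced over the
        # full diameter, with the duplicate +pi endpoint excluded by default
        spoke0 = traj.sample_coords[:n]
        steps = np.linalg.norm(np.diff(spoke0, axis=0), axis=1)
        assert np.allclose(steps, 2 * np.pi / n, atol=1e-12)
        start = spoke0[0]
        assert np.isclose(np.linalg.norm(start), np.pi)

    def test_random_theta0_is_seeded(self):
        a = ks.golden_angle_trajectory(2, 8, seed_for_theta0=5)
        b = ks.golden_angle_trajectory(2, 8, seed_for_theta0=5)
        assert a.theta0_rad == b.theta0_rad
        assert 0 <= a.theta0_rad < 2 * np.pi


class TestNUDFT:
    def test_centered_delta_gives_unit_magnitude_samples(self):
        vol = np.zeros((8, 8, 2), dtype=complex)
        vol[4, 4, 0] = 1.0  # floor(N/2) centering
        traj = ks.golden_angle_trajectory(3, 16, theta0_rad=0.4)
        out = ks.nudft_forward(ComplexVolume.from_complex(vol), traj)
        np.testing.assert_allclose(np.abs(out.values[:, 0]), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.values[:, 1], 0.0, atol=1e-12)

    def test_zero_volume_zero_samples_and_back(self):
        traj = ks.golden_angle_trajectory(2, 8)
        vol = ComplexVolume.from_complex(np.zeros((8, 8, 2), dtype=complex))
        out = ks.nudft_forward(vol, traj)
        assert np.all(out.values == 0)
        back = ks.nudft_adjoint(out, (8, 8, 2))
        assert np.all(back.data == 0)

    def test_forward_matches_brute_force(self):
        rng = np.random.default_rng(3)
        traj = ks.golden_angle_trajectory(3, 8, theta0_rad=0.7)
        sl = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        vol = ComplexVolume.from_complex(sl[:, :, None])
        fast = ks.nudft_forward(vol, traj).values[:, 0]
        slow = brute_force_nudft(sl, traj)
        assert np.abs(fast - slow).max() / np.abs(slow).max() < 1e-10

    def test_adjointness_identity(self):
        rng = np.random.default_rng(4)
        traj = ks.golden_angle_trajectory(3, 8, theta0_rad=1.1)
        A = ks.nudft_matrix(traj, (8, 8))
        x = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        y = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        lhs = np.vdot(y, A @ x.ravel())
        rhs = np.vdot(A.conj().T @ y, x.ravel())
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_linearity(self):
        rng = np.random.default_rng(5)
        traj = ks.golden_angle_trajectory(3, 8)
        a = rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2))
        b = rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2))
        fa = ks.nudft_forward(ComplexVolume.from_complex(a), traj).values
        fb = ks.nudft_forward(ComplexVolume.from_complex(b), traj).values
        fab = ks.nudft_forward(
            ComplexVolume.from_complex(2 * a - 3 * b), traj
        ).values
        np.testing.assert_allclose(fab, 2 * fa - 3 * fb, atol=1e-9)

    def test_delta_sample_energy_equals_n_k_per_slice(self):
        vol = np.zeros((8, 8, 1), dtype=complex)
        vol[4, 4, 0] = 1.0
        traj = ks.golden_angle_trajectory(3, 16)
        out = ks.nudft_forward(ComplexVolume.from_complex(vol), traj)
        assert np.isclose(np.sum(np.abs(out.values) ** 2), traj.n_samples)

    def test_reconstruction_error_decreases_with_spokes(self):
        spec = PhantomSpec(
            (16, 16, 4), (1, 1, 1),
            [Ellipsoid((8, 8, 1.5), (4, 5, 1.2), 0.9)],
            texture_amp=0.05,
        )
        mag, _ = generate_phantom(spec, seed=6)
        vol = ComplexVolume(mag, np.zeros_like(mag))
        # the plain (uncompensated) adjoint carries a fixed blur, so the
        # undersampling artifact is isolated against a densely-sampled
        # adjoint reference: streak error falls monotonically with spokes
        dense = ks.RadialTrajectory(400, 32, theta0_rad=0.2)
        ref = ks.nudft_adjoint(ks.nudft_forward(vol, dense), vol.shape)
        errs = []
        for n_spokes in (5, 13, 50):
            traj = ks.RadialTrajectory(n_spokes, 32, theta0_rad=0.2)
            rec = ks.nudft_adjoint(ks.nudft_forward(vol, traj), vol.shape)
            errs.append(relative_error(rec.magnitude, ref.magnitude))
        assert errs[0] > errs[1] > errs[2]


class TestAcceleration:
    @pytest.mark.parametrize("spokes,expected", [(13, 31), (9, 45), (5, 80)])
    def test_printed_acceleration_factors(self, spokes, expected):
        assert ks.acceleration_factor_rounded(256, spokes) == expected

    def test_fully_sampled_radial_is_unity(self):
        n = 64
        assert np.isclose(ks.acceleration_factor(n, int(np.pi / 2 * n)), 1.0,
                          atol=0.02)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            ks.acceleration_factor(0, 5)


class TestPreprocess:
    def test_six_planes_and_identity_source_planes(self, small_case):
        assert small_case.x.planes.shape[0] == 6
        np.testing.assert_array_equal(small_case.x.planes[0], small_case.s_fi.real)
        np.testing.assert_array_equal(small_case.x.planes[1], small_case.s_fi.imag)

    def test_recomputation_is_bitwise_identical(self, small_case):
        x2, s_ui2, _, _ = ks.preprocess_case(small_case.s_fi, small_case.t_uk)
        np.testing.assert_array_equal(x2.planes, small_case.x.planes)
        np.testing.assert_array_equal(s_ui2.real, small_case.s_ui.real)

    def test_shape_mismatch_rejected(self, small_case):
        bad = ComplexVolume(np.zeros((8, 8, 2)), np.zeros((8, 8, 2)))
        with pytest.raises(ValueError):
            ks.preprocess_case(bad, small_case.t_uk)
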