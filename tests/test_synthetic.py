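"""Unit and property tests for the synthetic phantom/cohort generator."""

import numpy as np
import pytest

from cminr import synthetic as syn
from cminr.metrics import relative_error
from cminr.volumes import ComplexVolume
from cminr.warp import warp_complex, warp_mask  # noqa: F401 (both used)


def test_empty_scene_is_uniform_background():
    spec = syn.PhantomSpec((8, 8, 4), (1, 1, 1), [], background_intensity=0.3)
    vol, masks = syn.generate_phantom(spec, seed=0)
    assert masks == []
    np.testing.assert_array_equal(vol, np.full((8, 8, 4), 0.3))


def test_ellipsoid_mask_matches_bruteforce_inclusion():
    spec = syn.PhantomSpec(
        (32, 32, 8), (1, 1, 1),
        [syn.Ellipsoid((15.0, 16.0, 3.5), (4.0, 4.0, 2.0), 0.9)],
    )
    _, masks = syn.generate_phantom(spec, seed=1)
    count = 0
    for i in range(32):  # independent voxel-by-voxel inequality check
        for j in range(32):
            for k in range(8):
                q = ((i - 15.0) / 4) ** 2 + ((j - 16.0) / 4) ** 2 + ((k - 3.5) / 2) ** 2
                count += q <= 1.0
    assert masks[0].sum() == count


def test_phantom_determinism_and_bounds_error():
    spec = syn.default_phantom_spec((16, 16, 8))
    a, _ = syn.generate_phantom(spec, seed=5)
    b, _ = syn.generate_phantom(spec, seed=5)
    np.testing.assert_array_equal(a, b)
    assert a.min() >= 0 and a.max() <= 1
    bad = syn.PhantomSpec(
        (16, 16, 8), (1, 1, 1), [syn.Ellipsoid((1.0, 8.0, 4.0), (5, 2, 1), 0.5)]
    )
    with pytest.raises(ValueError, match="outside"):
        syn.generate_phantom(bad, seed=0)


class TestPhaseMap:
    def test_degenerate_single_frequency_matches_closed_form(self):
        f = 2.0e-3
        spec = syn.PhaseMapSpec(1, (f, f), amplitude=1.0, random_shifts=False,
                                seed=3)
        shape, spacing = (12, 10, 6), (2.0, 3.0, 5.0)
        phase = syn.make_phase_map(shape, spacing, spec)
        expect = np.zeros(shape)
        for axis, (n, s) in enumerate(zip(shape, spacing)):
            coord = np.arange(n) * s
            term = np.sin(2 * np.pi * f * coord)
            sh = [1, 1, 1]
            sh[axis] = n
            expect = expect + term.reshape(sh)
        np.testing.assert_allclose(phase, expect, atol=1e-12)

    def test_bounded_by_axes_times_components(self):
        spec = syn.PhaseMapSpec(seed=11)
        phase = syn.make_phase_map((16, 16, 8), (4, 4, 8), spec)
        assert np.abs(phase).max() <= 3 * spec.n_freqs_per_axis * spec.amplitude

    def test_determinism_and_spacing_validation(self):
        spec = syn.PhaseMapSpec(seed=7)
        a = syn.make_phase_map((8, 8, 4), (1, 1, 1), spec)
        b = syn.make_phase_map((8, 8, 4), (1, 1, 1), spec)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            syn.make_phase_map((8, 8, 4), (0.0, 1, 1), spec)


class TestMotion:
    def test_identity_bin_and_zero_amplitude(self):
        model = syn.MotionModel((0.5, 1.0, 2.0), 5.0, 4)
        assert np.all(syn.analytic_motion_dvf((8, 8, 4), model, 0.0).field == 0)
        zero = syn.MotionModel((0, 0, 0), 5.0, 4)
        assert np.all(syn.analytic_motion_dvf((8, 8, 4), zero, 0.7).field == 0)

    def test_displacement_bounded_by_amplitude(self):
        model = syn.MotionModel((0.5, 1.0, 2.0), 5.0, 4)
        d = syn.analytic_motion_dvf((16, 16, 8), model, 0.5)
        assert d.magnitude().max() <= np.linalg.norm((0.5, 1.0, 2.0)) + 1e-12
        for j, a in enumerate((0.5, 1.0, 2.0)):
            assert np.abs(d.field[j]).max() <= a + 1e-12

    def test_warped_mask_centroid_shift_matches_mean_displacement(self):
        from scipy.ndimage import center_of_mass

        model = syn.MotionModel((0.4, 0.8, 1.5), 20.0, 4)  # near-constant field
        shape = (24, 24, 12)
        d = syn.analytic_motion_dvf(shape, model, 0.5)
        spec = syn.PhantomSpec(
            shape, (1, 1, 1), [syn.Ellipsoid((12, 12, 6), (4, 4, 2.5), 1.0)]
        )
        _, masks = syn.generate_phantom(spec, 0)
        # continuous (trilinear) warp of the float mask avoids the half-voxel
        # quantisation of nearest-neighbour warping in the centroid estimate
        vol = ComplexVolume(masks[0].astype(float), np.zeros(shape))
        warped = warp_complex(vol, d).real
        shift = np.array(center_of_mass(warped)) - np.array(center_of_mass(masks[0]))
        mean_d = d.field[:, masks[0]].mean(axis=1)
        # backward warping pulls content against the displacement direction
        np.testing.assert_allclose(shift, -mean_d, atol=0.25)


class TestNoise:
    def test_zero_sd_is_identity(self):
        vol = ComplexVolume(np.ones((8, 8, 4)), np.zeros((8, 8, 4)))
        out = syn.add_complex_noise(vol, syn.NoiseSpec((0.0, 0.0), seed=1))
        np.testing.assert_array_equal(out.real, vol.real)
        np.testing.assert_array_equal(out.imag, vol.imag)

    def test_empirical_sd_matches_drawn_sd(self):
        shape = (64, 64, 32)  # >= 1e5 voxels
        vol = ComplexVolume(np.zeros(shape), np.zeros(shape))
        spec = syn.NoiseSpec(seed=9)
        out = syn.add_complex_noise(vol, spec)
        drawn = np.random.default_rng(9).uniform(*spec.sd_range)
        for plane in (out.real, out.imag):
            assert abs(plane.std() - drawn) / drawn < 0.05

    def test_determinism(self):
        vol = ComplexVolume(np.ones((8, 8, 4)), np.ones((8, 8, 4)))
        a = syn.add_complex_noise(vol, syn.NoiseSpec(seed=4))
        b = syn.add_complex_noise(vol, syn.NoiseSpec(seed=4))
        np.testing.assert_array_equal(a.real, b.real)


class TestCohort:
    def test_single_bin_subject_has_one_volume_and_no_motion(self):
        subs = syn.generate_cohort(
            1, syn.default_phantom_spec((16, 16, 8)),
            syn.MotionModel((0.3, 0.6, 1.2), 5.0, n_bins=1),
            syn.PhaseMapSpec(), syn.NoiseSpec(), seed=1,
        )
        assert subs[0].n_bins == 1
        assert np.all(subs[0].dvfs[0].field == 0)

    def test_reference_bin_dvf_is_zero(self, small_cohort):
        for s in small_cohort:
            assert np.all(s.dvfs[0].field == 0)

    def test_bins_equal_warped_reference_before_noise(self, small_cohort):
        s = small_cohort[0]
        for b in range(1, s.n_bins):
            rewarped = warp_complex(s.clean_volumes[0], s.dvfs[b])
            np.testing.assert_allclose(rewarped.real, s.clean_volumes[b].real,
                                       atol=1e-12)
            np.testing.assert_allclose(rewarped.imag, s.clean_volumes[b].imag,
                                       atol=1e-12)

    def test_determinism(self, small_cohort):
        again = syn.generate_cohort(
            3, syn.default_phantom_spec((16, 16, 8)),
            syn.MotionModel((0.3, 0.6, 1.2), 5.0, 4),
            syn.PhaseMapSpec(), syn.NoiseSpec(), seed=42,
        )
        for a, b in zip(small_cohort, again):
            for va, vb in zip(a.volumes, b.volumes):
                np.testing.assert_array_equal(va.real, vb.real)

    def test_inverse_unwarp_recovers_reference_magnitude(self):
        # smooth phantom, small motion: < 5% RE after inverse-mapping back
        spec = syn.default_phantom_spec((32, 32, 8))
        spec.texture_amp = 0.0
        spec.edge_smooth_vox = 2.0  # smooth anatomy (no step edges)
        subs = syn.generate_cohort(
            1, spec, syn.MotionModel((0.3, 0.5, 1.0), 10.0, 4),
            syn.PhaseMapSpec(), syn.NoiseSpec((0, 0)), seed=2,
            jitter_anatomy=False,
        )
        s = subs[0]
        b = 2
        back = warp_complex(s.clean_volumes[b], s.dvfs[b].approx_inverse())
        re = relative_error(back.magnitude, s.clean_volumes[0].magnitude)
        assert re < 5.0
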