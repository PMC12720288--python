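"""SIREN template, modulators and coordinate machinery."""

import numpy as np
import pytest

from cminr.autodiff import Tensor, no_grad
from cminr.inr import (CNNModulator, INRTemplate, Modulation, TokenModulator,
                       coordinate_grid, init_template, siren_forward)
from cminr.nn import Adam


class TestTemplate:
    def test_parameter_count_closed_form(self):
        widths = (3, 256, 256, 256, 3)
        t = init_template(widths, seed=0)
        d_in, h, _, _, d_out = widths
        expected = (d_in * h + h) + 3 * (h * h + h) + (h * d_out + d_out)
        assert t.n_parameters() == expected

    def test_siren_initialisation_bounds(self):
        t = init_template((3, 64, 64, 64, 3), omega0=30.0, seed=1)
        assert np.abs(t.w_i.data).max() <= 1.0 / 3
        bound = np.sqrt(6.0 / 64) / 30.0
        for w in t.w_h + [t.w_o]:
            assert np.abs(w.data).max() <= bound

    def test_same_seed_identical_parameters(self):
        a = init_template((3, 32, 32, 32, 3), seed=5)
        b = init_template((3, 32, 32, 32, 3), seed=5)
        np.testing.assert_array_equal(a.state_vector(), b.state_vector())

    def test_unequal_hidden_widths_rejected(self):
        with pytest.raises(ValueError):
            init_template((3, 32, 64, 32, 3))


class TestForward:
    def test_all_ones_modulation_is_identity(self):
        t = init_template((3, 32, 32, 32, 3), seed=2)
        coords = np.random.default_rng(0).uniform(-1, 1, (50, 3))
        with no_grad():
            plain = siren_forward(t, None, coords).data
            ones = siren_forward(t, Modulation.ones(32), coords).data
        np.testing.assert_array_equal(plain, ones)

    def test_zero_output_weights_give_bias(self):
        t = init_template((3, 16, 16, 16, 3), seed=3)
        t.w_o.data[:] = 0.0
        t.b_o.data[:] = [1.0, -2.0, 0.5]
        with no_grad():
            out = siren_forward(t, None, np.zeros((7, 3))).data
        np.testing.assert_allclose(out, np.tile([1.0, -2.0, 0.5], (7, 1)))

    def test_toy_template_matches_hand_computation(self):
        # width-2 template with hand-set parameters, one coordinate
        t = INRTemplate((3, 2, 2, 2, 3), omega0=2.0)
        t.w_i.data = np.array([[0.1, 0.2], [0.3, -0.1], [0.0, 0.4]])
        t.b_i.data = np.array([0.05, -0.05])
        for layer in range(3):
            t.w_h[layer].data = np.array([[0.5, -0.2], [0.1, 0.3]]) * (layer + 1)
            t.b_h[layer].data = np.array([0.01 * (layer + 1), -0.02])
        t.w_o.data = np.array([[1.0, 0.0, 2.0], [0.5, -1.0, 0.0]])
        t.b_o.data = np.array([0.1, 0.2, 0.3])
        gammas = [np.array([1.1, 0.9]), np.array([1.0, 1.2]), np.array([0.8, 1.0])]
        betas = [np.array([0.9, 1.0]), np.array([1.1, 1.0]), np.array([1.0, 0.7])]
        v = np.array([[0.3, -0.5, 0.2]])

        f = np.sin(2.0 * (v @ t.w_i.data + t.b_i.data))
        for layer in range(3):
            f = np.sin(gammas[layer] * (f @ t.w_h[layer].data)
                       + betas[layer] * t.b_h[layer].data)
        expected = f @ t.w_o.data + t.b_o.data

        with no_grad():
            out = siren_forward(t, Modulation(gammas, betas), v).data
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_modulation_width_mismatch_rejected(self):
        t = init_template((3, 16, 16, 16, 3), seed=4)
        with pytest.raises(ValueError):
            siren_forward(t, Modulation.ones(8), np.zeros((2, 3)))

    def test_expressivity_fits_smooth_field(self):
        # gradient descent fit of an analytic smooth DVF on a 16^3 grid
        from cminr.synthetic import MotionModel, analytic_motion_dvf

        target = analytic_motion_dvf((16, 16, 16),
                                     MotionModel((0.5, 1.0, 2.0), 6.0, 4), 0.5)
        grid = coordinate_grid((16, 16, 16), 1)
        ref = target.field.reshape(3, -1).T  # (N, 3)
        t = init_template((3, 64, 64, 64, 3), seed=7)
        opt = Adam(t.parameters(), lr=2e-3)
        for _ in range(500):
            out = siren_forward(t, None, grid.coords)
            loss = (out - Tensor(ref)).abs().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert loss.item() < 0.05  # mean absolute error in voxels


class TestCoordinateGrid:
    def test_symmetric_middle_coordinate(self):
        g = coordinate_grid((3, 3, 3), 1)
        assert g.coords.shape == (27, 3)
        np.testing.assert_allclose(g.coords[13], [0.0, 0.0, 0.0], atol=1e-15)

    @pytest.mark.parametrize("shape,ds", [((16, 16, 8), 2), ((15, 9, 5), (2, 3, 1))])
    def test_count_is_ceil_ratio(self, shape, ds):
        g = coordinate_grid(shape, ds)
        dst = (ds,) * 3 if np.isscalar(ds) else ds
        expected = int(np.prod([int(np.ceil(n / d)) for n, d in zip(shape, dst)]))
        assert g.coords.shape[0] == expected

    def test_corner_coordinates_exactly_unit(self):
        g = coordinate_grid((16, 12, 8), 2)
        assert g.coords.min() == -1.0 and g.coords.max() == 1.0
        np.testing.assert_array_equal(g.coords[0], [-1.0, -1.0, -1.0])
        np.testing.assert_array_equal(g.coords[-1], [1.0, 1.0, 1.0])


class TestModulators:
    @pytest.mark.parametrize("kind", ["token", "cnn"])
    def test_identity_at_initialisation(self, kind):
        if kind == "token":
            mod = TokenModulator((16, 16, 8), 64, token_dim=48, seed=0)
        else:
            mod = CNNModulator((16, 16, 8), 64, seed=0)
        x = np.random.default_rng(1).standard_normal((6, 16, 16, 8))
        with no_grad():
            m = mod(x)
        for g, b in zip(m.gammas, m.betas):
            np.testing.assert_allclose(np.asarray(g.data), 1.0, atol=1e-15)
            np.testing.assert_allclose(np.asarray(b.data), 1.0, atol=1e-15)
            assert g.shape == (64,)

    def test_wrong_plane_count_rejected(self):
        mod = TokenModulator((16, 16, 8), 32, seed=0)
        with pytest.raises(ValueError):
            mod(np.zeros((5, 16, 16, 8)))

    def test_trained_modulator_distinguishes_inputs(self):
        # after a few gradient steps the modulation is input-dependent
        mod = TokenModulator((16, 16, 8), 16, token_dim=24, patch_size=(4, 4, 4),
                             seed=2)
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal((6, 16, 16, 8))
        x2 = rng.standard_normal((6, 16, 16, 8))
        opt = Adam(mod.parameters(), lr=1e-2)
        for _ in range(5):
            m = mod(x1)
            loss = sum(((g - 2.0) ** 2).mean() for g in m.gammas)
            opt.zero_grad()
            loss.backward()
            opt.step()
        with no_grad():
            m1, m2 = mod(x1), mod(x2)
        diff = max(
            np.abs(np.asarray(a.data) - np.asarray(b.data)).max()
            for a, b in zip(m1.gammas, m2.gammas)
        )
        assert diff > 1e-6
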