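"""Meta-training algorithm, test-time adaptation and variant run modes."""

import hashlib

import numpy as np
import pytest

from cminr.autodiff import no_grad
from cminr.inr import coordinate_grid, init_template
from cminr.losses import LossWeights, loss_kspace
from cminr.meta import (VARIANTS, MetaConfig, adapt_case, case_from_subject,
                        inner_loop_stepA, inner_loop_stepB, make_modulator,
                        meta_train, run_variant, stepB_epochs_to_threshold,
                        _coarse_field, _sample_train_case, _stepB_graph)
from cminr.metrics import relative_error
from cminr.nn import Adam
from cminr.seeding import rng_for
from cminr.volumes import DVF

WIDTHS = (3, 32, 32, 32, 3)


def small_cfg(**kw):
    base = dict(n_outer=2, n_inner=4, n_adapt=10, lr=5e-3, variant="ks_inr",
                samples_per_spoke=32, train_spokes_range=(8, 13), seed=0)
    base.update(kw)
    return MetaConfig(**base)


class TestInnerLoops:
    def test_zero_epochs_leave_parameters_unchanged(self, small_case):
        t = init_template(WIDTHS, seed=0)
        before = t.state_vector()
        grid = coordinate_grid(small_case.shape, 2)
        assert inner_loop_stepA(t, None, DVF.zeros(small_case.shape), grid,
                                0, 1e-3) == []
        assert inner_loop_stepB(t, None, small_case, grid, 0, 1e-3,
                                LossWeights()) == []
        np.testing.assert_array_equal(t.state_vector(), before)

    def test_stepA_loss_decreases(self, small_case):
        t = init_template(WIDTHS, seed=1)
        grid = coordinate_grid(small_case.shape, 2)
        ref = DVF(np.full((3,) + small_case.shape, 0.5))
        hist = inner_loop_stepA(t, None, ref, grid, 10, 5e-3)
        assert hist[-1] < hist[0]

    def test_stepA_fixed_point_when_reference_matches_output(self, small_case):
        # d_reg equal to the INR's own output: loss ~0 and near-zero update
        t = init_template(WIDTHS, seed=2)
        grid = coordinate_grid(small_case.shape, 2)
        from cminr.ops import resize_trilinear

        with no_grad():
            d_now = resize_trilinear(_coarse_field(t, None, grid),
                                     small_case.shape).data
        before = t.state_vector()
        hist = inner_loop_stepA(t, None, DVF(d_now), grid, 1, 1e-12)
        assert hist[0] < 1e-12
        assert np.abs(t.state_vector() - before).max() < 1e-9

    def test_stepB_loss_decreases(self, small_case):
        t = init_template(WIDTHS, seed=3)
        grid = coordinate_grid(small_case.shape, 2)
        hist = inner_loop_stepB(t, None, small_case, grid, 30, 5e-3,
                                LossWeights(1.0, 0.0, 0.5))
        assert hist[-1]["total"] < hist[0]["total"]


class TestMetaTrain:
    def test_zero_outer_iterations_noop(self, small_cohort):
        t = init_template(WIDTHS, seed=4)
        mod = make_modulator("meta_inr_a", (16, 16, 8), 32, seed=5)
        before_t, before_m = t.state_vector(), mod.state_vector()
        meta_train(small_cohort, t, mod, None, small_cfg(variant="meta_inr_a",
                                                         n_outer=0))
        np.testing.assert_array_equal(t.state_vector(), before_t)
        np.testing.assert_array_equal(mod.state_vector(), before_m)

    def test_empty_cohort_rejected(self):
        t = init_template(WIDTHS, seed=4)
        with pytest.raises(ValueError):
            meta_train([], t, None, None, small_cfg())

    def test_single_subject_reptile_update_equals_phi_double_prime(
            self, small_cohort):
        """With one subject, Phi_new = Phi'' exactly (delta = (Phi''-Phi)/1).

        Verified by replaying the identical inner-loop computation through
        the public pieces with the same seeded case draw."""
        cfg = small_cfg(variant="meta_inr_a", n_outer=1, n_inner=3, seed=9)
        cohort = small_cohort[:1]
        t = init_template(WIDTHS, seed=6)
        mod = make_modulator("meta_inr_a", (16, 16, 8), 32, seed=7)
        t_ref = init_template(WIDTHS, seed=6)
        mod_ref = make_modulator("meta_inr_a", (16, 16, 8), 32, seed=7)

        meta_train(cohort, t, mod, None, cfg)

        rng = rng_for(cfg.seed, "meta-train")
        case = _sample_train_case(cohort[0], rng, cfg)
        with no_grad():
            modulation = mod_ref(case.x).detached()
        grid = coordinate_grid((16, 16, 8), cfg.downsample)
        opt = Adam(t_ref.parameters(), lr=cfg.lr)
        inner_loop_stepB(t_ref, modulation, case, grid, cfg.n_inner, cfg.lr,
                         cfg.weights, optimizer=opt)
        np.testing.assert_allclose(t.state_vector(), t_ref.state_vector(),
                                   atol=1e-12)

    def test_prior_is_frozen_during_meta_training(self, small_cohort,
                                                  trained_prior):
        prior, _ = trained_prior
        digest = hashlib.sha256(prior.state_vector().tobytes()).hexdigest()
        t = init_template(WIDTHS, seed=8)
        mod = make_modulator("cmeta", (16, 16, 8), 32, seed=9)
        meta_train(small_cohort, t, mod, prior,
                   small_cfg(variant="cmeta", n_outer=1, n_inner=2))
        assert hashlib.sha256(
            prior.state_vector().tobytes()).hexdigest() == digest

    def test_reproducible_loss_trajectories(self, small_cohort):
        runs = []
        for _ in range(2):
            t = init_template(WIDTHS, seed=10)
            mod = make_modulator("meta_inr", (16, 16, 8), 32, seed=11)
            _, _, hist = meta_train(small_cohort, t, mod, None,
                                    small_cfg(variant="meta_inr", n_outer=2,
                                              n_inner=3, seed=13))
            runs.append([h["stepB"] for h in hist])
        assert runs[0] == runs[1]

    def test_modulator_gradient_flow(self, small_case):
        """Step-B gradients w.r.t. modulator parameters are nonzero."""
        t = init_template(WIDTHS, seed=12)
        mod = make_modulator("meta_inr_a", (16, 16, 8), 32, seed=13)
        grid = coordinate_grid(small_case.shape, 2)
        modulation = mod(small_case.x)
        total, _ = _stepB_graph(_coarse_field(t, modulation, grid), small_case,
                                None, LossWeights(), False, None)
        total.backward()
        grads = [p.grad for p in mod.parameters() if p.grad is not None]
        assert grads and max(np.abs(g).max() for g in grads) > 0


class TestAdapt:
    def test_zero_epochs_gives_zero_shot_prediction(self, small_case):
        t = init_template(WIDTHS, seed=14)
        cfg = small_cfg(n_adapt=0)
        res = adapt_case(t, None, None, small_case, cfg)
        grid = coordinate_grid(small_case.shape, cfg.downsample)
        from cminr.ops import resize_trilinear

        with no_grad():
            expect = resize_trilinear(_coarse_field(t, None, grid),
                                      small_case.shape).data
        np.testing.assert_array_equal(res.dvf.field, expect)

    def test_adaptation_reduces_relative_error(self, small_case):
        t = init_template(WIDTHS, seed=15)
        res = adapt_case(t, None, None, small_case, small_cfg(n_adapt=40))
        re_before = relative_error(small_case.s_fi.magnitude,
                                   small_case.truth["target_magnitude"])
        assert res.report.re_percent < re_before

    def test_missing_prior_rejected(self, small_case):
        t = init_template(WIDTHS, seed=16)
        with pytest.raises(ValueError, match="prior"):
            adapt_case(t, None, None, small_case, small_cfg(variant="cmeta"))

    def test_ks_iterative_zero_motion_converges_to_near_zero(
            self, small_cohort):
        case0 = case_from_subject(small_cohort[0], 0, 13, 32, theta0_seed=3)
        res = adapt_case(None, None, None, case0,
                         small_cfg(variant="ks_iterative", n_adapt=40))
        assert np.abs(res.dvf.field).mean() < 0.25

    def test_trained_template_is_not_mutated(self, small_case):
        t = init_template(WIDTHS, seed=17)
        before = t.state_vector()
        adapt_case(t, None, None, small_case, small_cfg(n_adapt=5))
        np.testing.assert_array_equal(t.state_vector(), before)


class TestVariants:
    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            run_variant("nope", small_cohort, small_cfg())
        with pytest.raises(ValueError):
            MetaConfig(variant="nope")

    def test_flag_algebra_cmeta_reduces_to_meta_inr_a(self):
        c, a = VARIANTS["cmeta"], VARIANTS["meta_inr_a"]
        assert (c.modulator, c.parametrization) == (a.modulator,
                                                    a.parametrization)
        # disabling step A and the embedding term recovers meta_inr_a
        assert (False, False) == (a.use_stepA, a.use_embed)

    def test_all_variants_emit_same_schema(self, small_cohort, trained_prior):
        prior, _ = trained_prior
        case = case_from_subject(small_cohort[2], 1, 13, 32, theta0_seed=21)
        keys = None
        for variant in ("ks_inr", "ks_iterative", "meta_inr"):
            out = run_variant(variant, small_cohort[:2],
                              small_cfg(n_outer=1, n_inner=2, n_adapt=3),
                              test_cases=[case], prior=prior)
            assert set(out) == {"variant", "template", "modulator",
                                "meta_history", "adaptations", "reports"}
            rep = out["reports"][0]
            if keys is None:
                keys = set(rep)
            assert set(rep) == keys


def test_meta_template_reaches_threshold_quickly(small_cohort, small_case):
    """Sanity check of the epochs-to-threshold measurement machinery."""
    t = init_template(WIDTHS, seed=18)
    cfg = small_cfg()
    L0 = loss_kspace(small_case.s_uk, small_case.t_uk)
    n = stepB_epochs_to_threshold(t, None, small_case, cfg,
                                  threshold=0.5 * L0, max_epochs=60)
    assert 0 < n <= 60
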