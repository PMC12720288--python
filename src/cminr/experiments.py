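"""Reproducible desk-scale studies of the registration framework.

Three self-contained experiments, each a pure function of its seed:

* :func:`recovery_experiment` — single-case motion recovery from 13-spoke
  k-space by from-scratch INR optimisation (``ks_inr``), plus the
  zero-motion control;
* :func:`meta_advantage_experiment` — step-B epochs needed to reach a
  fixed k-space fidelity threshold, meta-learned template versus random
  initialisation, over several seeds and held-out cases;
* :func:`ablation_experiment` — held-out Dice of the ablation ladder
  (CNN-modulated meta baseline -> + prior guidance -> + embedding loss),
  pooled over sub-seeds.

Problem sizes are chosen so each study runs in minutes on one CPU: grids
of 32x32x8 (recovery) and 16x16x8 (meta/ablation), 32-64 samples per
spoke, hidden width 64, and inner/outer iteration counts well below the
published schedule.  The learning rate is raised accordingly (5e-3; the
published 1e-5 pairs with tens of thousands of steps at full scale).
"""

from __future__ import annotations

import numpy as np

from .autodiff import no_grad
from .inr import init_template
from .losses import loss_kspace
from .meta import (MetaConfig, adapt_case, case_from_subject, make_modulator,
                   meta_train, stepB_epochs_to_threshold)
from .metrics import dice, relative_error
from .prior import PriorNet, train_prior
from .seeding import child_seed
from .synthetic import (MotionModel, NoiseSpec, PhaseMapSpec,
                        default_phantom_spec, generate_cohort)

__all__ = [
    "recovery_experiment",
    "meta_advantage_experiment",
    "ablation_experiment",
]

HIDDEN = 64
WIDTHS = (3, HIDDEN, HIDDEN, HIDDEN, 3)
DESK_LR = 5e-3


def recovery_experiment(seed: int = 0) -> dict:
    """Motion recovery on a 32x32x8 phantom with 13 spokes (ks_inr mode).

    Returns unregistered/registered relative error and Dice, and the mean
    displacement magnitude the optimiser settles to on a zero-motion case.
    """
    cohort = generate_cohort(
        1,
        default_phantom_spec((32, 32, 8)),
        MotionModel((0.5, 1.0, 2.0), 8.0, 4),
        PhaseMapSpec(),
        NoiseSpec(),
        seed=child_seed(seed, "recovery-cohort"),
    )
    subject = cohort[0]
    cfg = MetaConfig(n_adapt=100, lr=DESK_LR, variant="ks_inr",
                     samples_per_spoke=64, seed=seed)
    case = case_from_subject(subject, 2, n_spokes=13, samples_per_spoke=64,
                             theta0_seed=child_seed(seed, "recovery-theta0"))
    template = init_template(WIDTHS, seed=child_seed(seed, "recovery-template"))
    result = adapt_case(template, None, None, case, cfg)

    truth_mag = case.truth["target_magnitude"]
    name = "structure_0"
    re_before = relative_error(case.s_fi.magnitude, truth_mag)
    dice_before = dice(case.truth["source_masks"][name],
                       case.truth["target_masks"][name])

    zero_case = case_from_subject(subject, 0, n_spokes=13, samples_per_spoke=64,
                                  theta0_seed=child_seed(seed, "recovery-zero"))
    zero_cfg = MetaConfig(n_adapt=60, lr=DESK_LR, variant="ks_inr",
                          samples_per_spoke=64, seed=seed)
    zero_tmpl = init_template(WIDTHS, seed=child_seed(seed, "recovery-zt"))
    zero_res = adapt_case(zero_tmpl, None, None, zero_case, zero_cfg)

    return {
        "re_before_percent": re_before,
        "re_after_percent": result.report.re_percent,
        "re_reduction_percent": 100.0 * (1 - result.report.re_percent / re_before),
        "dice_before": dice_before,
        "dice_after": result.report.dice,
        "ssim_after": result.report.ssim,
        "zero_motion_mean_disp_vox": float(np.abs(zero_res.dvf.field).mean()),
        "n_voxels": int(np.prod(case.shape)),
    }


def meta_advantage_experiment(seed: int = 0, n_subseeds: int = 3,
                              n_held_out: int = 5) -> dict:
    """Step-B epochs to a fixed k-space threshold: meta template vs random.

    For each sub-seed a 6-subject cohort is meta-trained (token modulator,
    no prior: the comparison isolates the initialisation).  On held-out
    subjects both arms run pure step-B optimisation until the k-space
    fidelity loss falls below 10% of its zero-displacement value (capped at
    150 epochs); medians are pooled over all (sub-seed, case) pairs.
    """
    phantom = default_phantom_spec((16, 16, 8))
    motion = MotionModel((0.3, 0.6, 1.2), 5.0, 4)
    cfg_kw = dict(n_outer=25, n_inner=10, lr=DESK_LR, samples_per_spoke=32,
                  train_spokes_range=(8, 13))
    epochs_meta, epochs_random = [], []
    for sub in range(n_subseeds):
        s = child_seed(seed, f"meta-adv-{sub}")
        train = generate_cohort(6, phantom, motion, PhaseMapSpec(), NoiseSpec(),
                                seed=child_seed(s, "train"))
        held = generate_cohort(n_held_out, phantom, motion, PhaseMapSpec(),
                               NoiseSpec(), seed=child_seed(s, "held"))
        cfg = MetaConfig(variant="meta_inr_a", seed=child_seed(s, "meta"),
                         **cfg_kw)
        template = init_template(WIDTHS, seed=child_seed(s, "template"))
        modulator = make_modulator("meta_inr_a", (16, 16, 8), HIDDEN,
                                   seed=child_seed(s, "modulator"))
        meta_train(train, template, modulator, None, cfg)
        for ci, subject in enumerate(held):
            case = case_from_subject(subject, 2, 13, 32,
                                     theta0_seed=child_seed(s, f"theta-{ci}"))
            L0 = loss_kspace(case.s_uk, case.t_uk)  # zero-displacement loss
            threshold = 0.1 * L0
            with no_grad():
                modulation = modulator(case.x).detached()
            epochs_meta.append(stepB_epochs_to_threshold(
                template, modulation, case, cfg, threshold, 150))
            rand = init_template(WIDTHS, seed=child_seed(s, f"random-{ci}"))
            epochs_random.append(stepB_epochs_to_threshold(
                rand, None, case, cfg, threshold, 150))
    return {
        "median_epochs_meta": float(np.median(epochs_meta)),
        "median_epochs_random": float(np.median(epochs_random)),
        "epochs_meta": epochs_meta,
        "epochs_random": epochs_random,
        "n_comparisons": len(epochs_meta),
    }


def ablation_experiment(seed: int = 0, n_subseeds: int = 4) -> dict:
    """Held-out Dice for the ablation ladder, pooled over sub-seeds.

    Each sub-seed: 12 subjects (6 train / 6 held out), a 200-epoch prior,
    15 outer meta iterations per variant, then short (10-epoch) adaptation
    on 18 held-out cases (6 subjects x 3 bins) — deliberately brief so the
    quality of the meta-learned initialisation, not the per-case
    optimisation, dominates.  The component effects are small relative to
    per-case spread, so Dice is pooled over all sub-seeds (72 cases by
    default, averaging over cohort, prior and meta-training noise) before
    taking medians.
    """
    phantom = default_phantom_spec((16, 16, 8))
    motion = MotionModel((0.5, 1.0, 2.0), 5.0, 4)
    variants = ("meta_inr", "meta_inr_b", "cmeta")
    pooled = {v: [] for v in variants}
    for sub in range(n_subseeds):
        s = child_seed(seed, f"ablation-{sub}")
        subjects = generate_cohort(12, phantom, motion, PhaseMapSpec(),
                                   NoiseSpec(), seed=child_seed(s, "cohort"))
        train, held = subjects[:6], subjects[6:]
        prior = PriorNet(8, seed=child_seed(s, "prior"))
        prior, _ = train_prior(prior, train, 200, 2e-3,
                               n_spokes_range=(5, 13), samples_per_spoke=32,
                               seed=child_seed(s, "train-prior"))
        cases = [
            case_from_subject(subj, b, 13, 32,
                              theta0_seed=child_seed(s, f"theta-{ci}-{b}"))
            for ci, subj in enumerate(held) for b in (1, 2, 3)
        ]
        for variant in variants:
            p = prior if variant in ("meta_inr_b", "cmeta") else None
            cfg = MetaConfig(n_outer=15, n_inner=10, n_adapt=10, lr=DESK_LR,
                             variant=variant, samples_per_spoke=32,
                             train_spokes_range=(5, 13),
                             seed=child_seed(s, "meta"))
            template = init_template(WIDTHS, seed=child_seed(s, "template"))
            modulator = make_modulator(variant, (16, 16, 8), HIDDEN,
                                       seed=child_seed(s, "modulator"))
            meta_train(train, template, modulator, p, cfg)
            for case in cases:
                res = adapt_case(template, modulator, p, case, cfg)
                pooled[variant].append(res.report.dice)
    medians = {v: float(np.median(d)) for v, d in pooled.items()}
    return {
        "median_dice_meta_inr": medians["meta_inr"],
        "median_dice_meta_inr_b": medians["meta_inr_b"],
        "median_dice_cmeta": medians["cmeta"],
        "dices": pooled,
        "n_cases": len(pooled["cmeta"]),
    }
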