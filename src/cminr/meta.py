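"""Cohort-informed meta-training and test-time adaptation.

Meta-training follows a Reptile-style outer loop: per outer iteration the
template parameters Phi are loaded for each training subject, optimised
for ``n_inner`` epochs on the deformation-discrepancy loss (step A,
against the frozen prior net's reference DVF) and ``n_inner`` epochs on
the weighted k-space/embedding/smoothness objective (step B), and the
averaged parameter difference ``(Phi'' - Phi) / N_x`` is applied to the
template.  After each subject's inner loops the token-aware modulator is
updated once by backpropagating the step-B loss through the modulation
coefficients with the INR frozen at Phi''.

Test-time adaptation re-runs ``n_adapt`` epochs of step A then step B on
a new case, starting from the meta-learned template under the case's own
modulation; it is fully unsupervised (no ground-truth DVF is consumed).

Ablation variants and baselines are exposed as run modes:

========  =========  ======  ======  ====  ==============
variant   modulator  step A  embed   meta  parametrisation
========  =========  ======  ======  ====  ==============
cmeta       token      yes     yes    yes    SIREN INR
meta_inr_b  token      yes     no     yes    SIREN INR
meta_inr_a  token      no      no     yes    SIREN INR
meta_inr    CNN        no      no     yes    SIREN INR
ks_inr      none       no      no     no     SIREN INR (random init)
ks_iterative none      no      no     no     voxelwise DVF array
========  =========  ======  ======  ====  ==============
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, no_grad
from .inr import (CNNModulator, CoordinateGrid, INRTemplate, Modulation,
                  TokenModulator, coordinate_grid, init_template, siren_forward)
from .kspace import (KSpaceData, ModelInput, golden_angle_trajectory,
                     nudft_forward, nudft_forward_t, nudft_matrix,
                     preprocess_case)
from .losses import LossWeights, loss_embed, loss_kspace, loss_smooth, loss_stepA
from .metrics import MetricReport, evaluate_case
from .nn import Adam
from .ops import resize_trilinear, trilinear_sample
from .prior import PriorNet, encode_tensor, prior_encode, prior_predict
from .seeding import child_seed, rng_for
from .synthetic import Subject
from .volumes import ComplexVolume, DVF
from .warp import warp_complex, warp_mask

__all__ = [
    "MetaConfig",
    "VariantSpec",
    "VARIANTS",
    "RegistrationCase",
    "case_from_subject",
    "inner_loop_stepA",
    "inner_loop_stepB",
    "meta_train",
    "adapt_case",
    "run_variant",
    "stepB_epochs_to_threshold",
    "AdaptResult",
]


@dataclass
class VariantSpec:
    modulator: str | None  # 'token', 'cnn' or None
    use_stepA: bool
    use_embed: bool
    meta: bool
    parametrization: str = "inr"  # 'inr' or 'voxel'


VARIANTS: dict[str, VariantSpec] = {
    "cmeta": VariantSpec("token", True, True, True),
    "meta_inr_b": VariantSpec("token", True, False, True),
    "meta_inr_a": VariantSpec("token", False, False, True),
    "meta_inr": VariantSpec("cnn", False, False, True),
    "ks_inr": VariantSpec(None, False, False, False),
    "ks_iterative": VariantSpec(None, False, False, False, "voxel"),
}


@dataclass
class MetaConfig:
    """Hyper-parameters of meta-training and adaptation.

    Published-scale defaults: 500 outer iterations, 10 inner epochs, 50
    adaptation epochs, Adam at 1e-5, batch size 1.  Desk-scale experiments
    shrink the counts and grids through this config.
    """

    n_outer: int = 500
    n_inner: int = 10
    n_adapt: int = 50
    lr: float = 1e-5
    optimizer: str = "adam"
    batch_size: int = 1
    seed: int = 0
    variant: str = "cmeta"
    spokes: int = 13
    samples_per_spoke: int = 256
    train_spokes_range: tuple = (5, 50)
    downsample: int = 2
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.n_outer < 0 or self.n_inner < 0 or self.n_adapt < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")

    @property
    def variant_spec(self) -> VariantSpec:
        return VARIANTS[self.variant]


@dataclass
class RegistrationCase:
    """One preprocessed registration problem: prior volume + target k-space."""

    s_fi: ComplexVolume
    t_uk: KSpaceData
    x: ModelInput
    s_ui: ComplexVolume
    t_ui: ComplexVolume
    s_uk: KSpaceData
    matrix: np.ndarray  # cached NUDFT matrix for the case trajectory
    truth: dict | None = None  # evaluation-only ground truth

    @property
    def shape(self):
        return self.s_fi.shape

    @property
    def spacing_mm(self):
        return self.s_fi.spacing_mm


def build_case(s_fi: ComplexVolume, t_uk: KSpaceData,
               truth: dict | None = None) -> RegistrationCase:
    x, s_ui, t_ui, s_uk = preprocess_case(s_fi, t_uk)
    A = nudft_matrix(t_uk.trajectory, s_fi.shape[:2])
    return RegistrationCase(s_fi, t_uk, x, s_ui, t_ui, s_uk, A, truth)


def case_from_subject(
    subject: Subject,
    target_bin: int,
    n_spokes: int = 13,
    samples_per_spoke: int = 64,
    theta0_seed: int | None = None,
    with_truth: bool = True,
) -> RegistrationCase:
    """Build a case: source = bin 0, target = undersampled k-space of a bin."""
    traj = golden_angle_trajectory(
        n_spokes, samples_per_spoke, seed_for_theta0=theta0_seed
    )
    t_uk = nudft_forward(subject.volumes[target_bin], traj)
    truth = None
    if with_truth:
        truth = {
            "target_magnitude": subject.clean_volumes[target_bin].magnitude,
            "dvf": subject.dvfs[target_bin],
            "source_masks": subject.bin_masks[0],
            "target_masks": subject.bin_masks[target_bin],
        }
    return build_case(subject.volumes[0], t_uk, truth)


# --------------------------------------------------------------------------
# loss graphs
# --------------------------------------------------------------------------

def _coarse_field(template: INRTemplate, modulation: Modulation | None,
                  grid: CoordinateGrid) -> Tensor:
    out = siren_forward(template, modulation, grid.coords)  # (N, 3)
    return out.transpose((1, 0)).reshape((3,) + grid.coarse_shape)


def _stepB_graph(d_coarse: Tensor, case: RegistrationCase, prior: PriorNet | None,
                 weights: LossWeights, use_embed: bool,
                 target_embed: np.ndarray | None):
    """Full step-B pipeline: upsample -> warp -> NUDFT -> weighted losses."""
    d_full = resize_trilinear(d_coarse, case.shape)
    warped = trilinear_sample(Tensor(case.s_fi.planes()), d_full)
    yr, yi = nudft_forward_t(warped[0], warped[1], case.t_uk.trajectory,
                             matrix=case.matrix)
    lk = loss_kspace((yr, yi), (case.t_uk.values.real, case.t_uk.values.imag))
    ls = loss_smooth(d_full)
    if use_embed:
        if prior is None:
            raise ValueError("embedding loss requires a prior network")
        e_pred = encode_tensor(prior, warped)
        le = loss_embed(e_pred, Tensor(target_embed))
        total = lk * weights.lambda1 + le * weights.lambda2 + ls * weights.lambda3
        le_val = le.item()
    else:
        total = lk * weights.lambda1 + ls * weights.lambda3
        le_val = 0.0
    parts = {"kspace": lk.item(), "embed": le_val, "smooth": ls.item(),
             "total": total.item()}
    return total, parts


def _clone_template(template: INRTemplate) -> INRTemplate:
    out = INRTemplate(template.widths, template.omega0)
    out.load_state_vector(template.state_vector())
    return out


# --------------------------------------------------------------------------
# inner loops
# --------------------------------------------------------------------------

def inner_loop_stepA(
    template: INRTemplate,
    modulation: Modulation | None,
    d_reg: DVF,
    grid: CoordinateGrid,
    n_epochs: int,
    lr: float,
    optimizer: Adam | None = None,
) -> list[float]:
    """Optimise the INR on the deformation-discrepancy loss only.

    Mutates the template in place; returns the per-epoch loss history."""
    if n_epochs <= 0:
        return []
    opt = optimizer or Adam(template.parameters(), lr=lr)
    ref = Tensor(d_reg.field)
    history = []
    for _ in range(int(n_epochs)):
        d_full = resize_trilinear(
            _coarse_field(template, modulation, grid), grid.source_shape
        )
        loss = loss_stepA(d_full, ref)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(loss.item())
    return history


def inner_loop_stepB(
    template: INRTemplate,
    modulation: Modulation | None,
    case: RegistrationCase,
    grid: CoordinateGrid,
    n_epochs: int,
    lr: float,
    weights: LossWeights,
    prior: PriorNet | None = None,
    use_embed: bool = False,
    optimizer: Adam | None = None,
) -> list[dict]:
    """Optimise the INR on the weighted step-B objective; in-place."""
    if n_epochs <= 0:
        return []
    opt = optimizer or Adam(template.parameters(), lr=lr)
    target_embed = (
        prior_encode(prior, case.t_ui).vectors if use_embed else None
    )
    history = []
    for _ in range(int(n_epochs)):
        total, parts = _stepB_graph(
            _coarse_field(template, modulation, grid), case, prior,
            weights, use_embed, target_embed,
        )
        opt.zero_grad()
        total.backward()
        opt.step()
        history.append(parts)
    return history


# --------------------------------------------------------------------------
# meta-training
# --------------------------------------------------------------------------

def make_modulator(variant: str, grid_shape, hidden_width: int, seed: int,
                   token_dim: int = 48, n_heads: int = 4,
                   patch_size=(4, 4, 4), cnn_channels: int = 8):
    spec = VARIANTS[variant]
    if spec.modulator == "token":
        return TokenModulator(grid_shape, hidden_width, token_dim, n_heads,
                              patch_size, seed=seed)
    if spec.modulator == "cnn":
        return CNNModulator(grid_shape, hidden_width, cnn_channels, seed=seed)
    return None


def _sample_train_case(subject: Subject, rng: np.random.Generator,
                       cfg: MetaConfig) -> RegistrationCase:
    """Random (source, target) bin pair with a fresh random trajectory."""
    bins = rng.choice(subject.n_bins, size=2, replace=False)
    lo, hi = cfg.train_spokes_range
    n_spokes = int(rng.integers(lo, hi + 1))
    traj = golden_angle_trajectory(
        n_spokes, cfg.samples_per_spoke,
        seed_for_theta0=int(rng.integers(2**31 - 1)),
    )
    t_uk = nudft_forward(subject.volumes[bins[1]], traj)
    return build_case(subject.volumes[bins[0]], t_uk)


def meta_train(
    cohort: list[Subject],
    template: INRTemplate,
    modulator,
    prior: PriorNet | None,
    cfg: MetaConfig,
) -> tuple[INRTemplate, object, list[dict]]:
    """Reptile meta-training of (template, modulator); both mutated in place.

    Per outer iteration and subject: modulation from the *frozen* modulator,
    inner step-A epochs (if the variant uses the prior), inner step-B epochs,
    Reptile delta accumulation, then one modulator update by backpropagating
    the step-B loss with the INR frozen at Phi''.  Adam state is re-created
    per subject (and reset between step A and step B) so inner loops stay
    independent.  The prior net is never updated.
    """
    spec = cfg.variant_spec
    if not cohort:
        raise ValueError("empty cohort")
    if spec.use_stepA and prior is None:
        raise ValueError(f"variant {cfg.variant!r} requires a prior network")
    rng = rng_for(cfg.seed, "meta-train")
    grid = coordinate_grid(cohort[0].volumes[0].shape, cfg.downsample)
    mod_opt = Adam(modulator.parameters(), lr=cfg.lr) if modulator else None
    history: list[dict] = []
    n_x = len(cohort)
    for outer in range(int(cfg.n_outer)):
        phi = template.state_vector()
        delta = np.zeros_like(phi)
        outer_log = {"outer": outer, "stepA": [], "stepB": [], "modulator": []}
        for subject in cohort:
            case = _sample_train_case(subject, rng, cfg)
            if modulator is not None:
                with no_grad():
                    modulation = modulator(case.x).detached()
            else:
                modulation = None
            template.load_state_vector(phi)
            opt = Adam(template.parameters(), lr=cfg.lr)
            if spec.use_stepA:
                d_reg = prior_predict(prior, case.x)
                hist_a = inner_loop_stepA(
                    template, modulation, d_reg, grid, cfg.n_inner, cfg.lr, opt
                )
                outer_log["stepA"].append(hist_a[-1] if hist_a else None)
                opt.reset_state()
            hist_b = inner_loop_stepB(
                template, modulation, case, grid, cfg.n_inner, cfg.lr,
                cfg.weights, prior, spec.use_embed, opt,
            )
            outer_log["stepB"].append(hist_b[-1]["total"] if hist_b else None)
            phi2 = template.state_vector()
            delta += (phi2 - phi) / n_x
            if modulator is not None:
                # one modulator gradient step with the INR frozen at Phi''
                modulation_t = modulator(case.x)
                target_embed = (
                    prior_encode(prior, case.t_ui).vectors
                    if spec.use_embed else None
                )
                total, parts = _stepB_graph(
                    _coarse_field(template, modulation_t, grid), case, prior,
                    cfg.weights, spec.use_embed, target_embed,
                )
                mod_opt.zero_grad()
                total.backward()
                mod_opt.step()
                template.zero_grad()  # frozen: discard any INR grads
                outer_log["modulator"].append(parts["total"])
        template.load_state_vector(phi + delta)
        history.append(outer_log)
    return template, modulator, history


# --------------------------------------------------------------------------
# adaptation
# --------------------------------------------------------------------------

@dataclass
class AdaptResult:
    dvf: DVF
    s_di: ComplexVolume
    report: MetricReport | None
    history: dict
    modulation: Modulation | None


def adapt_case(
    template: INRTemplate | None,
    modulator,
    prior: PriorNet | None,
    case: RegistrationCase,
    cfg: MetaConfig,
) -> AdaptResult:
    """Test-time adaptation on one case; the trained template is not mutated.

    ``n_adapt=0`` returns the template's zero-shot prediction under the
    case's modulation.  For the ``ks_iterative`` baseline the DVF is a raw
    voxelwise array on the coarse grid, optimised through the same
    upsampling path.
    """
    spec = cfg.variant_spec
    if spec.use_stepA and prior is None:
        raise ValueError(f"variant {cfg.variant!r} requires a prior network")
    grid = coordinate_grid(case.shape, cfg.downsample)
    history: dict = {"stepA": [], "stepB": []}

    if modulator is not None:
        with no_grad():
            modulation = modulator(case.x).detached()
    else:
        modulation = None

    if spec.parametrization == "voxel":
        d_param = Tensor(np.zeros((3,) + grid.coarse_shape), requires_grad=True)

        def coarse():
            return d_param

        params = [d_param]
    else:
        if template is None:
            raise ValueError("INR-parameterised variants require a template")
        work = _clone_template(template)

        def coarse():
            return _coarse_field(work, modulation, grid)

        params = work.parameters()

    if spec.use_stepA and cfg.n_adapt > 0:
        d_reg = prior_predict(prior, case.x)
        opt = Adam(params, lr=cfg.lr)
        ref = Tensor(d_reg.field)
        for _ in range(int(cfg.n_adapt)):
            d_full = resize_trilinear(coarse(), case.shape)
            loss = loss_stepA(d_full, ref)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history["stepA"].append(loss.item())

    if cfg.n_adapt > 0:
        opt = Adam(params, lr=cfg.lr)
        target_embed = (
            prior_encode(prior, case.t_ui).vectors if spec.use_embed else None
        )
        for _ in range(int(cfg.n_adapt)):
            total, parts = _stepB_graph(
                coarse(), case, prior, cfg.weights, spec.use_embed, target_embed
            )
            opt.zero_grad()
            total.backward()
            opt.step()
            history["stepB"].append(parts)

    with no_grad():
        d_full = resize_trilinear(coarse(), case.shape)
    dvf = DVF(d_full.data, case.spacing_mm)
    s_di = warp_complex(case.s_fi, dvf)
    report = None
    if case.truth is not None:
        masks_s = case.truth.get("source_masks") or {}
        masks_t = case.truth.get("target_masks") or {}
        name = next(iter(masks_s), None)
        pred_mask = warp_mask(masks_s[name], dvf) if name else None
        truth_mask = masks_t.get(name) if name else None
        report = evaluate_case(
            s_di.magnitude, case.truth["target_magnitude"],
            pred_mask, truth_mask, case.spacing_mm,
        )
    return AdaptResult(dvf, s_di, report, history, modulation)


def stepB_epochs_to_threshold(
    template: INRTemplate,
    modulation: Modulation | None,
    case: RegistrationCase,
    cfg: MetaConfig,
    threshold: float,
    max_epochs: int,
) -> int:
    """Step-B epochs until the k-space fidelity loss first drops below
    ``threshold`` (``max_epochs`` if never reached).  The template is copied."""
    work = _clone_template(template)
    opt = Adam(work.parameters(), lr=cfg.lr)
    grid = coordinate_grid(case.shape, cfg.downsample)
    for epoch in range(1, int(max_epochs) + 1):
        total, parts = _stepB_graph(
            _coarse_field(work, modulation, grid), case, None,
            cfg.weights, False, None,
        )
        if parts["kspace"] <= threshold:
            return epoch - 1  # reached before this epoch's update
        opt.zero_grad()
        total.backward()
        opt.step()
    return int(max_epochs)


def run_variant(
    variant: str,
    cohort: list[Subject],
    cfg: MetaConfig,
    test_cases: list[RegistrationCase] | None = None,
    prior: PriorNet | None = None,
    template_seed: int | None = None,
) -> dict:
    """End-to-end run mode: (meta-)train as the variant prescribes, then
    adapt every test case.  All variants emit the same result schema."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    cfg = replace(cfg, variant=variant)
    spec = cfg.variant_spec
    shape = cohort[0].volumes[0].shape
    seed = template_seed if template_seed is not None else cfg.seed
    hidden = 64
    template = init_template((3, hidden, hidden, hidden, 3),
                             seed=child_seed(seed, "template"))
    modulator = make_modulator(variant, shape, hidden,
                               seed=child_seed(seed, "modulator"))
    history: list = []
    if spec.meta:
        template, modulator, history = meta_train(
            cohort, template, modulator, prior, cfg
        )
    results = []
    for case in test_cases or []:
        res = adapt_case(template, modulator, prior, case, cfg)
        results.append(res)
    return {
        "variant": variant,
        "template": template,
        "modulator": modulator,
        "meta_history": history,
        "adaptations": results,
        "reports": [r.report.as_dict() if r.report else None for r in results],
    }
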