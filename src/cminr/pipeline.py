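"""End-to-end orchestration behind the CLI subcommands.

Every stage writes into the run directory: the resolved config, the
per-stage seeds, a version stamp, JSONL loss logs and JSON metric
reports.  A single global seed controls all stages through the
documented fan-out, so re-running any stage with the same config
reproduces its outputs bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, save_config
from .inr import init_template
from .io import load_checkpoint, load_subject, save_checkpoint, save_subject
from .kspace import acceleration_factor_rounded
from .meta import (adapt_case, case_from_subject, make_modulator, meta_train)
from .metrics import evaluate_case
from .prior import PriorNet, train_prior
from .synthetic import (MotionModel, NoiseSpec, PhantomSpec, PhaseMapSpec,
                        default_phantom_spec, generate_cohort)

__all__ = ["cmd_simulate", "cmd_train_prior", "cmd_meta_train", "cmd_adapt",
           "cmd_evaluate", "cmd_pipeline"]


def _run_dir(cfg: RunConfig) -> Path:
    d = Path(cfg.output_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stamp(cfg: RunConfig, stage: str, payload: dict):
    d = _run_dir(cfg)
    save_config(cfg, d / "config.yaml")
    stampfile = d / "run_stamp.json"
    stamp = {}
    if stampfile.exists():
        stamp = json.loads(stampfile.read_text())
    stamp.setdefault("version", __version__)
    stamp.setdefault("global_seed", cfg.seed)
    stamp.setdefault("stages", {})
    stamp["stages"][stage] = {"seed": cfg.stage_seed(stage), **payload}
    stampfile.write_text(json.dumps(stamp, indent=2))


def _phantom_spec(cfg: RunConfig) -> PhantomSpec:
    base = default_phantom_spec(cfg.phantom.grid_shape, cfg.phantom.spacing_mm,
                                textured=cfg.phantom.texture_amp > 0)
    base.background_intensity = cfg.phantom.background_intensity
    base.texture_amp = cfg.phantom.texture_amp
    base.texture_scale_vox = cfg.phantom.texture_scale_vox
    return base


def build_cohort(cfg: RunConfig, seed: int | None = None, n_subjects=None):
    return generate_cohort(
        n_subjects or cfg.cohort.n_subjects,
        _phantom_spec(cfg),
        MotionModel(cfg.motion.amplitude_vox, cfg.motion.spatial_scale,
                    cfg.motion.n_bins),
        PhaseMapSpec(cfg.phase.n_freqs_per_axis, cfg.phase.freq_range_per_mm,
                     cfg.phase.amplitude),
        NoiseSpec(cfg.noise.sd_range),
        seed=cfg.stage_seed("simulate") if seed is None else seed,
        n_phase_maps=cfg.cohort.n_phase_maps,
        jitter_anatomy=cfg.cohort.jitter_anatomy,
    )


def cmd_simulate(cfg: RunConfig) -> list[Path]:
    """Write the synthetic cohort to HDF5 subject files."""
    d = _run_dir(cfg) / "cohort"
    d.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(cfg)
    specs_json = json.dumps({
        "phantom": cfg.phantom.model_dump(mode="json"),
        "motion": cfg.motion.model_dump(mode="json"),
        "phase": cfg.phase.model_dump(mode="json"),
        "noise": cfg.noise.model_dump(mode="json"),
    })
    paths = []
    for subj in cohort:
        p = d / f"subject_{subj.index:03d}.h5"
        save_subject(p, subj, specs_json, seed=cfg.stage_seed("simulate"))
        paths.append(p)
    af = acceleration_factor_rounded(256, cfg.trajectory.spokes)
    _stamp(cfg, "simulate", {
        "n_subjects": len(cohort),
        "n_bins": cfg.motion.n_bins,
        "files": [p.name for p in paths],
        "acceleration_factor_matrix256": af,
    })
    return paths


def _load_cohort_dir(path: Path):
    files = sorted(Path(path).glob("subject_*.h5"))
    if not files:
        raise FileNotFoundError(f"no subject files under {path}")
    return [load_subject(p) for p in files]


def cmd_train_prior(cfg: RunConfig, cohort=None) -> Path:
    """Train the lite prior registration net on the cohort; checkpoint it."""
    d = _run_dir(cfg)
    if cohort is None:
        cohort = _load_cohort_dir(d / "cohort")
    net = PriorNet(cfg.prior.base_channels, seed=cfg.stage_seed("prior-init"))
    net, history = train_prior(
        net, cohort, cfg.prior.epochs, cfg.prior.lr,
        n_spokes_range=cfg.trajectory.train_spokes_range,
        samples_per_spoke=cfg.trajectory.samples_per_spoke,
        downsample=cfg.inr.downsample,
        seed=cfg.stage_seed("train-prior"),
    )
    ckpt = d / "prior.npz"
    save_checkpoint(ckpt, prior=net)
    with open(d / "prior_loss.jsonl", "w") as f:
        for epoch, val in enumerate(history):
            f.write(json.dumps({"epoch": epoch, "loss": val}) + "\n")
    _stamp(cfg, "train-prior", {"epochs": cfg.prior.epochs,
                                "final_loss": history[-1] if history else None})
    return ckpt


def cmd_meta_train(cfg: RunConfig, cohort=None, prior=None) -> Path:
    """Meta-train the template and modulator; checkpoint both."""
    d = _run_dir(cfg)
    if cohort is None:
        cohort = _load_cohort_dir(d / "cohort")
    spec_needs_prior = cfg.variant in ("cmeta", "meta_inr_b")
    if prior is None and spec_needs_prior:
        prior = load_checkpoint(d / "prior.npz")["prior"]
    shape = cohort[0].volumes[0].shape
    w = cfg.inr.hidden_width
    template = init_template((3, w, w, w, 3), cfg.inr.omega0,
                             seed=cfg.stage_seed("template-init"))
    modulator = make_modulator(cfg.variant, shape, w,
                               seed=cfg.stage_seed("modulator-init"),
                               token_dim=cfg.inr.token_dim,
                               n_heads=cfg.inr.n_heads,
                               patch_size=cfg.inr.patch_size)
    mcfg = cfg.meta_config()
    template, modulator, history = meta_train(cohort, template, modulator,
                                              prior, mcfg)
    ckpt = d / "template.npz"
    save_checkpoint(ckpt, template=template, modulator=modulator,
                    extra={"variant": cfg.variant})
    with open(d / "meta_loss.jsonl", "w") as f:
        for rec in history:
            f.write(json.dumps(rec) + "\n")
    _stamp(cfg, "meta-train", {"n_outer": mcfg.n_outer, "variant": cfg.variant})
    return ckpt


def cmd_adapt(cfg: RunConfig, subject_path=None, target_bin: int = 1,
              template=None, modulator=None, prior=None) -> dict:
    """Adapt to one held-out case and write its metric report."""
    d = _run_dir(cfg)
    if subject_path is not None:
        subject = load_subject(subject_path)
    else:
        subject = _load_cohort_dir(d / "cohort")[0]
    if template is None and cfg.variant != "ks_iterative":
        ck = load_checkpoint(d / "template.npz")
        template, modulator = ck["template"], ck["modulator"]
    if prior is None and cfg.variant in ("cmeta", "meta_inr_b"):
        prior = load_checkpoint(d / "prior.npz")["prior"]
    mcfg = cfg.meta_config()
    case = case_from_subject(
        subject, target_bin, cfg.trajectory.spokes,
        cfg.trajectory.samples_per_spoke,
        theta0_seed=cfg.stage_seed(f"adapt-theta0-{target_bin}"),
    )
    result = adapt_case(template, modulator, prior, case, mcfg)
    report = result.report.as_dict() if result.report else None
    out = {
        "variant": cfg.variant,
        "target_bin": target_bin,
        "spokes": cfg.trajectory.spokes,
        "report": report,
        "final_stepB": result.history["stepB"][-1]
        if result.history["stepB"] else None,
    }
    with open(d / f"adapt_bin{target_bin}.json", "w") as f:
        json.dump(out, f, indent=2)
    _stamp(cfg, "adapt", {"target_bin": target_bin})
    return out


def cmd_evaluate(pred_magnitude, truth_magnitude, pred_mask=None,
                 truth_mask=None, spacing=(1.0, 1.0, 1.0),
                 out_path=None, out_csv=None) -> dict:
    """Metric report for stored prediction/truth volumes (arrays or .npy)."""
    def _arr(x):
        return np.load(x) if isinstance(x, (str, Path)) else np.asarray(x)

    report = evaluate_case(
        _arr(pred_magnitude), _arr(truth_magnitude),
        _arr(pred_mask) if pred_mask is not None else None,
        _arr(truth_mask) if truth_mask is not None else None,
        spacing,
    ).as_dict()
    if out_path:
        Path(out_path).write_text(json.dumps(report, indent=2))
    if out_csv:
        keys = list(report)
        Path(out_csv).write_text(
            ",".join(keys) + "\n"
            + ",".join("" if report[k] is None else str(report[k])
                       for k in keys) + "\n"
        )
    return report


def cmd_pipeline(cfg: RunConfig, held_out_bins=(1, 2)) -> dict:
    """simulate -> train-prior -> meta-train -> adapt (held-out) -> evaluate.

    The last cohort subject is held out of prior/meta training and used for
    adaptation.  One global seed controls every stage.  Returns the final
    report (also written to the run directory).
    """
    d = _run_dir(cfg)
    cohort = build_cohort(cfg)
    if len(cohort) < 2:
        raise ValueError("pipeline needs at least 2 subjects (1 held out)")
    train, held = cohort[:-1], cohort[-1]

    prior = None
    if cfg.variant in ("cmeta", "meta_inr_b"):
        net = PriorNet(cfg.prior.base_channels, seed=cfg.stage_seed("prior-init"))
        prior, _ = train_prior(
            net, train, cfg.prior.epochs, cfg.prior.lr,
            n_spokes_range=cfg.trajectory.train_spokes_range,
            samples_per_spoke=cfg.trajectory.samples_per_spoke,
            seed=cfg.stage_seed("train-prior"),
        )

    shape = train[0].volumes[0].shape
    w = cfg.inr.hidden_width
    template = init_template((3, w, w, w, 3), cfg.inr.omega0,
                             seed=cfg.stage_seed("template-init"))
    modulator = make_modulator(cfg.variant, shape, w,
                               seed=cfg.stage_seed("modulator-init"),
                               token_dim=cfg.inr.token_dim,
                               n_heads=cfg.inr.n_heads,
                               patch_size=cfg.inr.patch_size)
    mcfg = cfg.meta_config()
    if mcfg.variant_spec.meta:
        template, modulator, _ = meta_train(train, template, modulator,
                                            prior, mcfg)

    reports = {}
    for b in held_out_bins:
        if b >= held.n_bins:
            continue
        case = case_from_subject(
            held, b, cfg.trajectory.spokes, cfg.trajectory.samples_per_spoke,
            theta0_seed=cfg.stage_seed(f"adapt-theta0-{b}"),
        )
        res = adapt_case(template, modulator, prior, case, mcfg)
        reports[f"bin_{b}"] = res.report.as_dict() if res.report else None
    out = {"variant": cfg.variant, "seed": cfg.seed, "reports": reports}
    (d / "pipeline_report.json").write_text(json.dumps(out, indent=2))
    _stamp(cfg, "pipeline", {"held_out_bins": list(held_out_bins)})
    return out
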