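"""Run configuration schema (YAML-backed, schema-validated).

A single :class:`RunConfig` describes an end-to-end run: cohort synthesis,
trajectory, INR/modulator/prior architecture, loss weights and the
meta-learning schedule.  Unknown keys are rejected.  One global seed fans
out to per-stage seeds through :func:`cminr.seeding.child_seed`, so every
stage is reproducible in isolation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .losses import LossWeights
from .meta import VARIANTS, MetaConfig
from .seeding import child_seed

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    background_intensity: float = 0.08
    texture_amp: float = 0.06
    texture_scale_vox: float = 3.0


class MotionConfig(_Strict):
    amplitude_vox: tuple[float, float, float] = (0.5, 1.0, 2.0)
    spatial_scale: float = 8.0
    n_bins: int = 4


class PhaseConfig(_Strict):
    n_freqs_per_axis: int = 4
    freq_range_per_mm: tuple[float, float] = (1.25e-3, 2.50e-3)
    amplitude: float = 1.0


class NoiseConfig(_Strict):
    sd_range: tuple[float, float] = (3.0e-3, 5.0e-3)


class CohortConfig(_Strict):
    n_subjects: int = 6
    n_phase_maps: int = 1
    jitter_anatomy: bool = True


class TrajectoryConfig(_Strict):
    spokes: int = 13
    samples_per_spoke: int = 64
    train_spokes_range: tuple[int, int] = (5, 13)
    include_edge: bool = False


class INRConfig(_Strict):
    hidden_width: int = 64
    omega0: float = 30.0
    downsample: int = 2
    token_dim: int = 48
    n_heads: int = 4
    patch_size: tuple[int, int, int] = (4, 4, 4)


class PriorConfig(_Strict):
    base_channels: int = 8
    epochs: int = 200
    lr: float = 2.0e-3


class LossConfig(_Strict):
    lambda1: float = 1.0
    lambda2: float = 0.5
    lambda3: float = 0.5

    def weights(self) -> LossWeights:
        return LossWeights(self.lambda1, self.lambda2, self.lambda3)


class MetaScheduleConfig(_Strict):
    n_outer: int = 30
    n_inner: int = 10
    n_adapt: int = 50
    lr: float = 5.0e-3


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "runs/default"
    variant: str = "cmeta"
    phantom: PhantomConfig = PhantomConfig()
    motion: MotionConfig = MotionConfig()
    phase: PhaseConfig = PhaseConfig()
    noise: NoiseConfig = NoiseConfig()
    cohort: CohortConfig = CohortConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    inr: INRConfig = INRConfig()
    prior: PriorConfig = PriorConfig()
    losses: LossConfig = LossConfig()
    meta: MetaScheduleConfig = MetaScheduleConfig()

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v):
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {sorted(VARIANTS)}")
        return v

    def stage_seed(self, stage: str) -> int:
        return child_seed(self.seed, stage)

    def meta_config(self) -> MetaConfig:
        return MetaConfig(
            n_outer=self.meta.n_outer,
            n_inner=self.meta.n_inner,
            n_adapt=self.meta.n_adapt,
            lr=self.meta.lr,
            seed=self.stage_seed("meta-train"),
            variant=self.variant,
            spokes=self.trajectory.spokes,
            samples_per_spoke=self.trajectory.samples_per_spoke,
            train_spokes_range=self.trajectory.train_spokes_range,
            downsample=self.inr.downsample,
            weights=self.losses.weights(),
        )


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg.model_dump(mode="json"), f, sort_keys=False)
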