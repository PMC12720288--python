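"""HDF5 / NIfTI serialisation and model checkpoints.

Subjects are written one file each: per-bin groups hold ``real``, ``imag``,
``dvf`` and ``mask/<name>`` datasets; spacing, seed and the generating
specs (as JSON) sit in the root attributes.  K-space data stores the
sample values split into real/imaginary parts together with the
trajectory definition.  Checkpoints are plain ``.npz`` archives holding a
JSON metadata header plus flat parameter vectors — no pickling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .inr import CNNModulator, INRTemplate, TokenModulator
from .kspace import KSpaceData, RadialTrajectory
from .prior import PriorNet
from .synthetic import Subject
from .volumes import ComplexVolume, DVF

__all__ = [
    "save_subject",
    "load_subject",
    "save_kspace",
    "load_kspace",
    "save_checkpoint",
    "load_checkpoint",
    "export_nifti",
]

FORMAT_VERSION = 1


def save_subject(path, subject: Subject, specs_json: str | None = None,
                 seed: int | None = None):
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["spacing"] = subject.spacing_mm
        f.attrs["index"] = subject.index
        if seed is not None:
            f.attrs["seed"] = seed
        if specs_json is not None:
            f.attrs["specs"] = specs_json
        f.create_dataset("magnitude0", data=subject.magnitude0)
        for pm, arr in enumerate(subject.phase_maps):
            f.create_dataset(f"phase_maps/{pm}", data=arr)
        for b in range(subject.n_bins):
            g = f.create_group(f"bins/{b:02d}")
            g.create_dataset("real", data=subject.volumes[b].real)
            g.create_dataset("imag", data=subject.volumes[b].imag)
            g.create_dataset("clean_real", data=subject.clean_volumes[b].real)
            g.create_dataset("clean_imag", data=subject.clean_volumes[b].imag)
            g.create_dataset("dvf", data=subject.dvfs[b].field)
            for name, m in subject.bin_masks[b].items():
                g.create_dataset(f"mask/{name}", data=m.astype(np.uint8))


def load_subject(path) -> Subject:
    with h5py.File(path, "r") as f:
        spacing = tuple(float(s) for s in f.attrs["spacing"])
        index = int(f.attrs.get("index", 0))
        magnitude0 = f["magnitude0"][()]
        phase_maps = [f[f"phase_maps/{k}"][()] for k in sorted(f["phase_maps"])]
        volumes, clean, dvfs, bin_masks = [], [], [], []
        for key in sorted(f["bins"]):
            g = f[f"bins/{key}"]
            volumes.append(ComplexVolume(g["real"][()], g["imag"][()], spacing))
            clean.append(
                ComplexVolume(g["clean_real"][()], g["clean_imag"][()], spacing)
            )
            dvfs.append(DVF(g["dvf"][()], spacing))
            masks = {}
            if "mask" in g:
                for name in g["mask"]:
                    masks[name] = g[f"mask/{name}"][()].astype(bool)
            bin_masks.append(masks)
    return Subject(index, spacing, magnitude0, dict(bin_masks[0]), phase_maps,
                   volumes, clean, dvfs, bin_masks)


def save_kspace(path, k: KSpaceData):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("values_real", data=k.values.real)
        f.create_dataset("values_imag", data=k.values.imag)
        f.create_dataset("angles", data=k.trajectory.angles_rad)
        f.attrs["theta0"] = k.trajectory.theta0_rad
        f.attrs["n_spokes"] = k.trajectory.n_spokes
        f.attrs["samples_per_spoke"] = k.trajectory.samples_per_spoke
        f.attrs["include_edge"] = k.trajectory.include_edge


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        traj = RadialTrajectory(
            int(f.attrs["n_spokes"]),
            int(f.attrs["samples_per_spoke"]),
            float(f.attrs["theta0"]),
            bool(f.attrs["include_edge"]),
        )
        values = f["values_real"][()] + 1j * f["values_imag"][()]
    return KSpaceData(values, traj)


def _modulator_meta(mod) -> dict:
    if mod is None:
        return {"kind": "none"}
    if isinstance(mod, TokenModulator):
        return {
            "kind": "token",
            "grid_shape": list(mod.grid_shape),
            "hidden_width": mod.generators[0].width,
            "token_dim": mod.token_dim,
            "n_heads": mod.attn.n_heads,
            "patch_size": list(mod.patch_size),
        }
    if isinstance(mod, CNNModulator):
        return {
            "kind": "cnn",
            "grid_shape": list(mod.grid_shape),
            "hidden_width": mod.generators[0].width,
            "channels": mod.conv1.c_out,
        }
    raise TypeError(f"unknown modulator type {type(mod)!r}")


def save_checkpoint(path, template: INRTemplate | None = None, modulator=None,
                    prior: PriorNet | None = None, extra: dict | None = None):
    """Versioned single-archive checkpoint (.npz with JSON metadata)."""
    meta = {"format_version": FORMAT_VERSION, "extra": extra or {}}
    arrays = {}
    if template is not None:
        meta["template"] = {"widths": list(template.widths),
                            "omega0": template.omega0}
        arrays["template_state"] = template.state_vector()
    if modulator is not None:
        meta["modulator"] = _modulator_meta(modulator)
        arrays["modulator_state"] = modulator.state_vector()
    if prior is not None:
        meta["prior"] = {"base_channels": prior.base_channels,
                         "trained": prior.trained}
        arrays["prior_state"] = prior.state_vector()
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        out = {"meta": meta, "template": None, "modulator": None, "prior": None}
        if "template" in meta:
            t = INRTemplate(tuple(meta["template"]["widths"]),
                            meta["template"]["omega0"])
            t.load_state_vector(f["template_state"])
            out["template"] = t
        if "modulator" in meta and meta["modulator"]["kind"] != "none":
            m = meta["modulator"]
            if m["kind"] == "token":
                mod = TokenModulator(tuple(m["grid_shape"]), m["hidden_width"],
                                     m["token_dim"], m["n_heads"],
                                     tuple(m["patch_size"]))
            else:
                mod = CNNModulator(tuple(m["grid_shape"]), m["hidden_width"],
                                   m["channels"])
            mod.load_state_vector(f["modulator_state"])
            out["modulator"] = mod
        if "prior" in meta:
            p = PriorNet(meta["prior"]["base_channels"])
            p.load_state_vector(f["prior_state"])
            p.trained = bool(meta["prior"]["trained"])
            out["prior"] = p
    return out


def export_nifti(path, array: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)):
    """Write a magnitude volume or mask as NIfTI for visual inspection."""
    import nibabel as nib

    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), str(path))
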