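"""Golden-angle radial sampling: trajectory, undersampled images, k-space.

Simulates a 13-spoke stack-of-stars acquisition of a phantom and shows
the acceleration factor and the artifact level of the adjoint
reconstruction used as model input.
"""

import numpy as np

from cminr.kspace import (acceleration_factor, acceleration_factor_rounded,
                          golden_angle_trajectory, nudft_adjoint,
                          nudft_forward, preprocess_case)
from cminr.synthetic import default_phantom_spec, generate_phantom
from cminr.volumes import ComplexVolume

mag, _ = generate_phantom(default_phantom_spec((32, 32, 8)), seed=3)
vol = ComplexVolume(mag, np.zeros_like(mag), spacing_mm=(4, 4, 8))

traj = golden_angle_trajectory(n_spokes=13, samples_per_spoke=64,
                               seed_for_theta0=11)
print(f"spokes: {traj.n_spokes}, samples/spoke: {traj.samples_per_spoke}")
print(f"spoke angles (deg): {np.round(np.rad2deg(traj.angles_rad[:4]), 2)} ...")
# successive spokes rotate by the golden angle, 111.25 deg
for spokes in (13, 9, 5):
    print(f"  {spokes:>2} spokes on a 256 matrix -> acceleration factor "
          f"{acceleration_factor(256, spokes):.1f} "
          f"(~{acceleration_factor_rounded(256, spokes)})")

t_uk = nudft_forward(vol, traj)
print(f"k-space samples per slice: {t_uk.trajectory.n_samples}, "
      f"total N_k = {t_uk.n_k}")

x, s_ui, t_ui, s_uk = preprocess_case(vol, t_uk)
print(f"model input X: {x.planes.shape} (6 planes: Re/Im of the fully-sampled "
      "source, the artifact-matched undersampled source, and the "
      "undersampled target)")
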