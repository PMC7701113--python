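"""Build a phantom design and render a synthetic distorted scan.

Creates a small jittered-grid design (3 enlarged landmark spheres included),
draws a smooth random distortion field of known magnitude, renders one scan
with partial-volume sphere edges and 2% Gaussian noise, and prints where the
spheres ended up.  The 'apparent' positions differ from the placed ('true')
positions by the distortion field evaluated at the apparent location — the
quantity the whole method is built to recover.
"""

import numpy as np

from msemap import TruthField, design_extent, generate_synthetic_design
from msemap.simulate import SceneSpec, render_scan

design = generate_synthetic_design(grid_counts=(6, 5, 4),
                                   spacing=(35.0, 35.0, 35.0),
                                   jitter_sd=1.0, seed=1)
print(f"design: {len(design)} fiducials, {len(design.landmarks)} landmarks, "
      f"extent {np.round(design_extent(design))} mm")

box = np.stack([design.positions.min(axis=0) - 40,
                design.positions.max(axis=0) + 40])
truth = TruthField.random(box, orders=(3, 3, 3), max_magnitude=3.0, seed=2)

scene = SceneSpec(design=design, voxel_size=np.array([1.5625, 1.5625, 1.0]),
                  volume_shape=(160, 144, 176),
                  noise_model="gaussian", noise_sd=0.02)
scan, truth_table = render_scan(scene, truth, seed=3)

shift = np.linalg.norm(
    truth_table[["x_apparent", "y_apparent", "z_apparent"]].values
    - truth_table[["x_true", "y_true", "z_true"]].values, axis=1)
print(f"rendered volume {scan.shape}, voxel {scan.voxel_size} mm")
print(f"distortion moved sphere centres by {shift.mean():.2f} mm on average "
      f"(max {shift.max():.2f} mm)")
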