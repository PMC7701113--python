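# msemap

Multi-scan mapping of MRI geometric distortion from a compact fiducial
phantom.

MR images used for radiotherapy planning must be geometrically faithful, but
gradient nonlinearity and B0 inhomogeneity displace structures by several
millimetres far from the scanner isocenter — exactly where non-coplanar
beams pass.  Distortion is measured with phantoms carrying hundreds of
fiducial spheres at known positions, yet a phantom small enough to handle in
a clinic covers only ~20 cm of the bore.  `msemap` implements a multi-scan
expansion: scan the same compact phantom at several patient-table positions,
and fit **one** displacement field to all scans jointly, with independent
rigid-body terms per scan absorbing each phantom placement.  Discarding the
rigid terms leaves the scanner's distortion field over the union of the
scanned regions — no knowledge of the absolute phantom position is required,
and three scans at table shifts 0 / ±5 cm extend a 20 cm measurement to
30 cm.

The displacement of the point appearing at image location `x` in scan `s` is
modelled as

    d(x, s) = δ_s + ε_s × x + Σ'_{mnpi} A_mnpi U_m(x~) U_n(y~) U_p(z~) ê_i

with per-scan rigid parameters `(δ_s, ε_s)` and a shared tensor expansion in
Chebyshev polynomials of the second kind over box-normalized coordinates;
the prime excludes the six rigid basis functions (3 translations, 3
linearized rotations) from the distortion block, keeping the six symmetric
strain terms.  The fit is Tikhonov-regularized (order-dependent weights,
GCV-selected λ), so the deliberately over-complete basis does not overfit.
The centre scan, placed at isocenter by the alignment lasers, is special:
its fitted `(δ, ε)` measures the laser-to-gradient-frame misalignment.

The package covers the full workflow:

- **design**: phantom layouts (JSON/CSV), including a built-in 505-sphere
  design with three enlarged landmark spheres on a scalene triangle;
- **simulate**: a synthetic scan renderer with partial-volume sphere edges,
  Gaussian/Rician noise and a known ground-truth field, so every stage can
  be validated without a scanner;
- **segmentation**: NCC template matching (125-subsample partial-volume
  templates) with ×8 sinc sub-voxel refinement (~0.01 mm noiseless, ~0.06 mm
  in a realistic session);
- **localization**: unique landmark identification + orthogonal Procrustes
  placement, mutual-nearest-neighbour correspondence;
- **fieldfit**: the joint multi-scan fit, field evaluation, laser
  misalignment;
- **metrics**: point/image distortion correction (inverse warp by fixed
  point), radial boxplot profiles, rigid-invariant inter-sphere distance
  validation;
- **io / pipeline / cli**: NIfTI and DICOM readers/writers and an `mse`
  command (`simulate | segment | fit | correct | report | run`).

## Worked example

```python
import numpy as np
from msemap import TruthField, default_phantom_design
from msemap.fieldfit import build_design_matrix, fit_multiscan, laser_misalignment
from msemap.simulate import simulate_observations

design = default_phantom_design(seed=0)          # 505 spheres, 3 landmarks
box = np.stack([design.positions.min(0) - 30 - [0, 0, 50],
                design.positions.max(0) + 30 + [0, 0, 50]])
truth = TruthField.random(box, orders=(4, 4, 4), max_magnitude=5.0, seed=7)

sim = simulate_observations(design, truth,
                            [(0, 0, 0), (0, 0, 50), (0, 0, -50)],
                            placement_noise=(1.0, 0.3),
                            localization_noise_sd=0.2, seed=21)
fit = fit_multiscan(build_design_matrix(sim.observations, truth.as_fit().basis),
                    lam="gcv")
at = np.array([o.segmented for o in sim.observations])
err = np.linalg.norm(fit.evaluate(at) - truth.evaluate(at), axis=1)
print(len(sim.observations), fit.lam, err.mean())
```

prints (run as `examples/03_multiscan_fit.py`, which adds labels):

```
1515 observations from 3 scans
lambda (GCV) = 100; field error at fiducials: rms 0.022 mm, max 0.068 mm
series 0: fitted delta [ 0.55  0.02 -0.46] mm (placement perturbation was [ 0.56  0.02 -0.48] mm)
...
laser misalignment readout: |delta| = 0.72 mm, rotation 0.217 deg
```

1515 = 3 × 505 displacement observations enter one fit; despite each scan
carrying an unknown ~1 mm / 0.3° placement error and 0.2 mm localization
noise, the recovered field matches the 5 mm-peak truth to 0.02 mm rms at the
fiducials, and the per-series rigid terms reproduce the injected placements
— which is why the absolute phantom position never needs to be known.  The
`examples/` directory has one short script per capability (design+renderer,
segmentation+localization, multi-scan fit, correction+validation).

A full image-level session is one call:

```bash
mse simulate --out session/ --seed 1            # renders 3 distorted scans
mse run --config session.yaml                   # segment -> localize -> fit -> report
```

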