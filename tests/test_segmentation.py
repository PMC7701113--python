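import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msemap.design import FiducialSpec, PhantomDesign
from msemap.errors import MsemapError
from msemap.segmentation import (detect_fiducials, generate_template, ncc_map,
                                 refine_subvoxel)
from msemap.simulate import SceneSpec, TruthField, render_scan

VOXEL = np.array([1.5625, 1.5625, 1.0])


def direct_ncc(img: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Brute-force sliding-window zero-normalized cross-correlation oracle.

    Defined at window centres where the template fits entirely inside the
    image; NaN elsewhere.
    """
    t0 = t - t.mean()
    tss = (t0**2).sum()
    out = np.full(img.shape, np.nan)
    h = [s // 2 for s in t.shape]
    for i in range(h[0], img.shape[0] - h[0]):
        for j in range(h[1], img.shape[1] - h[1]):
            for k in range(h[2], img.shape[2] - h[2]):
                patch = img[i - h[0]:i + h[0] + 1, j - h[1]:j + h[1] + 1,
                            k - h[2]:k + h[2] + 1]
                p0 = patch - patch.mean()
                den = np.sqrt((p0**2).sum() * tss)
                out[i, j, k] = (p0 * t0).sum() / den if den > 1e-12 else 0.0
    return out


class TestGenerateTemplate:
    def test_oversampling_factor_is_125_subsamples_per_voxel(self):
        t = generate_template(10.0, VOXEL)
        assert t.subsamples_per_voxel == 125

    def test_interior_voxel_equals_sphere_level_exactly(self):
        t = generate_template(10.0, VOXEL, background=1.0, sphere_level=0.0)
        c = tuple((np.array(t.voxels.shape) - 1) // 2)
        assert t.voxels[c] == 0.0
        assert t.voxels[0, 0, 0] == 1.0  # corner is pure background

    def test_equatorial_half_cut_voxel_near_midpoint(self):
        # large-sphere limit: voxel centred on the surface sees a half-plane cut
        t = generate_template(60.0, (1.0, 1.0, 1.0))
        c = (np.array(t.voxels.shape) - 1) // 2
        value = t.voxels[c[0] + 30, c[1], c[2]]
        assert abs(value - 0.5) < 0.02

    def test_unresolvable_diameter_rejected(self):
        with pytest.raises(MsemapError, match="unresolvable"):
            generate_template(2.0, VOXEL)


class TestNccMap:
    def _pasted_template_image(self, shape=(32, 32, 32)):
        t = generate_template(6.0, (1.0, 1.0, 1.0))
        img = np.full(shape, 1.0)
        c = tuple(s // 2 for s in shape)
        h = [d // 2 for d in t.voxels.shape]
        img[c[0] - h[0]:c[0] + h[0] + 1, c[1] - h[1]:c[1] + h[1] + 1,
            c[2] - h[2]:c[2] + h[2] + 1] = t.voxels
        return img, t, c

    def test_self_match_peaks_at_one(self):
        img, t, c = self._pasted_template_image()
        ncc = ncc_map(img, t)
        assert np.unravel_index(np.argmax(ncc), ncc.shape) == c
        assert ncc[c] == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_invariant_to_positive_affine_intensity_maps(self, a, b):
        img, t, c = self._pasted_template_image()
        ncc = ncc_map(a * img + b, t)
        assert np.unravel_index(np.argmax(ncc), ncc.shape) == c
        assert ncc[c] == pytest.approx(1.0, abs=1e-7)

    def test_two_identical_spheres_give_equal_maxima(self):
        t = generate_template(6.0, (1.0, 1.0, 1.0))
        img = np.full((64, 32, 32), 1.0)
        h = [d // 2 for d in t.voxels.shape]
        for cx in (12, 52):
            img[cx - h[0]:cx + h[0] + 1, 16 - h[1]:16 + h[1] + 1,
                16 - h[2]:16 + h[2] + 1] = t.voxels
        ncc = ncc_map(img, t)
        assert abs(ncc[12, 16, 16] - ncc[52, 16, 16]) < 1e-6
        assert ncc[12, 16, 16] > 0.999

    def test_fft_ncc_equals_direct_sliding_window(self, rng):
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.random((16, 16, 16)), 1.0)
        t = generate_template(4.0, (1.0, 1.0, 1.0))
        ours = ncc_map(img, t)
        oracle = direct_ncc(img, t.voxels)
        m = ~np.isnan(oracle)
        assert np.abs(ours[m] - oracle[m]).max() < 1e-10

    def test_zero_variance_patch_gets_zero(self):
        t = generate_template(4.0, (1.0, 1.0, 1.0))
        ncc = ncc_map(np.full((16, 16, 16), 3.0), t)
        np.testing.assert_array_equal(ncc, np.zeros_like(ncc))


class TestDetectFiducials:
    def _toy_ncc(self):
        ncc = np.zeros((32, 32, 32))
        ncc[10, 10, 10] = 0.9
        ncc[10, 10, 20] = 0.7  # 10 mm away at unit voxels
        return ncc

    def test_exclusion_radius_keeps_only_stronger_peak(self):
        peaks = self._toy_ncc()
        kept = detect_fiducials(peaks, 0.5, min_separation=15.0,
                                voxel_size=(1, 1, 1))
        assert kept.tolist() == [[10, 10, 10]]

    def test_separated_peaks_both_kept(self):
        kept = detect_fiducials(self._toy_ncc(), 0.5, min_separation=8.0,
                                voxel_size=(1, 1, 1))
        assert sorted(kept.tolist()) == [[10, 10, 10], [10, 10, 20]]

    def test_threshold_above_max_gives_no_peaks(self, rng):
        ncc = np.clip(rng.normal(0, 0.1, (16, 16, 16)), -1, 1)
        assert len(detect_fiducials(ncc, 1.0 + 1e-9)) == 0

    def test_mm_separation_respects_anisotropic_voxels(self):
        ncc = np.zeros((32, 32, 32))
        ncc[10, 10, 10] = 0.9
        ncc[20, 10, 10] = 0.8  # 10 voxels = 15.6 mm at 1.5625 mm spacing
        kept = detect_fiducials(ncc, 0.5, min_separation=15.0,
                                voxel_size=(1.5625, 1, 1))
        assert len(kept) == 2


class TestRefineSubvoxel:
    def _sphere_ncc(self, offset):
        center = np.asarray(offset)
        design = PhantomDesign([FiducialSpec(0, center, 10.0, False)],
                               _validate=False)
        scene = SceneSpec(design=design, voxel_size=VOXEL,
                          volume_shape=(24, 24, 32), noise_model="none")
        scan, _ = render_scan(scene, TruthField.zero(), seed=0)
        t = generate_template(10.0, VOXEL)
        return ncc_map(scan, t), scan

    def test_factor_one_returns_integer_voxel(self):
        ncc, scan = self._sphere_ncc([0.0, 0.0, 0.0])
        peak = detect_fiducials(ncc, 0.5, 15.0, VOXEL)[0]
        det = refine_subvoxel(ncc, peak, factor=1, affine=scan.affine)
        np.testing.assert_allclose(det.position,
                                   scan.voxel_to_world(peak.astype(float))[0])

    def test_symmetric_peak_moves_less_than_sixteenth_voxel(self):
        # sphere rendered exactly at a voxel centre: origin of the centred grid
        ncc, scan = self._sphere_ncc([0.78125, 0.78125, 0.5])
        peak = detect_fiducials(ncc, 0.5, 15.0, VOXEL)[0]
        det = refine_subvoxel(ncc, peak, affine=scan.affine)
        shift = np.abs(det.position - scan.voxel_to_world(peak.astype(float))[0])
        assert np.all(shift / VOXEL < 1 / 16 + 1e-9)

    def test_random_subvoxel_offsets_localized_accurately(self, rng):
        errs = []
        t = generate_template(10.0, VOXEL)
        for i in range(20):
            ctr = rng.uniform(-0.5, 0.5, 3) * VOXEL
            design = PhantomDesign([FiducialSpec(0, ctr, 10.0, False)],
                                   _validate=False)
            scene = SceneSpec(design=design, voxel_size=VOXEL,
                              volume_shape=(24, 24, 32), noise_model="none")
            scan, _ = render_scan(scene, TruthField.zero(), seed=i)
            ncc = ncc_map(scan, t)
            det = refine_subvoxel(ncc, detect_fiducials(ncc, 0.5, 15.0, VOXEL)[0],
                                  affine=scan.affine)
            errs.append(np.linalg.norm(det.position - ctr))
        assert np.mean(errs) < 0.2

    def test_boundary_peak_returned_unrefined(self):
        ncc = np.zeros((16, 16, 16))
        ncc[1, 8, 8] = 0.9
        det = refine_subvoxel(ncc, (1, 8, 8))
        assert not det.refined
        np.testing.assert_array_equal(det.position, [1.0, 8.0, 8.0])
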