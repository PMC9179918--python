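"""Trabecular morphometry: lattice truths, fractal suite, binarization."""

import numpy as np
import pytest

from jointqmri.bone_morphometry import (
    binarize_trabeculae,
    bone_volume_fraction,
    compute_bone_biomarkers,
    fractal_dimension_2d,
    fractal_dimension_3d,
    trabecular_number,
    trabecular_spacing,
    trabecular_thickness,
)
from jointqmri.grids import DegenerateDataError, ParameterError, VolumeGrid
from jointqmri.phantoms import TrabecularPhantomSpec, make_trabecular_phantom


def plate_phantom(th=2, per=10, blur=0.0, noise=0.0, seed=0, shape=(32, 32, 66)):
    return make_trabecular_phantom(
        TrabecularPhantomSpec(
            shape=shape, thickness=th, period=per, blur_fwhm_mm=blur,
            noise_sigma=noise, seed=seed,
        )
    )


# ---------------------------------------------------------------- fractals

def sierpinski_carpet(iters=5):
    a = np.ones((1, 1), bool)
    for _ in range(iters):
        z = np.zeros_like(a)
        a = np.block([[a, a, a], [a, z, a], [a, a, a]])
    return a


def menger_sponge(iters=3):
    a = np.ones((1, 1, 1), bool)
    for _ in range(iters):
        s = a.shape[0]
        b = np.zeros((3 * s,) * 3, bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if (i == 1) + (j == 1) + (k == 1) < 2:
                        b[i * s:(i + 1) * s, j * s:(j + 1) * s, k * s:(k + 1) * s] = a
        a = b
    return a


class TestFractalDimensions:
    def test_filled_cube_is_three(self):
        assert fractal_dimension_3d(np.ones((81, 81, 81), bool)) == pytest.approx(3.0, abs=0.05)

    def test_straight_line_is_one(self):
        sl = np.zeros((243, 243), bool)
        sl[121, :] = True
        assert fractal_dimension_2d(sl) == pytest.approx(1.0, abs=0.05)

    def test_filled_square_area_vs_boundary_mode(self):
        sq = np.ones((243, 243), bool)
        assert fractal_dimension_2d(sq, mode="area") == pytest.approx(2.0, abs=0.05)
        # the boundary of a filled square is its perimeter, a curve
        assert fractal_dimension_2d(sq, mode="boundary") == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet_dimension(self):
        expected = np.log(8) / np.log(3)  # 1.8928
        assert fractal_dimension_2d(sierpinski_carpet(5)) == pytest.approx(expected, abs=0.05)

    def test_menger_sponge_dimension(self):
        expected = np.log(20) / np.log(3)  # 2.7268
        assert fractal_dimension_3d(menger_sponge(3)) == pytest.approx(expected, abs=0.08)

    def test_convergence_with_iteration_depth(self):
        expected = np.log(8) / np.log(3)
        errs = [abs(fractal_dimension_2d(sierpinski_carpet(k)) - expected) for k in (4, 5)]
        assert errs[1] <= errs[0] + 1e-9

    def test_too_few_scales_errors(self):
        with pytest.raises(ParameterError):
            fractal_dimension_3d(np.ones((8, 8, 8), bool))

    def test_empty_structure_errors(self):
        with pytest.raises(ParameterError):
            fractal_dimension_2d(np.zeros((81, 81), bool))

    def test_d2d_averages_slices_with_structure(self):
        vol = np.zeros((81, 81, 9), bool)
        vol[:, :, 2] = True  # one filled slice
        vol[40, :, 5] = True  # one line slice
        d = fractal_dimension_2d(vol, axis=2)
        assert d == pytest.approx(1.5, abs=0.05)


# ---------------------------------------------------------------- BV/TV etc.

class TestBoneVolumeFraction:
    def test_all_ones_and_all_zeros(self):
        voi = VolumeGrid(np.ones((8, 8, 8), bool))
        assert bone_volume_fraction(VolumeGrid(np.ones((8, 8, 8), bool)), voi) == 1.0
        assert bone_volume_fraction(VolumeGrid(np.zeros((8, 8, 8), bool)), voi) == 0.0

    def test_plate_truth_mask_exact(self):
        ph = plate_phantom(2, 10)
        assert bone_volume_fraction(ph.truth_binary, ph.voi) == pytest.approx(0.2)

    def test_random_mask_counting_oracle(self, rng):
        b = rng.random((10, 10, 10)) > 0.6
        v = rng.random((10, 10, 10)) > 0.3
        if not v.any():
            v[0, 0, 0] = True
        expect = (b & v).sum() / v.sum()
        assert bone_volume_fraction(VolumeGrid(b), VolumeGrid(v)) == pytest.approx(expect)

    def test_monotone_in_added_bone(self):
        voi = VolumeGrid(np.ones((8, 8, 8), bool))
        b = np.zeros((8, 8, 8), bool)
        b[:2] = True
        f1 = bone_volume_fraction(VolumeGrid(b), voi)
        b2 = b.copy()
        b2[4] = True
        assert bone_volume_fraction(VolumeGrid(b2), voi) > f1

    def test_empty_voi_errors(self):
        with pytest.raises(ParameterError):
            bone_volume_fraction(
                VolumeGrid(np.ones((4, 4, 4), bool)), VolumeGrid(np.zeros((4, 4, 4), bool))
            )


class TestThicknessSpacing:
    def test_plate_lattice_th4(self):
        ph = plate_phantom(4, 10)
        th = trabecular_thickness(ph.truth_binary, ph.voi)
        sp = trabecular_spacing(ph.truth_binary, ph.voi)
        assert th == pytest.approx(0.4, abs=0.1)
        assert sp == pytest.approx(0.6, abs=0.1)

    def test_rod_thickness_converges_to_diameter(self):
        # square rods of width w: thickness -> w * spacing as w grows
        for w, per, tol in [(3, 12, 0.35), (6, 24, 0.2)]:
            ph = make_trabecular_phantom(
                TrabecularPhantomSpec(
                    shape=(per * 3 + w, per * 3 + w, 30), lattice="orthogonal_rods",
                    thickness=w, period=per,
                )
            )
            th = trabecular_thickness(ph.truth_binary, ph.voi)
            assert th == pytest.approx(w * 0.1, rel=tol)

    def test_empty_phase_errors(self):
        with pytest.raises(ParameterError):
            trabecular_thickness(VolumeGrid(np.zeros((8, 8, 8), bool)))

    def test_tbn_identity_and_errors(self):
        assert trabecular_number(0.2, 0.4) == pytest.approx(0.5)
        assert trabecular_number(0.0, 0.4) == 0.0
        with pytest.raises(ParameterError):
            trabecular_number(0.2, 0.0)

    def test_plate_tbn_within_15pct_of_analytic(self):
        ph = plate_phantom(2, 10)
        bvtv = bone_volume_fraction(ph.truth_binary, ph.voi)
        th = trabecular_thickness(ph.truth_binary, ph.voi)
        tbn = trabecular_number(bvtv, th)
        assert tbn == pytest.approx(1.0 / (10 * 0.1), rel=0.15)
        assert tbn * th == pytest.approx(bvtv, rel=1e-12)  # identity by construction

    def test_anisotropic_input_resampled(self):
        # same physical plates on an anisotropic grid: thickness unchanged
        ph = plate_phantom(4, 10)
        iso = trabecular_thickness(ph.truth_binary, ph.voi)
        aniso = VolumeGrid(ph.truth_binary.data[::2], (0.2, 0.1, 0.1))
        voi2 = VolumeGrid(ph.voi.data[::2], (0.2, 0.1, 0.1))
        assert trabecular_thickness(aniso, voi2) == pytest.approx(iso, abs=0.1)


# ---------------------------------------------------------------- binarize

class TestBinarize:
    def test_idempotent_on_clean_binary(self):
        ph = plate_phantom(2, 10)
        voi = ph.voi
        out = binarize_trabeculae(ph.truth_binary.like(ph.truth_binary.data.astype(float)), voi)
        truth = ph.truth_binary.data & voi.data
        disagree = (out.data != truth)[voi.data].mean()
        assert disagree <= 0.01

    def test_blurred_plate_round_trip_bvtv(self):
        ph = plate_phantom(4, 10, blur=0.1)  # FWHM = 1 voxel
        binary = binarize_trabeculae(ph.gray, ph.voi)
        assert bone_volume_fraction(binary, ph.voi) == pytest.approx(0.4, abs=0.02)

    def test_inverted_contrast_same_mask(self):
        ph = plate_phantom(2, 10, blur=0.1, noise=0.02, seed=9)
        a = binarize_trabeculae(ph.gray, ph.voi)
        inv = ph.gray.like(1.0 - ph.gray.data)
        b = binarize_trabeculae(inv, ph.voi, inverted=True)
        assert (a.data != b.data).mean() <= 0.01

    def test_constant_voi_errors(self):
        flat = VolumeGrid(np.full((8, 8, 8), 3.0))
        with pytest.raises(DegenerateDataError):
            binarize_trabeculae(flat, VolumeGrid(np.ones((8, 8, 8), bool)))


class TestFullBiomarkers:
    def test_translation_invariance_on_periodic_plates(self):
        base = plate_phantom(2, 10, shape=(32, 32, 66))
        shifted_data = np.roll(base.truth_binary.data, 10, axis=2)  # one full period
        shifted = base.truth_binary.like(shifted_data)
        th_a = trabecular_thickness(base.truth_binary, base.voi)
        th_b = trabecular_thickness(shifted, base.voi)
        assert th_b == pytest.approx(th_a, rel=0.01)

    def test_biomarker_bundle_on_blurred_phantom(self):
        ph = plate_phantom(2, 10, blur=0.1, seed=2)
        bm = compute_bone_biomarkers(ph.gray, ph.voi, voi_label="lateral", slice_axis=0)
        assert bm.voi_label == "lateral"
        assert bm.bvtv == pytest.approx(ph.truth.bvtv, abs=0.02)
        assert bm.tb_th_mm == pytest.approx(ph.truth.tb_th_mm, abs=0.05)
        assert bm.tb_sp_mm == pytest.approx(ph.truth.tb_sp_mm, abs=0.05)
        assert bm.tb_n_per_mm * bm.tb_th_mm == pytest.approx(bm.bvtv, rel=1e-12)
        assert 0 <= bm.d2d <= 2.05 and 0 <= bm.d3d <= 3.05
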