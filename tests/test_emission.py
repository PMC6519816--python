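"""Iso-contour VOI quantification, calibration, resampling, frame selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batquant import (
    IsoContourQuantifier,
    NotQuantifiableError,
    PET_FRAME_SCHEDULE,
    VOIBox,
    calibrate_spect,
    quantify_voi,
    resample_isotropic,
    select_uptake_frame,
)


def brute_force_mask(voxels, bounds, cutoff):
    """Voxel-by-voxel reference implementation of the iso-contour rule."""
    (x0, x1), (y0, y1), (z0, z1) = bounds
    vmin, vmax = np.inf, -np.inf
    for i in range(x0, x1):
        for j in range(y0, y1):
            for k in range(z0, z1):
                v = voxels[i, j, k]
                vmin = min(vmin, v)
                vmax = max(vmax, v)
    thr = vmin + cutoff * (vmax - vmin)
    mask = np.zeros(voxels.shape, dtype=bool)
    for i in range(x0, x1):
        for j in range(y0, y1):
            for k in range(z0, z1):
                mask[i, j, k] = voxels[i, j, k] >= thr
    return mask, thr


class TestCalibrateSpect:
    def test_factor_635(self, image_factory):
        img = image_factory(np.full((4, 4, 4), 100.0), unit="counts_per_cc",
                            modality="SPECT", isotope="I123")
        out = calibrate_spect(img)
        assert out.value_unit == "Bq_per_cc"
        assert np.all(out.voxels == 63_500.0)

    def test_zero_voxels_stay_zero(self, image_factory):
        img = image_factory(np.zeros((3, 3, 3)), unit="counts_per_cc",
                            modality="SPECT", isotope="Tc99m")
        assert np.all(calibrate_spect(img, 123.4).voxels == 0)

    def test_round_trip_bit_exact(self, rng, image_factory):
        # discrete counts (quantized values): round trip is exactly invertible
        vox = rng.integers(0, 4096, size=(8, 8, 8)) / 1024.0
        img = image_factory(vox, unit="counts_per_cc", modality="SPECT",
                            isotope="Tc99m")
        back = calibrate_spect(img).voxels / 635.0
        assert np.array_equal(back, vox)

    def test_rejects_double_calibration_and_bad_factor(self, image_factory):
        calibrated = image_factory(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="already calibrated"):
            calibrate_spect(calibrated)
        raw = image_factory(np.ones((2, 2, 2)), unit="counts_per_cc",
                            modality="SPECT", isotope="I123")
        with pytest.raises(ValueError, match="positive"):
            calibrate_spect(raw, factor=0.0)


class TestResample:
    def test_identity_at_target(self, rng, image_factory):
        img = image_factory(rng.random((5, 5, 5)), spacing=(3.0, 3.0, 3.0))
        assert resample_isotropic(img, 3.0) is img

    def test_constant_preserved(self, image_factory):
        img = image_factory(np.full((9, 9, 9), 7.25), spacing=(1.0, 1.0, 1.0))
        out = resample_isotropic(img, 3.0)
        assert out.voxels.shape == (3, 3, 3)
        assert np.allclose(out.voxels, 7.25)

    def test_total_activity_conserved(self, rng, image_factory):
        img = image_factory(rng.random((12, 12, 12)), spacing=(1.5,) * 3)
        out = resample_isotropic(img, 3.0)
        total_in = img.voxels.sum() * np.prod(img.spacing_mm)
        total_out = out.voxels.sum() * 27.0
        assert abs(total_out - total_in) / total_in < 5e-3

    def test_noninteger_ratio_conserves_interior_mean(self, rng, image_factory):
        # 7 voxels of 1.4 mm (9.8 mm) onto 3 mm: edge voxel is partial
        img = image_factory(rng.random((7, 7, 7)), spacing=(1.4,) * 3)
        out = resample_isotropic(img, 3.0)
        assert out.voxels.shape == (4, 4, 4)
        # intensive: output range bounded by input range
        assert out.voxels.max() <= img.voxels.max() + 1e-12
        assert out.voxels.min() >= img.voxels.min() - 1e-12

    def test_rejects_upsampling(self, rng, image_factory):
        img = image_factory(rng.random((4, 4, 4)), spacing=(3.0,) * 3)
        with pytest.raises(ValueError, match="upsample"):
            resample_isotropic(img, 1.0)


class TestFrameSelection:
    def test_last_frame_spans_final_interval(self, rng, image_factory):
        vox = rng.random((4, 4, 4, len(PET_FRAME_SCHEDULE)))
        img = image_factory(vox, schedule=tuple(PET_FRAME_SCHEDULE))
        out = select_uptake_frame(img, "last")
        assert out.frame_schedule == ((1200.0, 300.0),)
        assert np.array_equal(out.voxels, vox[..., -1])

    def test_single_frame_identity(self, rng, image_factory):
        img = image_factory(rng.random((3, 3, 3)))
        assert select_uptake_frame(img, "sum") is img

    def test_duration_weighted_mean(self, image_factory):
        vox = np.stack([np.ones((2, 2, 2)), np.full((2, 2, 2), 2.0)], axis=3)
        img = image_factory(vox, schedule=((0.0, 15.0), (15.0, 300.0)))
        out = select_uptake_frame(img, "sum")
        assert np.allclose(out.voxels, (15 * 1 + 300 * 2) / 315)

    def test_index_policy_and_bounds(self, rng, image_factory):
        vox = rng.random((3, 3, 3, 4))
        img = image_factory(vox)
        assert np.array_equal(select_uptake_frame(img, 2).voxels, vox[..., 2])
        with pytest.raises(ValueError, match="out of range"):
            select_uptake_frame(img, 4)


class TestQuantifyVOI:
    def test_worked_cutoff_example(self, image_factory):
        # VOI values {0, 2, 4, 10}: threshold 0 + 0.3*(10-0) = 3.0,
        # retained {4, 10}, 2 voxels of 1 mm^3 -> 0.002 cm^3
        vox = np.zeros((4, 1, 1))
        vox[:, 0, 0] = [0.0, 2.0, 4.0, 10.0]
        r = quantify_voi(image_factory(vox), VOIBox(((0, 4), (0, 1), (0, 1))))
        assert r.threshold_value == pytest.approx(3.0)
        assert r.n_voxels == 2
        assert r.metabolic_volume_cm3 == pytest.approx(0.002)
        assert r.suv_mean == pytest.approx(7.0 / (5e7 / 500.0))

    def test_uniform_voi_closed_form(self, image_factory):
        # max == min: threshold = min, all retained;
        # SUV = 1000 / (5e7 / 500) = 0.01 g/cm^3
        img = image_factory(np.full((5, 5, 5), 1000.0))
        r = quantify_voi(img, VOIBox(((0, 5), (0, 5), (0, 5))))
        assert r.n_voxels == 125
        assert r.suv_mean == pytest.approx(0.01)
        assert r.total_metabolic_activity == pytest.approx(
            r.suv_mean * r.metabolic_volume_cm3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scan(self, seed, image_factory):
        rng = np.random.default_rng(seed)
        vox = rng.random((16, 16, 16)) * 1e4
        bounds = ((3, 13), (2, 14), (4, 16))
        q = IsoContourQuantifier().fit(image_factory(vox), VOIBox(bounds))
        ref_mask, ref_thr = brute_force_mask(vox, bounds, 0.30)
        assert np.array_equal(q.mask_, ref_mask)
        assert q.threshold_value_ == pytest.approx(ref_thr)

    def test_volume_monotone_in_cutoff(self, rng, image_factory):
        img = image_factory(rng.random((10, 10, 10)) * 100)
        box = VOIBox(((1, 9), (1, 9), (1, 9)))
        vols = [quantify_voi(img, box, cutoff_fraction=c).metabolic_volume_cm3
                for c in np.linspace(0.0, 1.0, 11)]
        assert vols[0] == pytest.approx(8 ** 3 * img.voxel_volume_cm3)
        assert all(a >= b - 1e-12 for a, b in zip(vols, vols[1:]))

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, scale):
        rng = np.random.default_rng(7)
        vox = rng.random((8, 8, 8)) * 1e3
        from conftest import make_image
        box = VOIBox(((1, 7), (1, 7), (1, 7)))
        r1 = quantify_voi(make_image(vox, dose=5e7), box)
        r2 = quantify_voi(make_image(vox * scale, dose=5e7 * scale), box)
        assert r2.suv_mean == pytest.approx(r1.suv_mean, rel=1e-9)
        assert r2.n_voxels == r1.n_voxels
        assert r2.metabolic_volume_cm3 == pytest.approx(
            r1.metabolic_volume_cm3)

    def test_calibration_linearity(self, rng, image_factory):
        counts = rng.random((8, 8, 8)) * 50
        box = VOIBox(((0, 8), (0, 8), (0, 8)))
        raw_as_bq = image_factory(counts, modality="SPECT", isotope="Tc99m")
        spect = image_factory(counts, unit="counts_per_cc", modality="SPECT",
                              isotope="Tc99m")
        r_raw = quantify_voi(raw_as_bq, box)
        r_cal = quantify_voi(calibrate_spect(spect, 635.0), box)
        assert r_cal.suv_mean == pytest.approx(635.0 * r_raw.suv_mean)
        assert r_cal.n_voxels == r_raw.n_voxels

    def test_not_quantifiable_flag_and_raise(self, image_factory):
        img = image_factory(np.zeros((4, 4, 4)))
        box = VOIBox(((0, 4), (0, 4), (0, 4)))
        r = quantify_voi(img, box)
        assert not r.quantifiable and np.isnan(r.suv_mean)
        with pytest.raises(NotQuantifiableError):
            IsoContourQuantifier(raise_on_nq=True).fit(img, box)

    def test_rejects_uncalibrated_dynamic_or_bad_box(self, rng, image_factory):
        box = VOIBox(((0, 2), (0, 2), (0, 2)))
        with pytest.raises(ValueError, match="calibrate"):
            quantify_voi(image_factory(np.ones((2, 2, 2)),
                                       unit="counts_per_cc",
                                       modality="SPECT", isotope="I123"), box)
        with pytest.raises(ValueError, match="dynamic"):
            quantify_voi(image_factory(rng.random((2, 2, 2, 3))), box)
        with pytest.raises(ValueError, match="extent"):
            quantify_voi(image_factory(np.ones((2, 2, 2))),
                         VOIBox(((0, 3), (0, 2), (0, 2))))


class TestDomainValidation:
    def test_image_invariants(self, image_factory):
        with pytest.raises(ValueError, match="non-negative"):
            image_factory(np.array([[[-1.0]]]))
        with pytest.raises(ValueError, match="positive"):
            image_factory(np.ones((2, 2, 2)), spacing=(1.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="contiguous"):
            image_factory(np.ones((2, 2, 2, 2)),
                          schedule=((0.0, 10.0), (20.0, 10.0)))

    def test_box_invariants(self):
        with pytest.raises(ValueError):
            VOIBox(((2, 2), (0, 1), (0, 1)))
        with pytest.raises(ValueError):
            VOIBox(((-1, 2), (0, 1), (0, 1)))
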