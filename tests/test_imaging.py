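import numpy as np
import pytest

from fdopakin import SubjectMeta, TimeActivityCurve, ValidationError, build_schedule, compute_suv, edvr
from fdopakin.imaging import (
    DynamicImage,
    RegionMask,
    extract_tac,
    gaussian_smooth,
    load_dynamic_image,
    load_mask,
    make_phantom,
    mean_frame_image,
    save_dynamic_image,
    save_mask,
    suv_image,
)
from fdopakin.simulate import (
    TissueKinetics,
    default_plasma_input,
    default_reference_kinetics,
    simulate_region,
)
from fdopakin.stats import asymmetry_index

META = SubjectMeta("r1", "WT", 5, weight_kg=0.37, injected_dose_MBq=18.5)


@pytest.fixture()
def small_schedule():
    return build_schedule([60.0, 60.0, 120.0])


@pytest.fixture()
def uniform_image(small_schedule):
    vox = np.full((8, 8, 8, 3), 5.0)
    return DynamicImage(vox, (0.4, 0.4, 0.4), small_schedule)


class TestExtractTac:
    def test_uniform_image_gives_constant_tac(self, uniform_image):
        mask = RegionMask(np.ones((8, 8, 8), dtype=bool), "whole")
        tac = extract_tac(uniform_image, mask)
        np.testing.assert_allclose(tac.activity, 5.0)
        assert tac.region_label == "whole"

    def test_single_voxel_mask_returns_its_time_course(self, small_schedule):
        vox = np.zeros((4, 4, 4, 3))
        vox[1, 2, 3] = [1.0, 2.0, 3.0]
        image = DynamicImage(vox, (0.4, 0.4, 0.4), small_schedule)
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 2, 3] = True
        np.testing.assert_allclose(extract_tac(image, RegionMask(m, "v")).activity, [1, 2, 3])

    def test_linear_in_image_and_order_invariant(self, uniform_image):
        rng = np.random.default_rng(0)
        vox = rng.uniform(0, 10, uniform_image.voxels.shape)
        img = DynamicImage(vox, (0.4, 0.4, 0.4), uniform_image.schedule)
        img2 = DynamicImage(2 * vox, (0.4, 0.4, 0.4), uniform_image.schedule)
        mask = RegionMask(rng.uniform(size=(8, 8, 8)) > 0.5, "m")
        np.testing.assert_allclose(
            extract_tac(img2, mask).activity, 2 * extract_tac(img, mask).activity
        )

    def test_grid_mismatch_and_empty_mask_rejected(self, uniform_image):
        with pytest.raises(ValidationError):
            extract_tac(uniform_image, RegionMask(np.ones((4, 4, 4), dtype=bool), "m"))
        with pytest.raises(ValidationError):
            RegionMask(np.zeros((8, 8, 8), dtype=bool), "empty")


class TestMeanFrameImage:
    def test_single_frame_window(self, small_schedule):
        vox = np.stack([np.full((4, 4, 4), v) for v in (1.0, 2.0, 3.0)], axis=-1)
        image = DynamicImage(vox, (0.4, 0.4, 0.4), small_schedule)
        np.testing.assert_allclose(mean_frame_image(image, 0.0, 60.0), 1.0)

    def test_constant_image_unchanged(self, uniform_image):
        np.testing.assert_allclose(mean_frame_image(uniform_image, 0.0, 240.0), 5.0)

    def test_equal_duration_frames_average(self):
        sched = build_schedule([60.0, 60.0])
        vox = np.stack([np.full((2, 2, 2), 1.0), np.full((2, 2, 2), 3.0)], axis=-1)
        image = DynamicImage(vox, (0.4, 0.4, 0.4), sched)
        np.testing.assert_allclose(mean_frame_image(image, 0.0, 120.0), 2.0)

    def test_empty_window_errors(self, uniform_image):
        with pytest.raises(ValidationError):
            mean_frame_image(uniform_image, 1000.0, 2000.0)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(size=(10, 10, 10))
        np.testing.assert_array_equal(gaussian_smooth(vol, 0.0, (0.4, 0.4, 0.4)), vol)

    def test_total_activity_conserved(self):
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 100.0
        out = gaussian_smooth(vol, (1.0, 1.0, 1.0), (0.4, 0.4, 0.4))
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_delta_spike_matches_analytic_kernel(self):
        vox_mm = 0.4
        fwhm = 1.0
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox_mm
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        out = gaussian_smooth(vol, fwhm, vox_mm)
        x = np.arange(41) - 20.0
        g = np.exp(-(x**2) / (2 * sigma_vox**2))
        g /= g.sum()
        # scipy truncates the kernel at 4 sigma, hence the loose-ish bound
        np.testing.assert_allclose(out[:, 20, 20], g[20] * g[20] * g, rtol=2e-3, atol=1e-6)


class TestSUVImage:
    def test_uniform_activity_printed_example(self, uniform_image):
        np.testing.assert_allclose(suv_image(uniform_image, META, 0.0, 240.0), 0.1)

    def test_doubling_dose_halves_suv(self, uniform_image):
        meta2 = SubjectMeta("r1", "WT", 5, weight_kg=0.37, injected_dose_MBq=37.0)
        np.testing.assert_allclose(
            suv_image(uniform_image, meta2, 0.0, 240.0),
            suv_image(uniform_image, META, 0.0, 240.0) / 2.0,
        )

    def test_consistent_with_tac_pathway(self, uniform_image):
        mask = RegionMask(np.ones((8, 8, 8), dtype=bool), "all")
        suv_tac = compute_suv(extract_tac(uniform_image, mask), META)
        w = uniform_image.schedule.frame_durations
        expected = float((suv_tac.suv * w).sum() / w.sum())
        np.testing.assert_allclose(suv_image(uniform_image, META, 0.0, 240.0), expected)


class TestPhantom:
    def _tacs(self, sched):
        return {
            "a": TimeActivityCurve(sched, np.array([1.0, 2.0, 3.0]), "a"),
            "b": TimeActivityCurve(sched, np.array([5.0, 4.0, 3.0]), "b"),
        }

    def test_round_trip_is_exact(self, small_schedule):
        tacs = self._tacs(small_schedule)
        image, masks = make_phantom(
            tacs,
            {"a": ((2.0, 2.0, 2.0), 1.0), "b": ((6.0, 6.0, 6.0), 1.5)},
            grid_shape=(24, 24, 24),
            voxel_size_mm=(0.4, 0.4, 0.4),
        )
        for mask in masks:
            np.testing.assert_allclose(
                extract_tac(image, mask).activity, tacs[mask.label].activity, atol=1e-10
            )

    def test_overlap_rejected(self, small_schedule):
        with pytest.raises(ValidationError, match="overlap"):
            make_phantom(
                self._tacs(small_schedule),
                {"a": ((2.0, 2.0, 2.0), 2.0), "b": ((2.4, 2.0, 2.0), 2.0)},
                grid_shape=(16, 16, 16),
            )

    def test_full_pipeline_detects_turnover_asymmetry_sign(self, sched):
        # left k_loss raised => lower left EDVR => positive asymmetry index
        # under the contralateral=right convention
        inp = default_plasma_input()
        left = simulate_region(TissueKinetics(k_loss=0.015), inp, sched, "L")
        right = simulate_region(TissueKinetics(k_loss=0.010), inp, sched, "R")
        cer = simulate_region(default_reference_kinetics(), inp, sched, "C")
        image, masks = make_phantom(
            {"L": left, "R": right, "C": cer},
            {"L": ((4.0, 8.0, 8.0), 1.6), "R": ((12.0, 8.0, 8.0), 1.6), "C": ((8.0, 3.0, 8.0), 2.0)},
        )
        by_label = {m.label: extract_tac(image, m) for m in masks}
        a = asymmetry_index(
            edvr(by_label["R"], by_label["C"]).EDVR, edvr(by_label["L"], by_label["C"]).EDVR
        )
        assert a > 0


class TestNiftiIO:
    def test_image_and_mask_round_trip(self, tmp_path, small_schedule):
        rng = np.random.default_rng(2)
        image = DynamicImage(rng.uniform(0, 10, (6, 5, 4, 3)), (0.4, 0.5, 0.6), small_schedule)
        path = tmp_path / "img.nii.gz"
        save_dynamic_image(image, path)
        loaded = load_dynamic_image(path)
        np.testing.assert_allclose(loaded.voxels, image.voxels, rtol=1e-6)
        assert loaded.voxel_size_mm == pytest.approx(image.voxel_size_mm)
        assert loaded.schedule.same_grid(image.schedule)

        mask = RegionMask(rng.uniform(size=(6, 5, 4)) > 0.5, "roi")
        mpath = tmp_path / "mask.nii.gz"
        save_mask(mask, mpath)
        np.testing.assert_array_equal(load_mask(mpath, "roi").voxels, mask.voxels)
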