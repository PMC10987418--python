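"""CRC/CNR computation, VOI construction, sigmoid fitting, FWHM measurement."""

import numpy as np
import pytest

from hospect.metrics import (
    CrcCurve,
    VoiSet,
    cnr,
    crc,
    fit_sigmoid,
    make_vois,
    measure_fwhm,
    sigmoid,
)
from hospect.phantom import (
    GridSpec,
    SphereSpec,
    build_jaszczak,
    default_grid,
    jaszczak_sphere_set,
)

SIX_X = np.array([9.9, 12.4, 15.4, 19.8, 24.8, 31.3]) / 5.0


@pytest.fixture(scope="module")
def phantom():
    return build_jaszczak(default_grid(64, 4.0), jaszczak_sphere_set())


@pytest.fixture(scope="module")
def vois(phantom):
    return make_vois(phantom, erosion_margin=0)


class TestMakeVois:
    def test_zero_margin_equals_full_label(self, phantom, vois):
        for lab, mask in vois.sphere_masks.items():
            np.testing.assert_array_equal(mask, phantom.labels == lab)

    def test_background_cylinder_restricted_to_background_label(self, phantom, vois):
        assert vois.background_mask.any()
        assert np.all(phantom.labels[vois.background_mask] == 1)
        z, y, x = phantom.grid.center_mesh()
        r = np.sqrt(y**2 + x**2)
        assert np.all(np.broadcast_to(r, phantom.grid.shape)[vois.background_mask] <= 25.0)

    def test_erosion_reduces_by_at_most_one_shell(self):
        sphere = SphereSpec(center=(0.0, 0.0, 0.0), inner_diameter=31.3, activity_conc=1.0)
        grid = GridSpec((48, 48, 48), (1.0, 1.0, 1.0), (-23.5, -23.5, -23.5))
        ph = build_jaszczak(grid, [sphere], background_conc=0.1)
        full = np.count_nonzero(ph.labels == 2)
        eroded = make_vois(ph, erosion_margin=1, bg_radius_mm=23.0, bg_height_mm=20.0)
        n_eroded = np.count_nonzero(eroded.sphere_masks[2])
        assert n_eroded < full
        # analytic one-voxel-shell bound: 4*pi*r^2*dr with r ~ 15.65 mm, dr = 1 mm
        shell = 4 * np.pi * 15.65**2 * 1.0 * 1.5
        assert full - n_eroded <= shell

    def test_erosion_emptying_sphere_raises_with_name(self, phantom):
        with pytest.raises(ValueError, match="sphere label 2"):
            make_vois(phantom, erosion_margin=3)


class TestCrc:
    def test_truth_volume_gives_unit_crc(self, phantom, vois):
        values = crc(phantom.activity, vois)
        for v in values.values():
            assert v == pytest.approx(1.0, rel=1e-9)

    def test_global_scaling_invariance(self, phantom, vois):
        base = crc(phantom.activity, vois)
        scaled = crc(7.3 * phantom.activity, vois)
        for lab in base:
            assert scaled[lab] == pytest.approx(base[lab], rel=1e-12)

    def test_hand_computed_toy(self):
        # 4-voxel toy: 2 sphere voxels (values 6, 8), 2 background (2, 4)
        vol = np.array([[[6.0, 8.0], [2.0, 4.0]]])
        sphere = np.array([[[True, True], [False, False]]])
        bg = np.array([[[False, False], [True, True]]])
        vois = VoiSet(
            sphere_masks={2: sphere}, background_mask=bg, true_conc={2: 3.5, 1: 1.0}
        )
        # CRC = (7/3.5) / (3/1) = 2/3
        assert crc(vol, vois)[2] == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_zero_background_errors(self):
        vol = np.zeros((1, 2, 2))
        vol[0, 0, 0] = 1.0
        vois = VoiSet(
            sphere_masks={2: vol > 0},
            background_mask=np.array([[[False, False], [True, True]]]),
            true_conc={2: 1.0, 1: 1.0},
        )
        with pytest.raises(ZeroDivisionError):
            crc(vol, vois)


class TestCnr:
    def test_equal_means_give_zero(self):
        vol = np.array([[[5.0, 5.0], [4.0, 6.0]]])
        vois = VoiSet(
            sphere_masks={2: np.array([[[True, True], [False, False]]])},
            background_mask=np.array([[[False, False], [True, True]]]),
            true_conc={2: 1.0, 1: 1.0},
        )
        assert cnr(vol, vois)[2] == 0.0

    def test_hand_computed_toy(self):
        # sphere mean 10, bg values (1, 2, 3): mean 2, sample sd 1
        vol = np.array([[[10.0, 10.0], [1.0, 2.0]], [[10.0, 10.0], [3.0, 0.0]]])
        sphere = np.zeros_like(vol, dtype=bool)
        sphere[:, 0, :] = True
        bg = np.zeros_like(vol, dtype=bool)
        bg[0, 1, 0] = bg[0, 1, 1] = bg[1, 1, 0] = True
        vois = VoiSet(sphere_masks={2: sphere}, background_mask=bg, true_conc={2: 1, 1: 1})
        assert cnr(vol, vois)[2] == pytest.approx(8.0, rel=1e-12)

    def test_positive_scaling_invariance(self, phantom, vois, rng):
        vol = phantom.activity + rng.normal(0, 0.01, phantom.activity.shape)
        base = cnr(vol, vois)
        scaled = cnr(3.0 * vol, vois)
        for lab in base:
            assert scaled[lab] == pytest.approx(base[lab], rel=1e-9)


class TestSigmoidFit:
    def test_exact_recovery_from_noise_free_curve(self):
        b, c, d = 2.0, 3.0, 0.1
        x = np.array([9.9, 12.4, 15.4, 19.8, 24.8, 31.3]) / 5.0
        curve = CrcCurve(x=x, crc=sigmoid(x, b, c, d))
        fit = fit_sigmoid(curve)
        assert fit.a == 1.0
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.d == pytest.approx(d, abs=1e-6)
        assert fit.residual_ss < 1e-12

    def test_asymptote_is_one_minus_d(self):
        fit = fit_sigmoid(CrcCurve(x=SIX_X, crc=sigmoid(SIX_X, 2.0, 3.0, 0.1)))
        assert fit(np.array([1e6]))[0] == pytest.approx(1.0 - fit.d, abs=1e-12)

    def test_median_recovery_under_noise(self):
        b, c, d = 2.0, 3.0, 0.1
        truth = sigmoid(SIX_X, b, c, d)
        rng = np.random.default_rng(2024)
        recovered = []
        for _ in range(200):
            noisy = truth + rng.normal(0, 0.02, truth.shape)
            try:
                fit = fit_sigmoid(CrcCurve(x=SIX_X, crc=noisy))
            except RuntimeError:
                continue
            recovered.append((fit.b, fit.c, fit.d))
        med = np.median(np.array(recovered), axis=0)
        assert med[0] == pytest.approx(b, rel=0.10)
        assert med[1] == pytest.approx(c, rel=0.10)
        assert med[2] == pytest.approx(d, abs=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(CrcCurve(x=np.array([1.0, 2.0]), crc=np.array([0.1, 0.2])))


class TestMeasureFwhm:
    def test_sampled_gaussian(self):
        x = np.arange(101, dtype=float)
        profile = np.exp(-0.5 * ((x - 50) / 5.0) ** 2)
        assert measure_fwhm(profile, 1.0) == pytest.approx(11.77, rel=0.01)

    def test_amplitude_invariance(self):
        x = np.arange(101, dtype=float)
        profile = np.exp(-0.5 * ((x - 50) / 5.0) ** 2)
        assert measure_fwhm(37.0 * profile, 1.0) == measure_fwhm(profile, 1.0)

    def test_noisy_gaussian_mean_within_3_percent(self):
        x = np.arange(101, dtype=float)
        truth = 2.3548 * 5.0
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(100):
            profile = np.exp(-0.5 * ((x - 50) / 5.0) ** 2) + rng.normal(0, 0.01, x.size)
            vals.append(measure_fwhm(profile, 1.0))
        assert np.mean(vals) == pytest.approx(truth, rel=0.03)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            measure_fwhm(np.ones(10), 1.0)


class TestEndToEndOrderings:
    def test_crc_ordering_matches_scatter_correction_quality(self, study_result):
        """Scatter-free > TEW > uncorrected in mean CRC."""
        sf = study_result.mean_crc("scatter_free")
        tew = study_result.mean_crc("tew")
        unc = study_result.mean_crc("uncorrected")
        assert sf > tew > unc

    def test_cnr_orderings(self, study_result):
        """Scatter-free beats uncorrected; TEW is noisier than DEW."""
        assert study_result.mean_cnr("scatter_free") > study_result.mean_cnr("uncorrected")
        assert study_result.mean_cnr("tew") < study_result.mean_cnr("dew")
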