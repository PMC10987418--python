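"""Spectrum component sampling and projection synthesis."""

import dataclasses

import numpy as np
import pytest

from hospect.phantom import SphereSpec, build_jaszczak, default_grid, jaszczak_sphere_set
from hospect.simulate import (
    COMPONENTS,
    AcquisitionGeometry,
    PsfModel,
    ScatterKernels,
    SpectrumComponentModel,
    forward_project,
    fwhm_at,
    sample_window_components,
    synthesize_acquisition,
)


def small_geometry(n=64, n_proj=8):
    return AcquisitionGeometry(
        n_projections=n_proj, detector_matrix=(n, n), pixel_size=4.0
    )


class TestSpectrumModel:
    def test_default_rows_sum_to_one(self):
        m = SpectrumComponentModel.default()
        for w, f in m.per_window_fraction.items():
            assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SpectrumComponentModel(
                per_window_fraction={"W2": np.array([0.5, 0.4, 0.0, 0.0])},
                window_rate_scale={"W2": 1.0},
            )

    @pytest.mark.parametrize(
        "window,component,expected",
        [("W2", "high_energy_scatter", 0.487), ("W4", "high_energy_scatter", 0.969)],
    )
    def test_multinomial_tallies_match_configured_fractions(self, window, component, expected):
        m = SpectrumComponentModel.default()
        n = 10**6
        tallies = sample_window_components(m, window, n, seed=7)
        assert sum(tallies.values()) == n
        frac = tallies[component] / n
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * sigma

    def test_single_component_model_gets_all_events(self):
        m = SpectrumComponentModel.photopeak_only()
        tallies = sample_window_components(m, "W2", 1000, seed=0)
        assert tallies[COMPONENTS[0]] == 1000
        assert all(tallies[c] == 0 for c in COMPONENTS[1:])

    def test_unknown_window_rejected(self):
        with pytest.raises(KeyError):
            sample_window_components(SpectrumComponentModel.default(), "W9", 10)


class TestPsf:
    def test_fwhm_at_zero_is_intrinsic(self):
        psf = PsfModel(fwhm_intrinsic=4.0, fwhm_slope=0.55)
        assert fwhm_at(psf, 0.0) == 4.0

    def test_monotone_in_distance(self):
        psf = PsfModel()
        d = np.linspace(0, 40, 20)
        f = [fwhm_at(psf, x) for x in d]
        assert np.all(np.diff(f) >= 0)

    def test_linear_model_recovered_from_two_points(self):
        psf = PsfModel(fwhm_intrinsic=3.1, fwhm_slope=0.72)
        d1, d2 = 5.0, 25.0
        slope = (fwhm_at(psf, d2) - fwhm_at(psf, d1)) / (d2 - d1)
        intercept = fwhm_at(psf, d1) - slope * d1
        assert slope == pytest.approx(0.72, rel=1e-12)
        assert intercept == pytest.approx(3.1, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            fwhm_at(PsfModel(), -1.0)


class TestForwardProject:
    def test_zero_activity_gives_zero_projections(self):
        ph = build_jaszczak(default_grid(64, 4.0), spheres=[], background_conc=0.0)
        ps = forward_project(ph, small_geometry(), psf=PsfModel())
        assert np.all(ps.windows["W2"] == 0)

    def test_hot_voxel_spot_width_matches_psf(self):
        # single hot voxel at the center, no attenuation
        ph = build_jaszczak(default_grid(64, 4.0), spheres=[], background_conc=0.0)
        center = tuple(s // 2 for s in ph.grid.shape)
        ph.activity[center] = 1.0
        psf = PsfModel(fwhm_intrinsic=4.0, fwhm_slope=0.55)
        geom = small_geometry(n_proj=1)
        ps = forward_project(ph, geom, psf=psf)
        proj = ps.windows["W2"][0]
        profile = proj[center[0], :]
        from hospect.metrics import measure_fwhm

        measured = measure_fwhm(profile, pixel_size_mm=4.0)
        # the voxel sits at the orbit-radius distance minus zero offset
        expected = psf.fwhm_at(geom.orbit_radius / 10.0)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_counts_conserved_across_angles_without_attenuation(self):
        ph = build_jaszczak(default_grid(64, 4.0), jaszczak_sphere_set())
        geom = small_geometry(n_proj=12)
        ps = forward_project(ph, geom, psf=None, mu=None, sensitivity=100.0)
        totals = ps.windows["W2"].sum(axis=(1, 2))
        expected = ph.total_activity_MBq * 100.0 * geom.time_per_projection
        np.testing.assert_allclose(totals, expected, rtol=1e-6)

    def test_mismatched_detector_rejected(self):
        ph = build_jaszczak(default_grid(64, 4.0), spheres=[])
        with pytest.raises(ValueError, match="detector"):
            forward_project(ph, small_geometry(n=32))


@pytest.fixture(scope="module")
def primary():
    ph = build_jaszczak(default_grid(64, 4.0), jaszczak_sphere_set())
    return forward_project(ph, small_geometry(n_proj=4), psf=PsfModel(), mu=ph.mu)


class TestSynthesizeAcquisition:

    def test_photopeak_only_model_gives_poisson_w2_and_empty_side_windows(self, primary):
        kernels = ScatterKernels(photopeak_self_scatter_fraction=0.0)
        acq = synthesize_acquisition(
            primary, SpectrumComponentModel.photopeak_only(), kernels=kernels, seed=3
        )
        for w in ("W1", "W3", "W4"):
            assert np.all(acq.windows[w] == 0)
        expectation = primary.windows["W2"] * 2.0 ** (
            -primary.geometry.projection_start_hours() / 26.8
        ).reshape(-1, 1, 1)
        total = acq.windows["W2"].sum()
        assert total == pytest.approx(expectation.sum(), rel=1e-3)  # Poisson at ~4e6

    def test_whole_stack_tallies_reproduce_window_fractions(self, primary):
        acq = synthesize_acquisition(primary, SpectrumComponentModel.default(), seed=11)
        model = SpectrumComponentModel.default()
        for w in ("W1", "W2", "W4"):
            tallies = acq.component_tallies[w]
            n = sum(tallies.values())
            for i, c in enumerate(COMPONENTS):
                p = model.per_window_fraction[w][i]
                sigma = np.sqrt(max(p * (1 - p) / n, 1e-18))
                assert abs(tallies[c] / n - p) < max(4 * sigma, 2e-3)

    def test_poisson_mean_variance_on_flat_field(self):
        geom = AcquisitionGeometry(n_projections=1, detector_matrix=(64, 64), pixel_size=4.0)
        from hospect.simulate import ProjectionSet

        flat = np.full((1, 64, 64), 400.0)
        primary = ProjectionSet(windows={"W2": flat}, geometry=geom, psf=PsfModel())
        kernels = ScatterKernels(photopeak_self_scatter_fraction=0.0)
        acq = synthesize_acquisition(
            primary, SpectrumComponentModel.photopeak_only(), kernels=kernels, seed=5
        )
        w2 = acq.windows["W2"]
        assert w2.var() == pytest.approx(w2.mean(), rel=0.05)

    def test_tallies_sum_to_total_counts_exactly(self, primary):
        acq = synthesize_acquisition(primary, SpectrumComponentModel.default(), seed=21)
        tally_total = sum(sum(t.values()) for t in acq.component_tallies.values())
        count_total = sum(int(acq.windows[w].sum()) for w in acq.windows)
        assert tally_total == count_total

    def test_seed_reproducibility_bitwise(self, primary):
        a = synthesize_acquisition(primary, SpectrumComponentModel.default(), seed=42)
        b = synthesize_acquisition(primary, SpectrumComponentModel.default(), seed=42)
        for w in a.windows:
            np.testing.assert_array_equal(a.windows[w], b.windows[w])

    def test_expected_totals_scale_with_time_and_activity(self):
        from hospect.phantom import DecayParams

        ph = build_jaszczak(default_grid(64, 4.0), jaszczak_sphere_set())
        ph2 = build_jaszczak(
            default_grid(64, 4.0),
            jaszczak_sphere_set(sphere_conc=2 * 29.0 / 31.53),
            background_conc=2 * 312.0 / 6200.0,
        )
        g1 = small_geometry(n_proj=2)
        g2 = dataclasses.replace(g1, time_per_projection=60.0)
        no_decay = DecayParams(half_life=1e15)
        e1 = synthesize_acquisition(
            forward_project(ph, g1, psf=PsfModel(), mu=ph.mu),
            noise=False, decay_params=no_decay,
        )
        # doubled time per projection, decay frozen to isolate the time scaling
        e_time = synthesize_acquisition(
            forward_project(ph, g2, psf=PsfModel(), mu=ph.mu),
            noise=False, decay_params=no_decay,
        )
        # doubled activity everywhere at the original schedule
        e_act = synthesize_acquisition(
            forward_project(ph2, g1, psf=PsfModel(), mu=ph2.mu),
            noise=False, decay_params=no_decay,
        )
        for w in e1.windows:
            np.testing.assert_allclose(e_time.windows[w], 2.0 * e1.windows[w], rtol=1e-9)
            np.testing.assert_allclose(e_act.windows[w], 2.0 * e1.windows[w], rtol=1e-9)

    def test_oversized_kernel_rejected(self, primary):
        with pytest.raises(ValueError, match="kernel"):
            synthesize_acquisition(
                primary, kernels=ScatterKernels(high_energy_fwhm_factor=100.0), seed=0
            )
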