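"""Difference-series construction and two-band decomposition."""

import numpy as np
import pytest

from uvkit.decomposition import (
    IrradiationSeries,
    compute_difference_series,
    decompose_difference,
    detect_photoconversion,
    fit_visible_component,
    photoreversibility_index,
)
from uvkit.errors import DomainError, GridMismatchError
from uvkit.simulate import SpectraSimConfig, simulate_irradiation_series
from uvkit.spectra import (
    AbsorbanceSpectrum,
    difference_spectrum,
    gaussian_band,
    pigment_template,
)


class TestDifferenceSeries:
    def test_count_and_sign_convention(self, default_series):
        series, truth = default_series
        diffs = compute_difference_series(series)
        assert len(diffs) == len(series) - 1
        # dark -> UV: earlier-minus-later leaves a positive UV lobe and a
        # negative visible lobe
        d0 = diffs[0]
        uv_region = (d0.wavelengths >= 330) & (d0.wavelengths <= 390)
        vis_region = (d0.wavelengths >= 440) & (d0.wavelengths <= 490)
        assert d0.absorbance[uv_region].mean() > 0
        assert d0.absorbance[vis_region].mean() < 0

    def test_identical_states_give_zero(self, nm_grid):
        s = gaussian_band(360.0, 35.0, 0.5, nm_grid).with_label("dark")
        series = IrradiationSeries((s, s.with_label("uv"), s.with_label("y")))
        for d in compute_difference_series(series):
            assert np.all(d.absorbance == 0.0)

    def test_differences_match_known_mixtures(self):
        # noiseless simulator states are exact affine combinations, so the
        # dark-minus-UV difference equals the signed component mixture
        cfg = SpectraSimConfig(seed=0, noise_sd=0.0)
        series, truth = simulate_irradiation_series(cfg)
        diffs = compute_difference_series(series)
        uv = np.array(truth["uv_component"])
        vis = np.array(truth["visible_component"])
        f = truth["fractions"]
        expected = (f["dark"] - f["uv_1"]) * (uv - vis)
        np.testing.assert_allclose(diffs[0].absorbance, expected, atol=1e-12)

    def test_too_few_states_rejected(self, nm_grid):
        with pytest.raises(DomainError):
            IrradiationSeries((gaussian_band(360.0, 35.0, 0.5, nm_grid),))


class TestFitVisibleComponent:
    def test_self_consistency_on_model_family(self, nm_grid):
        target = pigment_template(462.0, nm_grid)
        diff = AbsorbanceSpectrum(nm_grid, 0.01 * target.absorbance)
        band = fit_visible_component(diff)
        assert band.lambda_max == pytest.approx(462.0, abs=0.5)
        assert band.sign * band.amplitude == pytest.approx(0.01, abs=1e-4)

    def test_recovery_under_noise(self, nm_grid):
        target = pigment_template(462.0, nm_grid).absorbance * 0.01
        rng = np.random.default_rng(11)
        for _ in range(100):
            noisy = AbsorbanceSpectrum(
                nm_grid, target + rng.normal(0, 2e-4, nm_grid.size)
            )
            band = fit_visible_component(noisy)
            assert abs(band.lambda_max - 462.0) <= 2.0

    def test_negative_lobe_sign_flag(self, nm_grid):
        diff = AbsorbanceSpectrum(
            nm_grid, -0.02 * pigment_template(462.0, nm_grid).absorbance
        )
        band = fit_visible_component(diff)
        assert band.sign == -1
        assert band.amplitude == pytest.approx(0.02, abs=1e-4)

    def test_narrow_uv_band_invisible_to_window(self, nm_grid):
        # a narrow UV Gaussian leaves almost nothing inside 420-560 nm, so
        # the template fit captures < 1% of its peak (broad sigma ~35 bands
        # DO leak, which is why decompose_difference alternates the fits)
        diff = gaussian_band(360.0, 20.0, 1.0, nm_grid)
        band = fit_visible_component(diff)
        assert band.amplitude < 0.01


class TestDecomposeDifference:
    def test_parameter_recovery_on_synthetic_mixture(self, nm_grid):
        rng = np.random.default_rng(42)
        clean = (
            0.8 * pigment_template(462.0, nm_grid).absorbance
            - gaussian_band(360.0, 35.0, 1.0, nm_grid).absorbance
        )
        diff = AbsorbanceSpectrum(nm_grid, clean + rng.normal(0, 0.005, nm_grid.size))
        res = decompose_difference(diff)
        assert res.visible_band.lambda_max == pytest.approx(462.0, abs=2.0)
        assert res.uv_band.lambda_max == pytest.approx(360.0, abs=3.0)
        assert res.visible_band.sign == 1
        assert res.uv_band.sign == -1

    def test_noiseless_single_band(self, nm_grid):
        diff = AbsorbanceSpectrum(
            nm_grid, 0.5 * pigment_template(480.0, nm_grid).absorbance
        )
        res = decompose_difference(diff)
        assert res.uv_band.amplitude < 1e-3
        assert res.residual_rms < 1e-3

    def test_amplitude_ratio_matches_mixture(self):
        # recovered band amplitudes reproduce the simulated mixture within 5%
        cfg = SpectraSimConfig(seed=3)
        series, truth = simulate_irradiation_series(cfg)
        res = decompose_difference(compute_difference_series(series)[0])
        df = truth["fractions"]["dark"] - truth["fractions"]["uv_1"]
        assert res.uv_band.amplitude == pytest.approx(
            df * truth["uv_band"]["amplitude"], rel=0.05
        )
        assert res.visible_band.amplitude == pytest.approx(
            df * truth["visible_band"]["amplitude"], rel=0.05
        )

    def test_normalized_visible_component_peaks_at_one(self, default_series):
        series, _ = default_series
        res = decompose_difference(compute_difference_series(series)[0])
        vis, uv = res.normalized_components
        assert vis.absorbance.max() == pytest.approx(1.0, abs=1e-6)
        # UV form absorbs more strongly than the visible form here
        assert uv.absorbance.max() > 1.0

    def test_ordering_invariant(self, default_series):
        series, _ = default_series
        res = decompose_difference(compute_difference_series(series)[0])
        assert res.visible_band.lambda_max > res.uv_band.lambda_max
        assert res.residual_rms >= 0


class TestDetectPhotoconversion:
    def test_null_pair_not_detected(self, nm_grid):
        rng = np.random.default_rng(5)
        base = gaussian_band(360.0, 35.0, 0.5, nm_grid).absorbance
        sd = 0.002
        a = AbsorbanceSpectrum(nm_grid, base + rng.normal(0, sd, nm_grid.size))
        b = AbsorbanceSpectrum(nm_grid, base + rng.normal(0, sd, nm_grid.size))
        detected, _ = detect_photoconversion(a, b, noise_sd=np.sqrt(2) * sd)
        assert not detected

    def test_constructed_exceedance_detected(self, nm_grid):
        sd = 0.002
        base = gaussian_band(360.0, 35.0, 0.5, nm_grid)
        bumped = AbsorbanceSpectrum(
            nm_grid,
            base.absorbance
            + 10 * sd * pigment_template(460.0, nm_grid).absorbance,
        )
        detected, max_abs = detect_photoconversion(base, bumped, noise_sd=sd)
        assert detected
        assert max_abs >= 10 * sd * 0.99

    def test_false_positive_rate_at_k5(self, nm_grid):
        # pure-noise pairs: <= 1% of 500 seeded trials may exceed 5 sigma
        rng = np.random.default_rng(123)
        sd = 0.002
        base = gaussian_band(360.0, 35.0, 0.5, nm_grid).absorbance
        hits = 0
        for _ in range(500):
            a = AbsorbanceSpectrum(nm_grid, base + rng.normal(0, sd, nm_grid.size))
            b = AbsorbanceSpectrum(nm_grid, base + rng.normal(0, sd, nm_grid.size))
            det, _ = detect_photoconversion(a, b, noise_sd=np.sqrt(2) * sd, k=5.0)
            hits += det
        assert hits <= 5


class TestPhotoreversibilityIndex:
    def test_scale_invariance(self, nm_grid):
        s = gaussian_band(360.0, 35.0, 0.5, nm_grid)
        doubled = AbsorbanceSpectrum(nm_grid, 2.0 * s.absorbance)
        assert photoreversibility_index(s, doubled) == pytest.approx(0.0, abs=1e-12)

    def test_shape_change_detected(self, nm_grid):
        s = gaussian_band(360.0, 35.0, 0.5, nm_grid)
        changed = AbsorbanceSpectrum(
            nm_grid,
            s.absorbance
            + 0.5 * s.absorbance.max() * pigment_template(462.0, nm_grid).absorbance,
        )
        assert photoreversibility_index(s, changed) > 0.02

    def test_full_reversion_below_threshold(self):
        # dark state vs dark-after-complete-reversion differ only by noise
        cfg = SpectraSimConfig(
            seed=9,
            fractions=(("dark", 1.0), ("uv_1", 0.1), ("yellow_1", 1.0)),
        )
        series, _ = simulate_irradiation_series(cfg)
        assert photoreversibility_index(series.states[0], series.states[2]) < 0.02

    def test_grid_mismatch_rejected(self, nm_grid):
        a = gaussian_band(360.0, 35.0, 0.5, nm_grid)
        b = gaussian_band(360.0, 35.0, 0.5, nm_grid[:-5])
        with pytest.raises(GridMismatchError):
            photoreversibility_index(a, b)
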