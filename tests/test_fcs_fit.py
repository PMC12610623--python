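"""Model fitting, repeat averaging and the fit -> D -> RH chain."""

import numpy as np
import pytest

from rnptrack.errors import FitError, ValidationError
from rnptrack.fcs import (
    CorrelationCurve,
    FCSModelParams,
    FitConfig,
    FitResult,
    FocalVolumeCalibration,
    SolventConditions,
    analyze_sample,
    fit_curve,
    mean_diffusion_time,
    model_correlation,
)

TRUE = FCSModelParams(n_molecules=5.0, t_d1=5e-5, t_d2=1e-3, fraction_1=0.3,
                      aspect_ratio=5.0, triplet_amplitude=0.15,
                      triplet_lifetime=5e-6, baseline=0.0)
FIXED = {"t_d1": 5e-5, "aspect_ratio": 5.0, "baseline": 0.0}
FREE = ("n_molecules", "t_d2", "fraction_1", "triplet_amplitude",
        "triplet_lifetime")
LAGS = np.logspace(-6, -1, 64)


def noiseless_curve() -> CorrelationCurve:
    return CorrelationCurve(lags=LAGS, values=model_correlation(TRUE, LAGS))


class TestFitCurve:
    def test_noiseless_recovery_to_numerical_precision(self):
        result = fit_curve(noiseless_curve(), FitConfig(fixed_parameters=FIXED))
        assert result.converged
        assert result.reduced_chi_square < 1e-8
        for name in FREE:
            fitted = getattr(result.params, name)
            truth = getattr(TRUE, name)
            assert abs(fitted - truth) / truth < 1e-4, name

    def test_noisy_recovery_single_seed(self):
        g = model_correlation(TRUE, LAGS)
        rng = np.random.default_rng(1)
        noisy = CorrelationCurve(
            lags=LAGS, values=g + rng.normal(0.0, 0.005 * g[0], g.size))
        result = fit_curve(noisy, FitConfig(fixed_parameters=FIXED, seed=1))
        assert result.converged
        for name in FREE:
            fitted = getattr(result.params, name)
            truth = getattr(TRUE, name)
            assert abs(fitted - truth) / truth < 0.30, name

    def test_median_recovery_over_twenty_noisy_curves(self):
        """At 0.5% noise the median relative error of every free parameter
        stays below 10% over a fixed seed set."""
        g = model_correlation(TRUE, LAGS)
        errors = {name: [] for name in FREE}
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            noisy = CorrelationCurve(
                lags=LAGS, values=g + rng.normal(0.0, 0.005 * g[0], g.size))
            result = fit_curve(noisy,
                               FitConfig(fixed_parameters=FIXED, seed=seed))
            for name in FREE:
                truth = getattr(TRUE, name)
                errors[name].append(
                    abs(getattr(result.params, name) - truth) / truth)
        for name, errs in errors.items():
            assert np.median(errs) < 0.10, name

    def test_single_component_data_pushes_fraction_to_boundary(self):
        """Fitting two components to one-component data collapses: R at a
        boundary or the two diffusion times degenerate, and the fit is at
        least as good as a coarse grid search."""
        single = FCSModelParams(n_molecules=2.0, t_d1=1e-3, t_d2=1e-3,
                                fraction_1=1.0, aspect_ratio=5.0)
        curve = CorrelationCurve(lags=LAGS,
                                 values=model_correlation(single, LAGS))
        result = fit_curve(
            curve,
            FitConfig(fixed_parameters={"aspect_ratio": 5.0, "baseline": 0.0,
                                        "triplet_amplitude": 0.0,
                                        "triplet_lifetime": 1e-6}))
        p = result.params
        collapsed = (
            p.fraction_1 < 0.05 or p.fraction_1 > 0.95
            or abs(p.t_d1 - p.t_d2) / p.t_d2 < 0.05
        )
        assert collapsed
        # coarse grid-search oracle over (N, tD, R)
        best_grid = np.inf
        for n in (1.0, 2.0, 4.0):
            for td in (3e-4, 1e-3, 3e-3):
                for r in (0.0, 0.5, 1.0):
                    trial = FCSModelParams(n_molecules=n, t_d1=td, t_d2=td,
                                           fraction_1=r, aspect_ratio=5.0)
                    resid = curve.values - model_correlation(trial, LAGS)
                    best_grid = min(best_grid, float(resid @ resid))
        dof = len(curve) - 4
        assert result.reduced_chi_square <= best_grid / dof + 1e-12

    def test_lag_rescaling_invariance(self):
        """Rescaling lags to ms units (with fixed times rescaled) rescales
        the fitted diffusion time by the same factor."""
        scale = 1e3
        base = fit_curve(noiseless_curve(), FitConfig(fixed_parameters=FIXED))
        scaled_curve = CorrelationCurve(lags=LAGS * scale,
                                        values=noiseless_curve().values)
        scaled_fixed = dict(FIXED)
        scaled_fixed["t_d1"] = FIXED["t_d1"] * scale
        scaled = fit_curve(scaled_curve,
                           FitConfig(fixed_parameters=scaled_fixed))
        assert scaled.params.t_d2 / base.params.t_d2 == pytest.approx(
            scale, rel=1e-6)
        assert scaled.params.n_molecules == pytest.approx(
            base.params.n_molecules, rel=1e-6)

    def test_deterministic_given_seed(self):
        g = model_correlation(TRUE, LAGS)
        rng = np.random.default_rng(5)
        noisy = CorrelationCurve(
            lags=LAGS, values=g + rng.normal(0.0, 0.01 * g[0], g.size))
        config = FitConfig(fixed_parameters=FIXED, seed=42)
        a = fit_curve(noisy, config)
        b = fit_curve(noisy, config)
        assert a.params == b.params

    def test_sigma_weighting_uses_curve_errors(self):
        g = model_correlation(TRUE, LAGS)
        sigma = np.full(g.size, 0.01)
        curve = CorrelationCurve(lags=LAGS, values=g, sigma=sigma)
        result = fit_curve(curve, FitConfig(fixed_parameters=FIXED,
                                            weighting="sigma"))
        assert result.converged
        assert result.params.t_d2 == pytest.approx(TRUE.t_d2, rel=1e-4)

    def test_degenerate_curve_rejected(self):
        flat = CorrelationCurve(lags=LAGS, values=np.ones_like(LAGS))
        with pytest.raises(FitError):
            fit_curve(flat, FitConfig())

    def test_component_ordering_convention(self):
        """With both diffusion times free the fast component is labeled 1."""
        curve = noiseless_curve()
        result = fit_curve(
            curve,
            FitConfig(fixed_parameters={"aspect_ratio": 5.0, "baseline": 0.0},
                      initial_values={"t_d1": 2e-3, "t_d2": 4e-5}))
        assert result.params.t_d1 <= result.params.t_d2


class TestMeanDiffusionTime:
    def _result(self, t_d2):
        params = FCSModelParams(n_molecules=1.0, t_d1=1e-5, t_d2=t_d2)
        return FitResult(params=params, stderr={}, reduced_chi_square=0.0,
                         converged=True, n_points=64)

    def test_mean_and_standard_error(self):
        results = [self._result(t) for t in (500e-6, 525e-6, 550e-6)]
        out = mean_diffusion_time(results, component=2)
        assert out.mean == pytest.approx(525e-6)
        assert out.standard_error == pytest.approx(25e-6 / np.sqrt(3),
                                                   rel=1e-12)

    def test_single_result_flagged(self):
        out = mean_diffusion_time([self._result(500e-6)], component=2)
        assert out.mean == pytest.approx(500e-6)
        assert out.standard_error == 0.0
        assert out.single_measurement

    def test_identical_repeats_zero_error(self):
        out = mean_diffusion_time([self._result(1e-3)] * 4, component=2)
        assert out.standard_error == 0.0
        assert not out.single_measurement

    def test_all_unconverged_rejected(self):
        bad = FitResult(params=TRUE, stderr={}, reduced_chi_square=1.0,
                        converged=False, n_points=10)
        with pytest.raises(ValidationError):
            mean_diffusion_time([bad], component=2)


class TestAnalyzeSample:
    @pytest.mark.parametrize("ref_D,ref_td,target_D,expected_nm,tol_nm", [
        (4.3e-10, 525e-6, 0.207e-10, 11.9, 0.05),
        (3.6e-10, 271e-6, 0.111e-10, 22.0, 0.5),
    ])
    def test_table_reconstruction(self, ref_D, ref_td, target_D, expected_nm,
                                  tol_nm):
        """End-to-end: a curve whose slow component matches a measured D
        reproduces the printed hydrodynamic radius."""
        cal = FocalVolumeCalibration.from_reference(ref_D, ref_td)
        t_d2 = cal.beam_waist**2 / (4.0 * target_D)
        params = FCSModelParams(n_molecules=2.0, t_d1=ref_td, t_d2=t_d2,
                                fraction_1=0.4, aspect_ratio=5.0)
        curve = CorrelationCurve(
            lags=np.logspace(-6, 1, 96),
            values=model_correlation(params, np.logspace(-6, 1, 96)))
        props = analyze_sample(
            curve,
            FitConfig(fixed_parameters={"t_d1": ref_td, "aspect_ratio": 5.0,
                                        "baseline": 0.0,
                                        "triplet_amplitude": 0.0,
                                        "triplet_lifetime": 1e-6}),
            cal, SolventConditions(), component=2)
        assert props.diffusion_coefficient == pytest.approx(target_D, rel=1e-3)
        assert props.hydrodynamic_radius / 1e-9 == pytest.approx(expected_nm,
                                                                 abs=tol_nm)

    def test_calibration_dye_roundtrip(self):
        """Analyzing the reference dye's own curve returns the reference D."""
        cal = FocalVolumeCalibration.from_reference(4.3e-10, 525e-6)
        params = FCSModelParams(n_molecules=1.5, t_d1=525e-6, t_d2=525e-6,
                                fraction_1=1.0, aspect_ratio=5.0)
        lags = np.logspace(-6, 0, 80)
        curve = CorrelationCurve(lags=lags,
                                 values=model_correlation(params, lags))
        props = analyze_sample(
            curve,
            FitConfig(fixed_parameters={"fraction_1": 1.0, "t_d2": 525e-6,
                                        "aspect_ratio": 5.0, "baseline": 0.0,
                                        "triplet_amplitude": 0.0,
                                        "triplet_lifetime": 1e-6}),
            cal, component=1)
        assert props.diffusion_coefficient == pytest.approx(4.3e-10, rel=1e-6)
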