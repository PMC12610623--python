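"""Closed-form FCS model, calibration and Stokes-Einstein conversions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnptrack.errors import ValidationError
from rnptrack.fcs import (
    FCSModelParams,
    FocalVolumeCalibration,
    SolventConditions,
    beam_waist_from_reference,
    diffusion_from_time,
    focal_volume,
    hydrodynamic_radius,
    model_correlation,
)


class TestModelCorrelation:
    def test_zero_lag_amplitude_is_inverse_occupancy(self):
        p = FCSModelParams(n_molecules=1.0, t_d1=1e-4, t_d2=1e-3,
                           fraction_1=1.0, triplet_amplitude=0.0, baseline=0.0)
        assert model_correlation(p, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_decays_to_baseline_at_long_lag(self):
        p = FCSModelParams(n_molecules=2.0, t_d1=1e-4, t_d2=1e-3,
                           fraction_1=0.4, aspect_ratio=5.0, baseline=0.0)
        lags = np.logspace(-6, 3, 200)
        g = model_correlation(p, lags)
        assert g[-1] < 1e-3 / p.n_molecules
        assert np.all(np.diff(g) < 0)  # monotone decay

    def test_value_at_diffusion_time(self):
        # hand-evaluated: (1/2)*(1/2)*(1.04)^(-1/2)
        p = FCSModelParams(n_molecules=2.0, t_d1=1e-4, t_d2=1e-3,
                           fraction_1=1.0, aspect_ratio=5.0)
        expected = 0.5 * 0.5 * 1.04**-0.5
        assert model_correlation(p, 1e-4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.24514, abs=1e-5)

    def test_vectorizes_preserving_order(self):
        p = FCSModelParams(n_molecules=3.0, t_d1=1e-5, t_d2=1e-3,
                           fraction_1=0.3)
        lags = np.array([1e-3, 1e-6, 1e-4])
        g = model_correlation(p, lags)
        assert g.shape == (3,)
        assert [model_correlation(p, t) for t in lags] == pytest.approx(list(g))

    def test_component_collapse_identity(self):
        """R = 1 reduces exactly to the single-component model at all lags."""
        lags = np.logspace(-7, 0, 50)
        two = FCSModelParams(n_molecules=4.0, t_d1=2e-4, t_d2=9e-3,
                             fraction_1=1.0, aspect_ratio=6.0,
                             triplet_amplitude=0.2, triplet_lifetime=3e-6,
                             baseline=0.01)
        one = FCSModelParams(n_molecules=4.0, t_d1=2e-4, t_d2=2e-4,
                             fraction_1=0.5, aspect_ratio=6.0,
                             triplet_amplitude=0.2, triplet_lifetime=3e-6,
                             baseline=0.01)
        np.testing.assert_allclose(model_correlation(two, lags),
                                   model_correlation(one, lags), rtol=1e-14)

    @given(st.floats(min_value=-1e3, max_value=1e3,
                     allow_nan=False, allow_infinity=False))
    def test_rejects_negative_or_nonfinite_lag(self, lag):
        p = FCSModelParams(n_molecules=1.0, t_d1=1e-4, t_d2=1e-3)
        if lag < 0:
            with pytest.raises(ValidationError):
                model_correlation(p, lag)
        else:
            assert math.isfinite(model_correlation(p, lag))

    @pytest.mark.parametrize("field,value", [
        ("n_molecules", 0.0), ("n_molecules", float("nan")),
        ("t_d1", -1e-4), ("fraction_1", 1.5), ("aspect_ratio", 0.5),
        ("triplet_amplitude", -0.1), ("triplet_lifetime", 0.0),
    ])
    def test_invalid_parameters_name_the_field(self, field, value):
        kwargs = dict(n_molecules=1.0, t_d1=1e-4, t_d2=1e-3)
        kwargs[field] = value
        with pytest.raises(ValidationError, match=field):
            FCSModelParams(**kwargs)

    def test_params_dict_roundtrip(self):
        p = FCSModelParams(n_molecules=2.5, t_d1=3e-5, t_d2=2e-3,
                           fraction_1=0.7, aspect_ratio=4.0,
                           triplet_amplitude=0.1, triplet_lifetime=2e-6,
                           baseline=-0.001)
        assert FCSModelParams.from_dict(p.to_dict()) == p


class TestCalibration:
    @pytest.mark.parametrize("D,td,expected_um", [
        (4.3e-10, 525e-6, 0.95),   # green-channel reference dye
        (3.6e-10, 271e-6, 0.62),   # red-channel reference dye
        (0.25, 1.0, 1.0e6),        # sqrt(4*0.25*1) in arbitrary units
    ])
    def test_beam_waist_from_reference(self, D, td, expected_um):
        assert beam_waist_from_reference(D, td) / 1e-6 == pytest.approx(
            expected_um, abs=0.005 if expected_um < 10 else 1e-6)

    def test_roundtrip_identity_on_reference(self):
        cal = FocalVolumeCalibration.from_reference(3.6e-10, 271e-6)
        D = diffusion_from_time(cal.reference_diffusion_time, cal)
        assert D == pytest.approx(cal.reference_diffusion_coefficient,
                                  rel=1e-14)

    def test_diffusion_scales_inversely_with_time(self):
        cal = FocalVolumeCalibration.from_reference(3.6e-10, 271e-6)
        # ten times the reference diffusion time -> one tenth the coefficient
        assert diffusion_from_time(2.71e-3, cal) == pytest.approx(
            3.6e-11, rel=1e-12)

    def test_micron_waist_quarter_second(self):
        cal = FocalVolumeCalibration(
            reference_diffusion_coefficient=1e-12,
            reference_diffusion_time=0.25,
            beam_waist=1e-6,
        )
        assert diffusion_from_time(0.25, cal) == pytest.approx(1e-12, rel=1e-12)

    def test_inconsistent_waist_rejected(self):
        with pytest.raises(ValidationError):
            FocalVolumeCalibration(
                reference_diffusion_coefficient=4.3e-10,
                reference_diffusion_time=525e-6,
                beam_waist=1e-6,
            )

    def test_focal_volume_formula(self):
        # pi^(3/2) * Wxy^3 * omega
        assert focal_volume(1e-6, 5.0) == pytest.approx(
            math.pi**1.5 * 5e-18, rel=1e-14)


class TestStokesEinstein:
    @pytest.mark.parametrize("D_1e10,expected_nm,tol_nm", [
        (0.207, 11.9, 0.05),  # monomeric protein in cell medium
        (0.111, 22.0, 0.5),   # aggregated protein in HEPES buffer
    ])
    def test_printed_radii_recomputed(self, D_1e10, expected_nm, tol_nm):
        rh = hydrodynamic_radius(D_1e10 * 1e-10)
        assert rh / 1e-9 == pytest.approx(expected_nm, abs=tol_nm)

    def test_inverse_proportionality(self):
        cond = SolventConditions()
        assert hydrodynamic_radius(0.5e-10, cond) == pytest.approx(
            2.0 * hydrodynamic_radius(1e-10, cond), rel=1e-14)

    @given(st.floats(min_value=1e-13, max_value=1e-8))
    def test_stokes_einstein_product_constant(self, D):
        cond = SolventConditions(temperature=300.0, viscosity=1e-3)
        product = hydrodynamic_radius(D, cond) * D
        ref = hydrodynamic_radius(1e-10, cond) * 1e-10
        assert product == pytest.approx(ref, rel=1e-12)

    def test_rejects_nonpositive_diffusion(self):
        with pytest.raises(ValidationError):
            hydrodynamic_radius(0.0)
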