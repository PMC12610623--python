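"""Closed-form FCS correlation model and the physical conversions around it.

The model describes the normalized fluorescence fluctuation autocorrelation of
two freely diffusing species crossing a 3D Gaussian confocal volume, with an
optional fast exponential (triplet-blinking) factor and a constant baseline:

    G(t) = (1/N) * [ R * g(t; tD1) + (1 - R) * g(t; tD2) ]
                 * (1 + AT * exp(-t / tT)) + b0

    g(t; tD) = (1 + t/tD)^-1 * (1 + t/(omega^2 * tD))^-1/2

where ``N`` is the mean number of molecules in the effective focal volume,
``tD1``/``tD2`` are the diffusion correlation times of the two species with
fractional weight ``R``, ``omega`` is the axial/radial aspect ratio of the
focal volume, ``AT``/``tT`` the triplet amplitude and lifetime and ``b0`` the
long-lag baseline.  The triplet factor multiplies the whole two-component sum
(no ``1 - AT`` renormalization).

Calibration against a reference dye of known diffusion coefficient converts
fitted diffusion times to physical quantities through

    D = Wxy^2 / (4 * tD)          (beam-waist calibration)
    RH = kB * T / (6 * pi * eta * D)   (Stokes-Einstein)

with ``Wxy`` the radial 1/e^2 radius of the focal volume.  All quantities are
SI internally (seconds, meters, kelvin, pascal-seconds); unit conversion to
the customary um/nm/cP happens only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from rnptrack.errors import ValidationError

#: Boltzmann constant, J/K (CODATA 2018 exact value).
BOLTZMANN_CONSTANT = 1.380649e-23

#: Default solvent conditions: water at 25 C.
DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_VISCOSITY = 0.89e-3  # Pa s  (0.89 cP)

__all__ = [
    "BOLTZMANN_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_VISCOSITY",
    "FCSModelParams",
    "SolventConditions",
    "FocalVolumeCalibration",
    "DiffusionProperties",
    "model_correlation",
    "beam_waist_from_reference",
    "diffusion_from_time",
    "hydrodynamic_radius",
    "focal_volume",
]


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def _check_positive(name: str, value: float) -> float:
    value = _check_finite(name, value)
    if value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value!r}")
    return value


@dataclass(frozen=True)
class FCSModelParams:
    """Full parameter set of the two-component + triplet correlation model.

    Parameters
    ----------
    n_molecules
        Mean occupancy N of the effective focal volume (dimensionless, > 0).
    t_d1, t_d2
        Diffusion correlation times of components 1 and 2 in seconds (> 0).
        Convention: component 1 is the fast one (t_d1 <= t_d2) after fitting.
    fraction_1
        Weight R of component 1, in [0, 1].
    aspect_ratio
        Axial/radial extent omega of the focal volume (>= 1).
    triplet_amplitude, triplet_lifetime
        Amplitude AT (>= 0) and correlation time tT (seconds, > 0) of the
        triplet factor.
    baseline
        Asymptotic value b0 of the curve at long lags.
    """

    n_molecules: float
    t_d1: float
    t_d2: float
    fraction_1: float = 1.0
    aspect_ratio: float = 5.0
    triplet_amplitude: float = 0.0
    triplet_lifetime: float = 1e-6
    baseline: float = 0.0

    def __post_init__(self) -> None:
        _check_positive("n_molecules", self.n_molecules)
        _check_positive("t_d1", self.t_d1)
        _check_positive("t_d2", self.t_d2)
        r = _check_finite("fraction_1", self.fraction_1)
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"fraction_1 must be in [0, 1], got {r!r}")
        omega = _check_finite("aspect_ratio", self.aspect_ratio)
        if omega < 1.0:
            raise ValidationError(f"aspect_ratio must be >= 1, got {omega!r}")
        at = _check_finite("triplet_amplitude", self.triplet_amplitude)
        if at < 0:
            raise ValidationError(f"triplet_amplitude must be >= 0, got {at!r}")
        _check_positive("triplet_lifetime", self.triplet_lifetime)
        _check_finite("baseline", self.baseline)

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form (the serialization the config files use)."""
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "FCSModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class SolventConditions:
    """Temperature (K) and dynamic viscosity (Pa s) of the solvent.

    Defaults correspond to water at 25 C (eta = 0.89 cP).
    """

    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        _check_positive("temperature", self.temperature)
        _check_positive("viscosity", self.viscosity)


@dataclass(frozen=True)
class FocalVolumeCalibration:
    """Focal-volume calibration from a reference dye of known diffusivity.

    ``beam_waist`` is derived from the reference pair so that
    ``beam_waist**2 == 4 * D_ref * tD_ref`` holds exactly by construction;
    prefer :meth:`from_reference` over passing ``beam_waist`` yourself.
    """

    reference_diffusion_coefficient: float  # m^2/s
    reference_diffusion_time: float  # s
    beam_waist: float  # m, radial 1/e^2 radius
    aspect_ratio: float = 5.0

    def __post_init__(self) -> None:
        _check_positive(
            "reference_diffusion_coefficient", self.reference_diffusion_coefficient
        )
        _check_positive("reference_diffusion_time", self.reference_diffusion_time)
        _check_positive("beam_waist", self.beam_waist)
        if self.aspect_ratio < 1.0:
            raise ValidationError(
                f"aspect_ratio must be >= 1, got {self.aspect_ratio!r}"
            )
        expected = 4.0 * self.reference_diffusion_coefficient * (
            self.reference_diffusion_time
        )
        if not math.isclose(self.beam_waist**2, expected, rel_tol=1e-9):
            raise ValidationError(
                "beam_waist inconsistent with reference values: "
                f"beam_waist^2 = {self.beam_waist ** 2:.6e}, "
                f"4*D*tD = {expected:.6e}"
            )

    @classmethod
    def from_reference(
        cls,
        reference_diffusion_coefficient: float,
        reference_diffusion_time: float,
        aspect_ratio: float = 5.0,
    ) -> "FocalVolumeCalibration":
        waist = beam_waist_from_reference(
            reference_diffusion_coefficient, reference_diffusion_time
        )
        return cls(
            reference_diffusion_coefficient=reference_diffusion_coefficient,
            reference_diffusion_time=reference_diffusion_time,
            beam_waist=waist,
            aspect_ratio=aspect_ratio,
        )

    @property
    def focal_volume(self) -> float:
        """Effective focal volume pi^(3/2) * Wxy^2 * (omega * Wxy), m^3."""
        return focal_volume(self.beam_waist, self.aspect_ratio)


@dataclass(frozen=True)
class DiffusionProperties:
    """Diffusion coefficient (m^2/s) and hydrodynamic radius (m) of a sample."""

    diffusion_coefficient: float
    hydrodynamic_radius: float
    conditions: SolventConditions = field(default_factory=SolventConditions)

    def __post_init__(self) -> None:
        _check_positive("diffusion_coefficient", self.diffusion_coefficient)
        _check_positive("hydrodynamic_radius", self.hydrodynamic_radius)


def model_correlation(params: FCSModelParams, lag):
    """Evaluate the two-component + triplet correlation model.

    Parameters
    ----------
    params
        Model parameters (validated on construction).
    lag
        Lag time(s) in seconds, scalar or array-like, all >= 0.

    Returns
    -------
    float or ndarray
        G(lag); an array when ``lag`` is array-like, preserving order.
    """
    t = np.asarray(lag, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("lag must be finite")
    if np.any(t < 0):
        raise ValidationError("lag must be >= 0")

    omega_sq = params.aspect_ratio**2
    r = params.fraction_1

    def g(td: float):
        return (1.0 + t / td) ** -1.0 * (1.0 + t / (omega_sq * td)) ** -0.5

    diff = r * g(params.t_d1) + (1.0 - r) * g(params.t_d2)
    triplet = 1.0 + params.triplet_amplitude * np.exp(-t / params.triplet_lifetime)
    value = diff * triplet / params.n_molecules + params.baseline
    if np.ndim(lag) == 0:
        return float(value)
    return value


def beam_waist_from_reference(reference_D: float, reference_t_d: float) -> float:
    """Radial 1/e^2 beam waist (m) from a reference dye's D and fitted tD.

    Rearranges D = Wxy^2 / (4 tD) to Wxy = sqrt(4 * D * tD).
    """
    _check_positive("reference_D", reference_D)
    _check_positive("reference_t_d", reference_t_d)
    return math.sqrt(4.0 * reference_D * reference_t_d)


def diffusion_from_time(t_d: float, calibration: FocalVolumeCalibration) -> float:
    """Diffusion coefficient (m^2/s) from a fitted diffusion time (s)."""
    _check_positive("t_d", t_d)
    return calibration.beam_waist**2 / (4.0 * t_d)


def hydrodynamic_radius(D: float, conditions: SolventConditions | None = None) -> float:
    """Stokes-Einstein hydrodynamic radius (m) for a diffusion coefficient.

    RH = kB * T / (6 * pi * eta * D).
    """
    _check_positive("D", D)
    if conditions is None:
        conditions = SolventConditions()
    return BOLTZMANN_CONSTANT * conditions.temperature / (
        6.0 * math.pi * conditions.viscosity * D
    )


def focal_volume(beam_waist: float, aspect_ratio: float) -> float:
    """Effective focal volume pi^(3/2) * Wxy^2 * (omega * Wxy) in m^3.

    Only reproducible conditional on the aspect ratio used, which should
    always be reported alongside the value.
    """
    _check_positive("beam_waist", beam_waist)
    if aspect_ratio < 1.0:
        raise ValidationError(f"aspect_ratio must be >= 1, got {aspect_ratio!r}")
    return math.pi**1.5 * beam_waist**3 * aspect_ratio
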