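"""Reagent dosimetry: per-cell doses, BCA calibration, and mass balance.

Small closed-form accounting used around delivery experiments: the effective
reagent dose per cell from applied volume, mass concentration and cell count;
molar-to-mass conversion for RNP components; the linear BCA (bicinchoninic
acid, 562 nm) protein calibration and its inversion; and the bioconjugation
mass balance (bound + unbound = loaded, immobilization efficiency in
percent).

All computation is full precision; rounding to the customary printed
precision (2 significant figures for per-cell doses) is left to
:func:`round_sig` in the reporting layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from rnptrack.errors import ValidationError

__all__ = [
    "CAS9_MW",
    "SGRNA_MW",
    "RNP_MW",
    "DoseSpec",
    "MolarSpec",
    "LinearCalibration",
    "MassBalance",
    "dose_per_cell",
    "mass_from_molar",
    "fit_linear_calibration",
    "concentration_from_absorbance",
    "immobilization_balance",
    "round_sig",
]

#: Default molecular weights (g/mol), overridable everywhere they are used:
#: SpCas9 protein ~160 kDa; a ~100-nt sgRNA ~32 kDa; RNP = 1:1 complex.
CAS9_MW = 160_000.0
SGRNA_MW = 32_000.0
RNP_MW = CAS9_MW + SGRNA_MW


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class DoseSpec:
    """Applied reagent volume (uL), mass concentration (ng/uL), cell count."""

    volume: float
    concentration: float
    cells: float

    def __post_init__(self) -> None:
        _positive("volume", self.volume)
        _positive("concentration", self.concentration)
        _positive("cells", self.cells)


@dataclass(frozen=True)
class MolarSpec:
    """Molar concentration (uM), volume (uL) and molecular weight (g/mol)."""

    concentration: float
    volume: float
    molecular_weight: float

    def __post_init__(self) -> None:
        _positive("concentration", self.concentration)
        _positive("volume", self.volume)
        _positive("molecular_weight", self.molecular_weight)


@dataclass(frozen=True)
class LinearCalibration:
    """Linear standard curve: absorbance = slope * concentration + intercept.

    Slope is absorbance per (ug/mL); ``r_squared`` is the OLS coefficient of
    determination.
    """

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0 or not math.isfinite(self.slope):
            raise ValidationError("slope must be nonzero and finite")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError(f"r_squared must be in [0, 1], got {self.r_squared!r}")


@dataclass(frozen=True)
class MassBalance:
    """Conjugation mass balance in ug; bound + unbound = loaded exactly."""

    loaded: float
    bound: float
    unbound: float
    efficiency: float  # percent

    def __post_init__(self) -> None:
        if self.bound + self.unbound != self.loaded:
            raise ValidationError("mass balance violated: bound + unbound != loaded")


def dose_per_cell(spec: DoseSpec) -> float:
    """Reagent mass per cell, ng: volume * concentration / cells."""
    return spec.volume * spec.concentration / spec.cells


def mass_from_molar(spec: MolarSpec) -> float:
    """Total mass (ng) in a volume of a molar solution.

    concentration [uM = 1e-6 mol/L] * volume [uL = 1e-6 L] * MW [g/mol]
    gives grams * 1e-12; expressed in ng (x 1e9).
    """
    return spec.concentration * 1e-6 * spec.volume * 1e-6 * spec.molecular_weight * 1e9


def fit_linear_calibration(
    standards: Sequence[tuple[float, float]],
) -> LinearCalibration:
    """Ordinary least squares line through (concentration ug/mL, absorbance)."""
    if len(standards) < 2:
        raise ValidationError("need at least 2 standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    absorb = np.array([s[1] for s in standards], dtype=float)
    if np.all(conc == conc[0]):
        raise ValidationError("standards must span at least two concentrations")
    fit = stats.linregress(conc, absorb)
    return LinearCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def concentration_from_absorbance(
    absorbance: float, cal: LinearCalibration
) -> float:
    """Invert the calibration: (absorbance - intercept) / slope, ug/mL.

    A result below zero (absorbance under the blank) is returned as-is with a
    warning rather than raised, since it is a measurement artifact the caller
    may want to inspect.
    """
    conc = (absorbance - cal.intercept) / cal.slope
    if conc < 0:
        warnings.warn(
            f"absorbance {absorbance!r} below the calibration blank: "
            f"concentration {conc:.4g} ug/mL < 0",
            stacklevel=2,
        )
    return conc


def immobilization_balance(loaded: float, bound: float) -> MassBalance:
    """Mass balance of biomolecule immobilization onto a carrier.

    ``efficiency`` is 100 * bound / loaded (percent); ``unbound`` the mass
    left in the supernatant.
    """
    _positive("loaded", loaded)
    if bound < 0:
        raise ValidationError(f"bound must be >= 0, got {bound!r}")
    if bound > loaded:
        raise ValidationError(
            f"bound ({bound}) cannot exceed loaded ({loaded})"
        )
    return MassBalance(
        loaded=loaded,
        bound=bound,
        unbound=loaded - bound,
        efficiency=100.0 * bound / loaded,
    )


def round_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting layer only)."""
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))
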