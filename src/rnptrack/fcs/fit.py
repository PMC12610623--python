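"""Least-squares fitting of the FCS model to correlation curves.

The workhorse is :func:`fit_curve`, a Levenberg-Marquardt fit (via lmfit) of
the two-component + triplet model with per-parameter fixing, bounds and
optional 1/sigma weighting.  Unattended robustness comes from a physically
motivated initialization (N from the first-lag amplitude, the slow diffusion
time from the half-decay lag) and a small number of seeded multi-start
retries with jittered initial values.

:func:`analyze_sample` chains fit -> calibration -> Stokes-Einstein to turn a
measured curve into a diffusion coefficient and hydrodynamic radius, the
derivation path behind reported diffusional-property tables.

Because the second, fast component typically captures free label dye, the
recommended workflow fixes ``t_d1`` to the calibration dye's diffusion time
and reports the slow component (2) as the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import lmfit
import numpy as np

from rnptrack.errors import FitError, ValidationError
from rnptrack.fcs.correlate import CorrelationCurve
from rnptrack.fcs.model import (
    DiffusionProperties,
    FCSModelParams,
    FocalVolumeCalibration,
    SolventConditions,
    diffusion_from_time,
    hydrodynamic_radius,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "MeanDiffusionTime",
    "fit_curve",
    "mean_diffusion_time",
    "analyze_sample",
]

_PARAM_NAMES = (
    "n_molecules",
    "t_d1",
    "t_d2",
    "fraction_1",
    "aspect_ratio",
    "triplet_amplitude",
    "triplet_lifetime",
    "baseline",
)

# Default box constraints; diffusion-time bounds are tightened to the lag
# range of the curve being fit.
_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "n_molecules": (1e-6, 1e9),
    "t_d1": (1e-12, 1e6),
    "t_d2": (1e-12, 1e6),
    "fraction_1": (0.0, 1.0),
    "aspect_ratio": (1.0, 100.0),
    "triplet_amplitude": (0.0, 10.0),
    "triplet_lifetime": (1e-12, 1e6),
    "baseline": (-1e3, 1e3),
}


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a single-curve fit.

    ``fixed_parameters`` maps parameter names to the constant value they are
    held at; everything else is optimized.  ``bounds`` and ``initial_values``
    override the built-in defaults per parameter.  With ``weighting="sigma"``
    residuals are divided by the curve's per-lag standard errors when
    available.  ``seed`` controls the jitter of multi-start retries, making
    the fit deterministic.
    """

    fixed_parameters: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    initial_values: Mapping[str, float] = field(default_factory=dict)
    weighting: str = "none"
    max_iterations: int = 2000
    seed: int = 0
    n_starts: int = 3

    def __post_init__(self) -> None:
        for name in (*self.fixed_parameters, *self.bounds, *self.initial_values):
            if name not in _PARAM_NAMES:
                raise ValidationError(f"unknown model parameter {name!r}")
        if self.weighting not in ("none", "sigma"):
            raise ValidationError("weighting must be 'none' or 'sigma'")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"bounds for {name!r} must satisfy lo < hi")
            init = self.initial_values.get(name)
            if init is not None and not lo <= init <= hi:
                raise ValidationError(
                    f"initial value for {name!r} ({init}) outside bounds ({lo}, {hi})"
                )


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameters with uncertainties and goodness-of-fit."""

    params: FCSModelParams
    stderr: dict[str, float]
    reduced_chi_square: float
    converged: bool
    n_points: int

    def component_time(self, component: int) -> float:
        if component == 1:
            return self.params.t_d1
        if component == 2:
            return self.params.t_d2
        raise ValidationError(f"component must be 1 or 2, got {component!r}")


@dataclass(frozen=True)
class MeanDiffusionTime:
    """Mean diffusion time (s) over repeats with its standard error."""

    mean: float
    standard_error: float
    n: int

    @property
    def single_measurement(self) -> bool:
        """True when the standard error is undefined (only one repeat)."""
        return self.n < 2


def _default_initials(curve: CorrelationCurve) -> dict[str, float]:
    g = curve.values
    lags = curve.lags
    g0 = float(g[0])
    n0 = 1.0 / g0 if g0 > 0 else 1.0
    # lag where G first falls to half its initial value -> slow diffusion time
    half = g0 / 2.0
    below = np.nonzero(g <= half)[0]
    t_half = float(lags[below[0]]) if below.size else float(lags[len(lags) // 2])
    return {
        "n_molecules": max(n0, 1e-6),
        "t_d1": max(t_half / 10.0, float(lags[0])),
        "t_d2": t_half,
        "fraction_1": 0.5,
        "aspect_ratio": 5.0,
        "triplet_amplitude": 0.1,
        "triplet_lifetime": max(float(lags[0]), 1e-7),
        "baseline": 0.0,
    }


def _build_parameters(
    curve: CorrelationCurve, config: FitConfig
) -> tuple[lmfit.Parameters, list[str]]:
    initials = _default_initials(curve)
    initials.update(config.initial_values)
    params = lmfit.Parameters()
    free: list[str] = []
    for name in _PARAM_NAMES:
        lo, hi = config.bounds.get(name, _DEFAULT_BOUNDS[name])
        if name in config.fixed_parameters:
            params.add(name, value=float(config.fixed_parameters[name]), vary=False)
        else:
            value = float(np.clip(initials[name], lo, hi))
            params.add(name, value=value, min=lo, max=hi)
            free.append(name)
    return params, free


def _residual(params: lmfit.Parameters, curve: CorrelationCurve, weights):
    model = _evaluate(params, curve.lags)
    res = curve.values - model
    if weights is not None:
        res = res * weights
    return res


def _evaluate(params: lmfit.Parameters, lags: np.ndarray) -> np.ndarray:
    v = params.valuesdict()
    omega_sq = v["aspect_ratio"] ** 2
    t = lags

    def g(td):
        return (1.0 + t / td) ** -1.0 * (1.0 + t / (omega_sq * td)) ** -0.5

    diff = v["fraction_1"] * g(v["t_d1"]) + (1.0 - v["fraction_1"]) * g(v["t_d2"])
    trip = 1.0 + v["triplet_amplitude"] * np.exp(-t / v["triplet_lifetime"])
    return diff * trip / v["n_molecules"] + v["baseline"]


def _relabel(values: dict, stderr: dict[str, float], fixed: Mapping[str, float]):
    """Enforce t_d1 <= t_d2 by label swapping (and R <-> 1-R).

    Only applied when both diffusion times were free: a user-fixed component
    keeps its label.
    """
    if "t_d1" in fixed or "t_d2" in fixed:
        return values, stderr
    if values["t_d1"] <= values["t_d2"]:
        return values, stderr
    values = dict(values)
    stderr = dict(stderr)
    values["t_d1"], values["t_d2"] = values["t_d2"], values["t_d1"]
    values["fraction_1"] = 1.0 - values["fraction_1"]
    for a, b in (("t_d1", "t_d2"),):
        if a in stderr or b in stderr:
            sa, sb = stderr.get(a, float("nan")), stderr.get(b, float("nan"))
            stderr[a], stderr[b] = sb, sa
    return values, stderr


def fit_curve(curve: CorrelationCurve, config: FitConfig | None = None) -> FitResult:
    """Fit the FCS model to a correlation curve.

    Non-convergence is reported through ``FitResult.converged`` rather than
    an exception; a degenerate (constant) curve raises :class:`FitError`.
    """
    if config is None:
        config = FitConfig()
    if np.allclose(curve.values, curve.values[0]):
        raise FitError("degenerate (constant) curve cannot be fit")

    weights = None
    if config.weighting == "sigma" and curve.sigma is not None:
        sig = np.where(curve.sigma > 0, curve.sigma, np.inf)
        finite = np.isfinite(sig)
        if finite.any():
            # guard zero-sigma points with the smallest positive sigma
            fill = sig[finite].min() if np.isfinite(sig[finite].min()) else 1.0
            sig = np.where(np.isfinite(sig), sig, fill)
            weights = 1.0 / sig

    params, free = _build_parameters(curve, config)
    if len(curve) < len(free):
        raise FitError(
            f"curve has {len(curve)} points but {len(free)} free parameters"
        )

    rng = np.random.default_rng(config.seed)
    best = None
    for attempt in range(max(config.n_starts, 1)):
        trial = params.copy()
        if attempt > 0:  # jittered restart
            for name in free:
                p = trial[name]
                factor = float(np.exp(rng.normal(0.0, 0.5)))
                p.value = float(np.clip(p.value * factor, p.min, p.max))
        try:
            out = lmfit.minimize(
                _residual,
                trial,
                args=(curve, weights),
                method="least_squares",
                max_nfev=config.max_iterations,
            )
        except Exception:  # numerical failure: try the next start
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
        if out.success and out.chisqr < 1e-12:
            break
    if best is None:
        raise FitError("optimizer failed on every start")

    values = dict(best.params.valuesdict())
    stderr = {
        name: (best.params[name].stderr if best.params[name].stderr is not None
               else float("nan"))
        for name in free
    }
    values, stderr = _relabel(values, stderr, config.fixed_parameters)
    n_free = len(free)
    dof = max(len(curve) - n_free, 1)
    return FitResult(
        params=FCSModelParams(**values),
        stderr=stderr,
        reduced_chi_square=float(best.chisqr / dof),
        converged=bool(best.success),
        n_points=len(curve),
    )


def mean_diffusion_time(results: list[FitResult], component: int) -> MeanDiffusionTime:
    """Mean and standard error of one component's diffusion time over repeats.

    Unconverged results are dropped; an empty or all-unconverged list raises.
    For a single repeat the standard error is reported as 0 and flagged via
    :attr:`MeanDiffusionTime.single_measurement`.
    """
    times = [r.component_time(component) for r in results if r.converged]
    if not times:
        raise ValidationError("no converged fit results")
    arr = np.asarray(times)
    if arr.size == 1:
        return MeanDiffusionTime(mean=float(arr[0]), standard_error=0.0, n=1)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return MeanDiffusionTime(mean=float(arr.mean()), standard_error=se, n=int(arr.size))


def analyze_sample(
    curve: CorrelationCurve,
    config: FitConfig,
    calibration: FocalVolumeCalibration,
    conditions: SolventConditions | None = None,
    component: int = 2,
) -> DiffusionProperties:
    """Fit a curve and convert the chosen component to D and RH.

    Composes :func:`fit_curve` -> diffusion_from_time -> hydrodynamic_radius.
    """
    if conditions is None:
        conditions = SolventConditions()
    result = fit_curve(curve, config)
    t_d = result.component_time(component)
    D = diffusion_from_time(t_d, calibration)
    rh = hydrodynamic_radius(D, conditions)
    return DiffusionProperties(
        diffusion_coefficient=D, hydrodynamic_radius=rh, conditions=conditions
    )
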