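"""Synthetic data generators with known ground truth.

Two generators feed the pipeline:

* :func:`simulate_fcs_stream` performs Brownian dynamics of point emitters in
  a periodic box with a 3D Gaussian confocal detection profile and Poisson
  photon statistics, optionally with two-state triplet blinking, producing a
  photon-arrival stream whose correlation curve has an analytically known
  amplitude (1/N_eff) and diffusion time (Wxy^2 / 4D).

* :func:`simulate_two_channel_stack` builds a pair of confocal z-stacks as
  sums of 3D Gaussian blobs with per-blob, per-channel axial peak positions,
  emulating two-color z-stack acquisitions with a prescribed axial offset per
  region of interest.

Both are deterministic given their seed (byte-identical outputs), which is
what makes them usable as oracles in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

from rnptrack.errors import ValidationError
from rnptrack.fcs.correlate import PhotonStream
from rnptrack.fcs.model import focal_volume

__all__ = [
    "TripletKinetics",
    "FCSSimConfig",
    "StackSimConfig",
    "simulate_fcs_stream",
    "simulate_two_channel_stack",
    "expected_count_rate",
    "effective_n",
]

#: Steps simulated per vectorized chunk (bounds peak memory).
_CHUNK_STEPS = 20_000


@dataclass(frozen=True)
class TripletKinetics:
    """Two-state (bright/dark) telegraph blinking kinetics.

    ``off_rate`` is the bright->dark transition rate (1/s) and ``on_rate``
    the dark->bright recovery rate; the dark fraction emits nothing.  The
    equilibrium dark fraction is off_rate / (on_rate + off_rate) and the
    correlation signature decays with lifetime 1 / (on_rate + off_rate).
    """

    on_rate: float
    off_rate: float

    def __post_init__(self) -> None:
        if self.on_rate <= 0 or self.off_rate <= 0:
            raise ValidationError("triplet rates must be > 0")

    @property
    def dark_fraction(self) -> float:
        return self.off_rate / (self.on_rate + self.off_rate)

    @property
    def lifetime(self) -> float:
        return 1.0 / (self.on_rate + self.off_rate)


@dataclass(frozen=True)
class FCSSimConfig:
    """Configuration of a Brownian-dynamics FCS acquisition.

    ``species_counts`` are the particle numbers simulated in the box (rounded
    to integers so that the effective focal occupancy N_eff = count x
    V_eff/V_box is exact); ``brightness`` is the peak photon rate of one
    particle at the focus center, in counts/s.  The box half-widths must be
    at least five focal radii in each direction and the time step must
    resolve the fastest focal transit (dt <= Wxy^2 / (40 max D)).
    ``initial_positions`` (one (x, y, z) per particle, meters) overrides the
    default uniform placement; mainly useful for pinning a particle in tests.
    """

    diffusion_coefficients: Sequence[float]  # m^2/s, per species
    species_counts: Sequence[float]  # particles in the box, per species
    brightness: float  # counts/s per particle at focus center
    beam_waist: float  # m
    aspect_ratio: float = 5.0
    box_half_widths: tuple[float, float, float] | None = None  # m
    time_step: float = 1e-6  # s
    duration: float = 1.0  # s
    background_rate: float = 0.0  # counts/s
    triplet: TripletKinetics | None = None
    initial_positions: Sequence[tuple[float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ds = tuple(float(d) for d in self.diffusion_coefficients)
        ns = tuple(float(n) for n in self.species_counts)
        object.__setattr__(self, "diffusion_coefficients", ds)
        object.__setattr__(self, "species_counts", ns)
        if len(ds) != len(ns) or not ds:
            raise ValidationError(
                "diffusion_coefficients and species_counts must be nonempty "
                "and the same length"
            )
        if any(d < 0 for d in ds):
            raise ValidationError("diffusion coefficients must be >= 0")
        if any(n < 0 for n in ns):
            raise ValidationError("species_counts must be >= 0")
        if self.brightness < 0 or self.background_rate < 0:
            raise ValidationError("rates must be >= 0")
        if self.beam_waist <= 0 or self.aspect_ratio < 1:
            raise ValidationError("beam_waist must be > 0 and aspect_ratio >= 1")
        if self.time_step <= 0 or self.duration <= 0:
            raise ValidationError("time_step and duration must be > 0")
        if self.box_half_widths is None:
            axial = 5.0 * self.aspect_ratio * self.beam_waist
            lateral = 5.0 * self.beam_waist
            object.__setattr__(self, "box_half_widths", (lateral, lateral, axial))
        hw = tuple(float(h) for h in self.box_half_widths)
        object.__setattr__(self, "box_half_widths", hw)
        radii = (self.beam_waist, self.beam_waist,
                 self.aspect_ratio * self.beam_waist)
        for h, r, axis in zip(hw, radii, "xyz"):
            if h < 5.0 * r - 1e-12 * r:
                raise ValidationError(
                    f"box half-width along {axis} ({h:.3g} m) must be at least "
                    f"5x the focal radius ({r:.3g} m)"
                )
        if self.initial_positions is not None:
            pos = tuple(
                (float(x), float(y), float(z))
                for x, y, z in self.initial_positions
            )
            object.__setattr__(self, "initial_positions", pos)
            n_total = sum(int(round(n)) for n in ns)
            if len(pos) != n_total:
                raise ValidationError(
                    f"initial_positions has {len(pos)} entries for "
                    f"{n_total} particles"
                )
            for p in pos:
                for u, h, axis in zip(p, hw, "xyz"):
                    if abs(u) > h:
                        raise ValidationError(
                            f"initial position {u:.3g} outside the box "
                            f"along {axis}"
                        )
        d_max = max(ds)
        if d_max > 0:
            transit = self.beam_waist**2 / (4.0 * d_max)
            if self.time_step > transit / 10.0 * (1.0 + 1e-9):
                raise ValidationError(
                    f"time_step ({self.time_step:.3g} s) must be << the focal "
                    f"transit time ({transit:.3g} s); use <= {transit / 10:.3g} s"
                )

    @property
    def box_volume(self) -> float:
        hx, hy, hz = self.box_half_widths
        return 8.0 * hx * hy * hz


def effective_n(config: FCSSimConfig) -> float:
    """Ground-truth mean focal occupancy N_eff = counts x V_eff / V_box."""
    veff = focal_volume(config.beam_waist, config.aspect_ratio)
    total = sum(round(n) for n in config.species_counts)
    return total * veff / config.box_volume


def expected_count_rate(config: FCSSimConfig) -> float:
    """Analytic mean detected count rate (counts/s) for a configuration.

    Averages the Gaussian detection profile over the box (finite-box erf
    integral, exact) and accounts for the triplet equilibrium bright
    fraction.
    """
    w = config.beam_waist
    wz = config.aspect_ratio * w

    def axis_mean(half: float, waist: float) -> float:
        # mean over [-L, L] of exp(-2 u^2 / waist^2)
        return (waist * math.sqrt(math.pi / 2.0) / (2.0 * half)) * erf(
            math.sqrt(2.0) * half / waist
        )

    hx, hy, hz = config.box_half_widths
    mean_profile = axis_mean(hx, w) * axis_mean(hy, w) * axis_mean(hz, wz)
    bright = 1.0
    if config.triplet is not None:
        bright = 1.0 - config.triplet.dark_fraction
    total = sum(round(n) for n in config.species_counts)
    return config.background_rate + config.brightness * bright * total * mean_profile


def _telegraph_switch_times(
    rng: np.random.Generator, kin: TripletKinetics, duration: float
) -> tuple[bool, np.ndarray]:
    """Sample one particle's blink history over [0, duration].

    Returns the initial state (True = bright, drawn from equilibrium) and the
    sorted switch times; the state flips at each switch.  Sojourns are exact
    exponentials with the state-dependent rate.
    """
    bright = bool(rng.random() >= kin.dark_fraction)
    times = []
    t = 0.0
    state = bright
    mean_switches = duration * (kin.on_rate + kin.off_rate) / 2.0
    # draw in blocks to amortize RNG calls
    block = max(int(mean_switches * 1.5) + 16, 16)
    while t < duration:
        draws = rng.exponential(1.0, size=block)
        for u in draws:
            rate = kin.off_rate if state else kin.on_rate
            t += u / rate
            if t >= duration:
                break
            times.append(t)
            state = not state
        else:
            continue
        break
    return bright, np.asarray(times)


def _bright_mask(
    initial_bright: bool, switches: np.ndarray, step_times: np.ndarray
) -> np.ndarray:
    """Bright/dark state at each step midpoint, from the switch history."""
    n_before = np.searchsorted(switches, step_times, side="right")
    flipped = (n_before % 2).astype(bool)
    return flipped ^ initial_bright  # True where bright


def simulate_fcs_stream(config: FCSSimConfig) -> PhotonStream:
    """Simulate a photon-arrival stream from Brownian emitters.

    Each particle takes independent Gaussian steps (std sqrt(2 D dt) per
    coordinate) with periodic wrapping; the expected photon count per step is
    dt * [background + sum_p brightness * exp(-2(x^2+y^2)/Wxy^2
    - 2 z^2/(omega Wxy)^2) * bright_p]; counts are Poisson-drawn per step and
    placed uniformly within the step.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.time_step
    n_steps = int(round(config.duration / dt))
    if n_steps < 1:
        raise ValidationError("duration must cover at least one time step")
    duration = n_steps * dt

    hx, hy, hz = config.box_half_widths
    half = np.array([hx, hy, hz])
    w2 = config.beam_waist**2
    wz2 = (config.aspect_ratio * config.beam_waist) ** 2

    counts_per_species = [int(round(n)) for n in config.species_counts]
    n_particles = sum(counts_per_species)
    sigma_step = np.repeat(
        [math.sqrt(2.0 * d * dt) for d in config.diffusion_coefficients],
        counts_per_species,
    )

    if n_particles == 0 or config.brightness == 0.0:
        if config.background_rate == 0.0:
            return PhotonStream(timestamps=np.empty(0), duration=duration)
        positions = np.empty((0, 3))
    elif config.initial_positions is not None:
        positions = np.asarray(config.initial_positions, dtype=float)
    else:
        positions = rng.uniform(-half, half, size=(n_particles, 3))

    blink: list[tuple[bool, np.ndarray]] | None = None
    if config.triplet is not None and n_particles:
        blink = [
            _telegraph_switch_times(rng, config.triplet, duration)
            for _ in range(n_particles)
        ]

    chunks: list[np.ndarray] = []
    for start in range(0, n_steps, _CHUNK_STEPS):
        nt = min(_CHUNK_STEPS, n_steps - start)
        if n_particles and config.brightness > 0.0:
            # float32 throughout the hot path: step noise (~1e-8 m) is ten
            # orders of magnitude above float32 resolution at box scale
            steps = rng.standard_normal((n_particles, nt, 3), dtype=np.float32)
            steps *= sigma_step[:, None, None].astype(np.float32)
            traj = np.cumsum(steps, axis=1)
            traj += positions[:, None, :].astype(np.float32)
            # periodic wrap into [-half, half)
            half32 = half.astype(np.float32)
            traj = (traj + half32) % (2.0 * half32) - half32
            positions = traj[:, -1, :].astype(float)
            exponent = (
                -2.0 / w2 * (traj[:, :, 0] ** 2 + traj[:, :, 1] ** 2)
                - (2.0 / wz2) * traj[:, :, 2] ** 2
            )
            # exp() only where the detection profile is non-negligible
            rate = np.zeros_like(exponent)
            near = exponent > -25.0
            rate[near] = np.exp(exponent[near])
            rate *= np.float32(config.brightness)
            if blink is not None:
                mid = (start + np.arange(nt) + 0.5) * dt
                for p, (init, sw) in enumerate(blink):
                    rate[p] *= _bright_mask(init, sw, mid)
            lam = dt * (config.background_rate + rate.sum(axis=0, dtype=float))
        else:
            lam = np.full(nt, dt * config.background_rate)
        k = rng.poisson(lam)
        total = int(k.sum())
        if total:
            step_idx = np.repeat(np.arange(nt), k)
            ts = (start + step_idx + rng.random(total)) * dt
            chunks.append(np.sort(ts))
    timestamps = (
        np.concatenate(chunks) if chunks else np.empty(0)
    )
    timestamps = np.minimum(timestamps, duration)  # guard fp rounding at the edge
    return PhotonStream(timestamps=timestamps, duration=duration)


@dataclass(frozen=True)
class StackSimConfig:
    """Configuration of a synthetic two-channel confocal z-stack.

    Each blob is a separable 3D Gaussian centered laterally at
    ``blob_centers[i]`` (x, y in pixels) with axial peaks at
    ``z_peak_channel1[i]`` / ``z_peak_channel2[i]`` (slice indices, 0-based).
    Gaussian read noise of standard deviation ``noise_sd`` is added and the
    result clipped at zero.
    """

    shape: tuple[int, int, int]  # (n_slices, height, width)
    blob_centers: Sequence[tuple[float, float]]  # (x, y) pixel centers
    z_peak_channel1: Sequence[int]
    z_peak_channel2: Sequence[int]
    axial_sigma: float = 3.0  # slices
    lateral_sigma: float = 2.0  # pixels
    amplitude: float = 1000.0  # counts
    noise_sd: float = 0.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        n_slices, height, width = self.shape
        if n_slices < 1 or height < 1 or width < 1:
            raise ValidationError("shape entries must be >= 1")
        centers = tuple((float(x), float(y)) for x, y in self.blob_centers)
        z1 = tuple(int(z) for z in self.z_peak_channel1)
        z2 = tuple(int(z) for z in self.z_peak_channel2)
        object.__setattr__(self, "blob_centers", centers)
        object.__setattr__(self, "z_peak_channel1", z1)
        object.__setattr__(self, "z_peak_channel2", z2)
        if not (len(centers) == len(z1) == len(z2)):
            raise ValidationError(
                "blob_centers, z_peak_channel1 and z_peak_channel2 must have "
                "the same length"
            )
        for z in (*z1, *z2):
            if not 0 <= z < n_slices:
                raise ValidationError(
                    f"peak slice {z} outside [0, {n_slices})"
                )
        if self.axial_sigma <= 0 or self.lateral_sigma <= 0:
            raise ValidationError("sigmas must be > 0")
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _render_channel(
    config: StackSimConfig, z_peaks: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    n_slices, height, width = config.shape
    z = np.arange(n_slices, dtype=float)[:, None, None]
    y = np.arange(height, dtype=float)[None, :, None]
    x = np.arange(width, dtype=float)[None, None, :]
    stack = np.zeros(config.shape, dtype=float)
    for (cx, cy), zp in zip(config.blob_centers, z_peaks):
        lateral = np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * config.lateral_sigma**2)
        )
        axial = np.exp(-((z - zp) ** 2) / (2.0 * config.axial_sigma**2))
        stack += config.amplitude * axial * lateral
    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, size=config.shape)
    return np.clip(stack, 0.0, None)


def simulate_two_channel_stack(
    config: StackSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the two channels of a synthetic z-stack.

    Returns ``(channel1, channel2)`` as float arrays of shape
    ``(n_slices, height, width)``; in the noiseless limit the axial profile
    of each blob is maximal exactly at its prescribed peak slice.
    """
    rng = np.random.default_rng(config.seed)
    ch1 = _render_channel(config, config.z_peak_channel1, rng)
    ch2 = _render_channel(config, config.z_peak_channel2, rng)
    return ch1, ch2
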