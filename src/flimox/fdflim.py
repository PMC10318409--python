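"""Frequency-domain FLIM: phasor estimation, reference calibration, lifetimes.

In frequency-domain fluorescence lifetime imaging the excitation light is
modulated sinusoidally at frequency ``f`` (ω = 2πf) and the emission is
sampled at ``K`` equally spaced phase steps over one modulation period.  For a
mono-exponential emitter of lifetime τ the emission lags the excitation by a
phase ``φ = arctan(ωτ)`` and is demodulated to depth ``m = 1/sqrt(1+(ωτ)²)``.
The per-pixel first-harmonic Fourier coefficients of the phase series give
(φ, m) — the *phasor* — from which two independent lifetime estimates follow:

    τ_phase = tan(φ) / ω          τ_mod = sqrt(1/m² − 1) / ω

Instrument phase delay and demodulation are removed by calibrating against a
reference slide of known lifetime (default 3.75 ns) measured at the same
modulation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModulatedFrameStack",
    "PhasorImage",
    "InstrumentCalibration",
    "LifetimeImage",
    "compute_phasor",
    "calibrate_instrument",
    "correct_phasor",
    "lifetime_from_phase",
    "lifetime_from_modulation",
    "mean_lifetime",
]

#: Modulation frequency of the FLIM camera (Hz).
DEFAULT_FREQUENCY_HZ = 550e3
#: Lifetime of the reference slide dye (ns).
DEFAULT_REFERENCE_LIFETIME_NS = 3.75


def _wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to (−π, π]."""
    return -np.mod(-np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) + np.pi


@dataclass(frozen=True)
class ModulatedFrameStack:
    """One FLIM exposure: K phase-stepped intensity frames over one period.

    Parameters
    ----------
    pixels
        Intensity array indexed ``(phase_step, row, col)``; non-negative.
    modulation_frequency_hz
        Excitation modulation frequency in Hz.
    pixel_size_um
        Physical pixel pitch in μm.
    timestamp_s
        Acquisition time in seconds since experiment start.
    """

    pixels: np.ndarray
    modulation_frequency_hz: float = DEFAULT_FREQUENCY_HZ
    pixel_size_um: float = 0.065
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 3:
            raise ValueError("pixels must be a (phase_step, row, col) array")
        if pixels.shape[0] < 3:
            raise ValueError(
                f"need at least 3 phase steps, got {pixels.shape[0]}"
            )
        if not np.all(np.isfinite(pixels)):
            raise ValueError("intensities must be finite")
        if np.any(pixels < 0):
            raise ValueError("intensities must be non-negative")
        if self.modulation_frequency_hz <= 0:
            raise ValueError("modulation_frequency_hz must be positive")
        object.__setattr__(self, "pixels", pixels)

    @property
    def n_phase_steps(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PhasorImage:
    """Per-pixel first-harmonic phase and modulation at one frequency."""

    phase_rad: np.ndarray
    modulation: np.ndarray
    mean_intensity: np.ndarray
    modulation_frequency_hz: float = DEFAULT_FREQUENCY_HZ

    @property
    def omega(self) -> float:
        """Angular modulation frequency ω = 2πf (rad/s)."""
        return 2 * np.pi * self.modulation_frequency_hz

    @property
    def n_overmodulated(self) -> int:
        """Pixels with m > 1 (unphysical; noise or missing correction)."""
        return int(np.sum(self.modulation > 1))


@dataclass(frozen=True)
class InstrumentCalibration:
    """Instrument phase offset and modulation gain from a reference slide.

    ``phase_offset_rad`` and ``modulation_factor`` are what the instrument
    *adds* on top of the ideal response of the reference dye, and are valid
    only at the frequency they were measured at.
    """

    reference_lifetime_ns: float
    measured_ref_phase_rad: float
    measured_ref_modulation: float
    modulation_frequency_hz: float
    phase_offset_rad: float = field(init=False)
    modulation_factor: float = field(init=False)

    def __post_init__(self) -> None:
        omega = 2 * np.pi * self.modulation_frequency_hz
        wt = omega * self.reference_lifetime_ns * 1e-9
        object.__setattr__(
            self, "phase_offset_rad",
            float(_wrap_phase(self.measured_ref_phase_rad - np.arctan(wt))),
        )
        object.__setattr__(
            self, "modulation_factor",
            float(self.measured_ref_modulation * np.sqrt(1.0 + wt * wt)),
        )


@dataclass(frozen=True)
class LifetimeImage:
    """Per-pixel fluorescence lifetime in ns; NaN where undefined."""

    tau_ns: np.ndarray
    method: str = "phase"
    timestamp_s: float = 0.0
    pixel_size_um: float = 0.065
    n_flagged: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("phase", "modulation"):
            raise ValueError("method must be 'phase' or 'modulation'")


def compute_phasor(stack: ModulatedFrameStack) -> PhasorImage:
    """First-harmonic phasor of a phase-stepped intensity stack.

    For the pixel series ``I_k`` (k = 0..K−1, phases 2πk/K):

        c0 = mean(I_k)
        a  = (2/K) Σ I_k cos(2πk/K)
        b  = (2/K) Σ I_k sin(2πk/K)
        φ = atan2(b, a),  m = sqrt(a² + b²) / c0

    so that a delayed signal ``I_k ∝ 1 + m·cos(2πk/K − φ)`` yields positive
    phase φ.  Dark pixels (c0 = 0) get NaN phase and modulation.
    """
    pixels = stack.pixels
    k = pixels.shape[0]
    angles = 2 * np.pi * np.arange(k) / k
    cos_w = np.cos(angles)[:, None, None]
    sin_w = np.sin(angles)[:, None, None]
    c0 = pixels.mean(axis=0)
    a = (2.0 / k) * np.sum(pixels * cos_w, axis=0)
    b = (2.0 / k) * np.sum(pixels * sin_w, axis=0)
    amplitude = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        modulation = np.where(c0 > 0, amplitude / np.where(c0 > 0, c0, 1.0), np.nan)
    # phase of a (numerically) zero first harmonic is indeterminate; report
    # 0 for lit pixels (documented convention), NaN for dark ones
    lit = amplitude > 1e-9 * np.maximum(c0, 0.0)
    phase = np.where(lit, np.arctan2(b, a), 0.0)
    phase = np.where(c0 > 0, phase, np.nan)
    return PhasorImage(
        phase_rad=phase,
        modulation=modulation,
        mean_intensity=c0,
        modulation_frequency_hz=stack.modulation_frequency_hz,
    )


def _roi_slices(roi) -> tuple[slice, slice]:
    """ROI as ((row0, row1), (col0, col1)), 0-based half-open; None = all."""
    if roi is None:
        return slice(None), slice(None)
    (r0, r1), (c0, c1) = roi
    return slice(r0, r1), slice(c0, c1)


def calibrate_instrument(
    ref_phasor: PhasorImage,
    reference_lifetime_ns: float = DEFAULT_REFERENCE_LIFETIME_NS,
    roi=None,
) -> InstrumentCalibration:
    """Derive instrument phase offset and modulation gain from a reference
    slide phasor, given the reference dye's known lifetime.

    The ROI-mean phase and modulation of the reference are compared with the
    ideal mono-exponential response arctan(ωτ_ref), 1/sqrt(1+(ωτ_ref)²).
    """
    rs, cs = _roi_slices(roi)
    phase = ref_phasor.phase_rad[rs, cs]
    mod = ref_phasor.modulation[rs, cs]
    good = np.isfinite(phase) & np.isfinite(mod)
    if not np.any(good):
        raise ValueError("reference ROI contains no valid pixels")
    mean_mod = float(mod[good].mean())
    if mean_mod == 0:
        raise ValueError("reference ROI mean modulation is zero; cannot calibrate")
    return InstrumentCalibration(
        reference_lifetime_ns=reference_lifetime_ns,
        measured_ref_phase_rad=float(phase[good].mean()),
        measured_ref_modulation=mean_mod,
        modulation_frequency_hz=ref_phasor.modulation_frequency_hz,
    )


def correct_phasor(sample: PhasorImage, calib: InstrumentCalibration) -> PhasorImage:
    """Remove the instrument response from a sample phasor."""
    if not np.isclose(
        sample.modulation_frequency_hz, calib.modulation_frequency_hz
    ):
        raise ValueError(
            "calibration frequency "
            f"{calib.modulation_frequency_hz:g} Hz does not match sample "
            f"frequency {sample.modulation_frequency_hz:g} Hz"
        )
    return PhasorImage(
        phase_rad=_wrap_phase(sample.phase_rad - calib.phase_offset_rad),
        modulation=sample.modulation / calib.modulation_factor,
        mean_intensity=sample.mean_intensity,
        modulation_frequency_hz=sample.modulation_frequency_hz,
    )


def lifetime_from_phase(phasor: PhasorImage) -> LifetimeImage:
    """Phase lifetime τ = tan(φ)/ω per pixel (corrected phasor expected).

    Strictly negative phases and phases ≥ π/2 are unphysical for a
    mono-exponential decay and map to NaN; the count is reported via
    ``n_flagged``.
    """
    phi = phasor.phase_rad
    with np.errstate(invalid="ignore"):
        bad = (phi < 0) | (phi >= np.pi / 2)
        tau = np.where(bad | ~np.isfinite(phi), np.nan, np.tan(np.where(bad, 0.0, phi))) / phasor.omega
    n_flagged = int(np.sum(bad & np.isfinite(phi)))
    return LifetimeImage(tau_ns=tau * 1e9, method="phase", n_flagged=n_flagged)


def lifetime_from_modulation(phasor: PhasorImage) -> LifetimeImage:
    """Modulation lifetime τ = sqrt(1/m² − 1)/ω per pixel.

    Over-modulated pixels (m ≥ 1, possible under noise) clip to τ = 0 and are
    counted in ``n_flagged``; m ≤ 0 maps to NaN.
    """
    m = phasor.modulation
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(m > 0, np.sqrt(np.maximum(1.0 / np.where(m > 0, m, 1.0) ** 2 - 1.0, 0.0)), np.nan)
    tau = tau / phasor.omega
    n_flagged = int(np.sum(np.isfinite(m) & (m > 1)))
    return LifetimeImage(tau_ns=tau * 1e9, method="modulation", n_flagged=n_flagged)


def mean_lifetime(image: LifetimeImage, roi=None) -> tuple[float, int]:
    """ROI-mean lifetime in ns and the count of excluded (NaN) pixels.

    Lifetime images are noisy pixel-wise; the per-image ROI average is the
    quantity converted to an oxygen reading downstream.
    """
    rs, cs = _roi_slices(roi)
    tau = np.asarray(image.tau_ns)[rs, cs]
    if tau.size == 0:
        raise ValueError("empty ROI")
    finite = np.isfinite(tau)
    n_excluded = int(tau.size - finite.sum())
    if not np.any(finite):
        raise ValueError("ROI contains no finite lifetimes")
    return float(tau[finite].mean()), n_excluded
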