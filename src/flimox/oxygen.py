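"""Stern–Volmer oxygen sensing: calibration, conversion, step-test analysis.

The luminescence lifetime of the ruthenium dye RTDP is dynamically quenched
by dissolved oxygen following the Stern–Volmer relation

    [O2] = (1/Kq) * (τ0/τ − 1)

where τ0 is the lifetime in the absence of oxygen and Kq the quenching
constant.  A two-point calibration at 0% and at a known oxic level (here the
100% O2 point) fixes (τ0, Kq) at one temperature; lifetimes measured on chip
then convert directly to oxygen readings.  Oxygen is carried internally as a
*fraction of the full calibration scale* (1.0 = 100% O2) and converted to
percent only at I/O boundaries — the printed quenching constants
(Kq = τ0/τ100% − 1 ≈ 2.6) are only dimensionally consistent with fractional
units.

The module also characterises the chip's dynamic response to programmed
oxygen steps: per-step plateau averages (measured-vs-set comparison) and the
times t85/t90/t95 needed to traverse 85/90/95% of each step's change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SternVolmerCalibration",
    "StepSchedule",
    "O2Trace",
    "LifetimeSeries",
    "StepRecord",
    "SwitchingTimes",
    "PlateauSummary",
    "fit_stern_volmer",
    "o2_from_lifetime",
    "lifetime_from_o2",
    "trace_from_lifetimes",
    "plateau_values",
    "switching_times",
]

#: Default programmed setpoint sequence of the oxygen step test (% O2).
DEFAULT_STEP_LEVELS = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 21.0, 100.0)


@dataclass(frozen=True)
class SternVolmerCalibration:
    """Two-point RTDP calibration at one temperature.

    ``kq`` is dimensionless because oxygen is expressed as a fraction of the
    full scale; with the oxic point at 100% O2, ``kq = τ0/τ_ox − 1``.
    """

    tau0_ns: float
    tau_ox_ns: float
    o2_ox_fraction: float
    temperature_c: float
    kq: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.tau0_ns > self.tau_ox_ns > 0):
            raise ValueError(
                "need tau0_ns > tau_ox_ns > 0 (no quenching otherwise); got "
                f"tau0={self.tau0_ns}, tau_ox={self.tau_ox_ns}"
            )
        if not (0 < self.o2_ox_fraction <= 1):
            raise ValueError("o2_ox_fraction must be in (0, 1]")
        object.__setattr__(
            self, "kq",
            (self.tau0_ns / self.tau_ox_ns - 1.0) / self.o2_ox_fraction,
        )


def fit_stern_volmer(
    tau0_ns: float,
    tau_ox_ns: float,
    o2_ox_fraction: float = 1.0,
    temperature_c: float = 30.0,
) -> SternVolmerCalibration:
    """Build a Stern–Volmer calibration from the two anchor lifetimes.

    Parameters
    ----------
    tau0_ns
        Sensor lifetime at 0% O2 (ns).
    tau_ox_ns
        Sensor lifetime at the oxic calibration point (ns).
    o2_ox_fraction
        Oxygen at the oxic point as a fraction of full scale (1.0 = 100%).
    temperature_c
        Calibration temperature; calibrations are temperature-specific and
        must not be mixed across temperatures.
    """
    return SternVolmerCalibration(
        tau0_ns=tau0_ns,
        tau_ox_ns=tau_ox_ns,
        o2_ox_fraction=o2_ox_fraction,
        temperature_c=temperature_c,
    )


def o2_from_lifetime(tau_ns, calib: SternVolmerCalibration):
    """Invert the Stern–Volmer relation: [O2] = (1/Kq)(τ0/τ − 1).

    Returns the oxygen fraction of full scale.  Noisy lifetimes may produce
    slightly negative or super-unity readings; these are deliberately *not*
    clipped (clipping would bias downstream averages).
    """
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau[np.isfinite(tau)] <= 0):
        raise ValueError("lifetimes must be positive")
    out = (calib.tau0_ns / tau - 1.0) / calib.kq
    return float(out) if np.isscalar(tau_ns) else out


def lifetime_from_o2(o2_fraction, calib: SternVolmerCalibration):
    """Forward Stern–Volmer model: τ = τ0 / (1 + Kq·[O2])."""
    o2 = np.asarray(o2_fraction, dtype=float)
    if np.any(o2[np.isfinite(o2)] < 0):
        raise ValueError("o2_fraction must be non-negative")
    out = calib.tau0_ns / (1.0 + calib.kq * o2)
    return float(out) if np.isscalar(o2_fraction) else out


@dataclass(frozen=True)
class StepSchedule:
    """Programmed oxygen setpoints: an initial hold then equal-length steps."""

    levels_percent: tuple = DEFAULT_STEP_LEVELS
    initial_hold_h: float = 4.0
    step_duration_h: float = 3.0
    sample_interval_min: float = 5.0

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels_percent)
        if any(not 0 <= v <= 100 for v in levels):
            raise ValueError("levels must lie in [0, 100] %")
        if min(self.initial_hold_h, self.step_duration_h, self.sample_interval_min) <= 0:
            raise ValueError("durations must be positive")
        object.__setattr__(self, "levels_percent", levels)

    @property
    def n_steps(self) -> int:
        return len(self.levels_percent)

    @property
    def total_duration_h(self) -> float:
        return self.initial_hold_h + (self.n_steps - 1) * self.step_duration_h

    def step_bounds_s(self) -> list[tuple[float, float]]:
        """Per-level (start, end) in seconds since schedule start."""
        bounds = [(0.0, self.initial_hold_h * 3600.0)]
        t = self.initial_hold_h * 3600.0
        for _ in self.levels_percent[1:]:
            bounds.append((t, t + self.step_duration_h * 3600.0))
            t += self.step_duration_h * 3600.0
        return bounds

    def setpoint_fraction(self, t_s) -> np.ndarray:
        """Programmed setpoint (fraction of full scale) at time(s) t_s."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        out = np.empty_like(t)
        for (start, end), level in zip(self.step_bounds_s(), self.levels_percent):
            mask = (t >= start) & (t < end)
            out[mask] = level / 100.0
        out[t >= self.step_bounds_s()[-1][1]] = self.levels_percent[-1] / 100.0
        return out


@dataclass(frozen=True)
class O2Trace:
    """Measured (or simulated) oxygen concentration time series."""

    times_s: np.ndarray
    o2_fraction: np.ndarray
    source_roi: str = ""
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        o2 = np.asarray(self.o2_fraction, dtype=float)
        if t.shape != o2.shape:
            raise ValueError("times_s and o2_fraction must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "o2_fraction", o2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "o2_percent": self.o2_fraction * 100.0,
                "roi": self.source_roi,
            }
        )


@dataclass(frozen=True)
class LifetimeSeries:
    """ROI-mean lifetimes over time, as reduced from a FLIM time-lapse."""

    times_s: np.ndarray
    tau_ns: np.ndarray
    source_roi: str = ""
    temperature_c: float | None = None


def trace_from_lifetimes(
    series: LifetimeSeries, calib: SternVolmerCalibration
) -> O2Trace:
    """Convert a mean-lifetime time series to an oxygen trace via the
    calibration.  Non-finite lifetimes propagate as NaN (count warned)."""
    if (
        series.temperature_c is not None
        and not np.isclose(series.temperature_c, calib.temperature_c)
    ):
        raise ValueError(
            f"series temperature {series.temperature_c}°C does not match "
            f"calibration temperature {calib.temperature_c}°C; recalibrate at "
            "the measurement temperature"
        )
    tau = np.asarray(series.tau_ns, dtype=float)
    o2 = np.full_like(tau, np.nan)
    good = np.isfinite(tau) & (tau > 0)
    if tau.size and not np.all(good):
        warnings.warn(
            f"{int(tau.size - good.sum())} samples had invalid lifetimes; "
            "emitted as NaN"
        )
    if tau.size:
        o2[good] = o2_from_lifetime(tau[good], calib)
    return O2Trace(
        times_s=np.asarray(series.times_s, dtype=float),
        o2_fraction=o2,
        source_roi=series.source_roi,
        temperature_c=calib.temperature_c,
    )


@dataclass(frozen=True)
class StepRecord:
    """Switching-time record for one schedule step."""

    step_index: int
    setpoint_percent: float
    plateau_fraction: float
    t85_min: float | None
    t90_min: float | None
    t95_min: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class SwitchingTimes:
    """Per-step switching-time table (t85 ≤ t90 ≤ t95 where defined)."""

    records: list[StepRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


@dataclass(frozen=True)
class PlateauSummary:
    """Per-step plateau (last-hour average) vs programmed setpoint."""

    step_index: np.ndarray
    setpoint_percent: np.ndarray
    plateau_percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": self.step_index,
                "setpoint_percent": self.setpoint_percent,
                "plateau_percent": self.plateau_percent,
            }
        )


PLATEAU_WINDOW_S = 3600.0  # average over the last hour of each step


def plateau_values(trace: O2Trace, schedule: StepSchedule) -> PlateauSummary:
    """Per-step plateau estimate: mean concentration over the final hour of
    each step, paired with its setpoint."""
    idx, setp, plat = [], [], []
    for i, ((start, end), level) in enumerate(
        zip(schedule.step_bounds_s(), schedule.levels_percent)
    ):
        window_start = end - PLATEAU_WINDOW_S
        if window_start < start:
            warnings.warn(
                f"step {i} shorter than the plateau window; truncating"
            )
            window_start = start
        mask = (trace.times_s > window_start) & (trace.times_s <= end)
        mask &= np.isfinite(trace.o2_fraction)
        if not np.any(mask):
            warnings.warn(f"step {i}: no samples in plateau window")
            value = np.nan
        else:
            value = float(trace.o2_fraction[mask].mean())
        idx.append(i)
        setp.append(level)
        plat.append(value * 100.0)
    return PlateauSummary(
        step_index=np.array(idx),
        setpoint_percent=np.array(setp),
        plateau_percent=np.array(plat),
    )


def _sustained_crossing_min(
    t_s: np.ndarray, values: np.ndarray, onset_s: float,
    threshold: float, rising: bool, sustained: bool,
) -> float | None:
    """Time (min after onset) of the threshold crossing, linearly
    interpolated; with ``sustained`` the trace must stay past the threshold
    for the remainder of the step."""
    above = values >= threshold if rising else values <= threshold
    if not np.any(above):
        return None
    if sustained:
        # first index from which the trace never falls back
        ok = np.flip(np.logical_and.accumulate(np.flip(above)))
        if not np.any(ok):
            return None
        j = int(np.argmax(ok))
    else:
        j = int(np.argmax(above))
    if j == 0:
        return max((t_s[0] - onset_s) / 60.0, 0.0)
    t0, t1 = t_s[j - 1], t_s[j]
    v0, v1 = values[j - 1], values[j]
    if v1 == v0:
        t_cross = t1
    else:
        t_cross = t0 + (threshold - v0) / (v1 - v0) * (t1 - t0)
    return max((t_cross - onset_s) / 60.0, 0.0)


def switching_times(
    trace: O2Trace,
    schedule: StepSchedule,
    thresholds: tuple = (0.85, 0.90, 0.95),
    final_value: str = "last",
    sustained: bool = True,
) -> SwitchingTimes:
    """Per-step times to traverse the given fractions of each step's change.

    For step ``i`` with entry value ``c_i`` (latest sample at or before the
    step onset) and final value ``c_f``, ``t_X`` is the first time after
    onset at which the trace crosses ``c_i + X·(c_f − c_i)`` — located by
    linear interpolation between samples — and, by default, does not fall
    back across it for the remainder of the step.

    Parameters
    ----------
    final_value
        What defines ``c_f``: ``"last"`` (default) — the step's final
        measured sample; ``"plateau"`` — the last-hour average; or
        ``"setpoint"`` — the programmed level.
    sustained
        Require the crossing to hold for the rest of the step (robust to
        noise spikes).  ``False`` gives the pure first crossing.
    """
    if final_value not in ("last", "plateau", "setpoint"):
        raise ValueError("final_value must be 'last', 'plateau' or 'setpoint'")
    plateaus = plateau_values(trace, schedule)
    records: list[StepRecord] = []
    t = trace.times_s
    v = trace.o2_fraction
    for i, ((start, end), level) in enumerate(
        zip(schedule.step_bounds_s(), schedule.levels_percent)
    ):
        in_step = (t > start) & (t <= end) & np.isfinite(v)
        plateau_frac = plateaus.plateau_percent[i] / 100.0
        if not np.any(in_step):
            records.append(
                StepRecord(i, level, plateau_frac, None, None, None, True)
            )
            continue
        pre = (t <= start) & np.isfinite(v)
        c_i = float(v[pre][-1]) if np.any(pre) else float(v[in_step][0])
        if final_value == "last":
            c_f = float(v[in_step][-1])
        elif final_value == "plateau":
            c_f = plateau_frac
        else:
            c_f = level / 100.0
        if np.isclose(c_f, c_i):
            records.append(
                StepRecord(i, level, plateau_frac, 0.0, 0.0, 0.0, True)
            )
            continue
        rising = c_f > c_i
        times = {}
        for x in sorted(thresholds):
            thr = c_i + x * (c_f - c_i)
            times[x] = _sustained_crossing_min(
                t[in_step], v[in_step], start, thr, rising, sustained
            )
        records.append(
            StepRecord(
                i, level, plateau_frac,
                times.get(0.85), times.get(0.90), times.get(0.95), False,
            )
        )
    return SwitchingTimes(records=records)
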