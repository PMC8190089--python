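"""Temperature forcing for heat-memory simulations.

A :class:`TemperatureProfile` is a piecewise-constant temperature time
series T(t): the temperature ``temps[i]`` holds on the left-closed,
right-open interval ``[times[i], times[i+1])`` and the final value extends
to ``duration``.  Time is measured in hours since germination, so the
standard lab protocol places a 37 degC / 20 min acclimation (ACC) pulse on
4-day-old seedlings (96 h) and a 43.5 degC / 60 min heat shock (HS) on
7-day-old seedlings (168 h).

Profiles are either built from a :class:`LabProtocol`, generated by the
synthetic-data module (fluctuating "field" series), or read from an hourly
CSV with columns ``time_h,temp_c``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureProfile",
    "LabProtocol",
    "SpikeAnnotation",
    "build_lab_profile",
    "read_temperature_csv",
    "write_temperature_csv",
    "temperature_at",
    "detect_spikes",
]

#: absolute tolerance (hours) for floating-point time comparisons
TIME_TOL = 1e-9

ACC_DURATION_H = 1.0 / 3.0  # 20 min acclimation pulse


class ProfileError(ValueError):
    """Raised for invalid temperature profiles or protocol definitions."""


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant temperature versus time.

    Parameters
    ----------
    times : array of hours, strictly increasing, ``times[0] == 0``
    temps : array of degC, one per breakpoint; ``temps[i]`` holds on
        ``[times[i], times[i+1])``
    duration : total length of the profile in hours (>= last breakpoint)
    label : free-text description, e.g. ``"lab:+ACC+HS"``
    """

    times: np.ndarray
    temps: np.ndarray
    duration: float
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if times.ndim != 1 or temps.ndim != 1 or len(times) != len(temps):
            raise ProfileError("times and temps must be 1-D and equal length")
        if len(times) == 0:
            raise ProfileError("profile must have at least one breakpoint")
        if abs(times[0]) > TIME_TOL:
            raise ProfileError("profile must start at t=0")
        if np.any(np.diff(times) <= 0):
            i = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ProfileError(f"times not increasing at row {i + 1}")
        if not np.all(np.isfinite(temps)):
            raise ProfileError("temperatures must be finite")
        if np.any(temps < -20) or np.any(temps > 60):
            raise ProfileError("temperatures outside plausible range [-20, 60] degC")
        if self.duration < times[-1] - TIME_TOL:
            raise ProfileError("duration must be >= last breakpoint time")

    def __call__(self, t):
        return temperature_at(self, t)

    def with_label(self, label: str) -> "TemperatureProfile":
        return replace(self, label=label)

    def breakpoints(self) -> np.ndarray:
        """All step edges: the breakpoint times plus the profile end.

        Step ``i`` spans ``[breakpoints()[i], breakpoints()[i+1])``; the
        final entry is ``duration`` (the last step may be zero-width when
        the profile ends exactly at its last breakpoint).
        """
        return np.append(self.times, max(self.duration, self.times[-1]))


@dataclass(frozen=True)
class LabProtocol:
    """Laboratory heat-treatment schedule.

    Defaults encode the standard memory assay: baseline growth at 22 degC,
    ACC = 37 degC for 20 min at 96 h after germination, HS = 43.5 degC for
    60 min at 168 h, observation until 240 h.
    """

    baseline_temp: float = 22.0
    acc_enabled: bool = True
    acc_time: float = 96.0
    acc_temp: float = 37.0
    acc_duration: float = ACC_DURATION_H
    hs_enabled: bool = True
    hs_time: float = 168.0
    hs_temp: float = 43.5
    hs_duration: float = 1.0
    total_duration: float = 240.0

    def __post_init__(self):
        if self.acc_duration <= 0 or self.hs_duration <= 0 or self.total_duration <= 0:
            raise ProfileError("durations must be positive")
        if self.acc_enabled and self.hs_enabled:
            if self.acc_time + self.acc_duration > self.hs_time + TIME_TOL:
                raise ProfileError("ACC window overlaps HS window")

    @property
    def label(self) -> str:
        tag = ("+ACC" if self.acc_enabled else "") + ("+HS" if self.hs_enabled else "")
        return "lab:" + (tag if tag else "control")


@dataclass(frozen=True)
class SpikeAnnotation:
    """Heat spikes detected in a profile, in temporal order.

    ``intervals`` holds ``(start_h, end_h, max_temp_c)`` triples for the
    maximal intervals where T exceeds the calling threshold; ``roles``
    labels them ``ACC`` (first), ``HS`` (second) and ``extra`` after that.
    """

    intervals: list = field(default_factory=list)
    roles: list = field(default_factory=list)
    threshold: float = 30.0

    def __len__(self):
        return len(self.intervals)

    def role_interval(self, role: str):
        """Return the (start, end, max_temp) interval for a role, or None."""
        for iv, r in zip(self.intervals, self.roles):
            if r == role:
                return iv
        return None


def build_lab_profile(protocol: LabProtocol) -> TemperatureProfile:
    """Turn a :class:`LabProtocol` into a step-function profile.

    The profile equals the baseline temperature everywhere except inside
    the enabled heat windows; breakpoints sit exactly at window edges.
    """
    events = []
    if protocol.acc_enabled:
        events.append((protocol.acc_time, protocol.acc_duration, protocol.acc_temp))
    if protocol.hs_enabled:
        events.append((protocol.hs_time, protocol.hs_duration, protocol.hs_temp))
    events.sort()
    for (s1, d1, _), (s2, _, _) in zip(events, events[1:]):
        if s1 + d1 > s2 + TIME_TOL:
            raise ProfileError("heat windows overlap")

    times = [0.0]
    temps = [protocol.baseline_temp]
    for start, dur, temp in events:
        if start > protocol.total_duration:
            continue
        times.extend([start, start + dur])
        temps.extend([temp, protocol.baseline_temp])
    return TemperatureProfile(
        times=np.array(times),
        temps=np.array(temps),
        duration=float(protocol.total_duration),
        label=protocol.label,
    )


def read_temperature_csv(path) -> TemperatureProfile:
    """Read an hourly (or arbitrary-step) profile from ``time_h,temp_c`` CSV.

    The profile duration extends one median step past the last row, so an
    hourly file of k rows covers k hours.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_h", "temp_c"]:
        raise ProfileError("CSV must have header 'time_h,temp_c'")
    if len(df) == 0:
        raise ProfileError("empty temperature CSV")
    times = df["time_h"].to_numpy(dtype=float)
    temps = df["temp_c"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        # 1-based data rows: diff index i means row i+2 breaks monotonicity
        raise ProfileError(f"times not increasing at row {int(bad[0]) + 2}")
    spacing = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    name = getattr(path, "name", str(path))
    return TemperatureProfile(times=times, temps=temps,
                              duration=float(times[-1] + spacing),
                              label=f"csv:{name}")


def write_temperature_csv(profile: TemperatureProfile, path) -> None:
    """Write profile breakpoints as ``time_h,temp_c`` CSV (round-trippable)."""
    df = pd.DataFrame({"time_h": profile.times, "temp_c": profile.temps})
    if isinstance(path, io.IOBase):
        df.to_csv(path, index=False)
    else:
        df.to_csv(str(path), index=False)


def temperature_at(profile: TemperatureProfile, t):
    """Evaluate T(t) with the left-closed step convention.

    Accepts a scalar or array of times in ``[0, duration]``; ``t`` exactly
    equal to the duration returns the final step's temperature.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -TIME_TOL) or np.any(t_arr > profile.duration + TIME_TOL):
        raise ValueError(f"time outside [0, {profile.duration}] h")
    idx = np.searchsorted(profile.times, t_arr + TIME_TOL, side="right") - 1
    idx = np.clip(idx, 0, len(profile.temps) - 1)
    out = profile.temps[idx]
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def detect_spikes(profile: TemperatureProfile, threshold: float = 30.0) -> SpikeAnnotation:
    """Find maximal intervals with T strictly above ``threshold``.

    The first spike is annotated ACC, the second HS and the remainder
    ``extra``, following the convention used for fluctuating field series.
    """
    hot = profile.temps > threshold
    edges = profile.breakpoints()
    starts = profile.times
    intervals = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            start = float(starts[i])
            end = float(edges[j + 1])
            peak = float(np.max(profile.temps[i:j + 1]))
            intervals.append((start, end, peak))
            i = j + 1
        else:
            i += 1
    roles = ["ACC", "HS"][: len(intervals)] + ["extra"] * max(0, len(intervals) - 2)
    return SpikeAnnotation(intervals=intervals, roles=roles, threshold=threshold)
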