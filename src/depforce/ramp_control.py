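"""Digitized staircase voltage schedules and camera synchronization.

The instrument applies the pulling force by ramping the drive voltage in
discrete increments ("digitized voltage increment steps").  Because the DEP
force is quadratic in voltage (F = c * V_pp^2), a staircase that is linear in
*force* uses square-root-spaced voltages: after update k of N the voltage is
``v_max * sqrt(k / N)`` and the force is ``k * F_max / N``.  A voltage-linear
staircase is provided for comparison; its force ramp bends early.

Voltage updates happen at times ``t_k = k * duration / N`` (k = 1..N) and each
level holds on the left-closed interval [t_k, t_{k+1}); before the first
update the voltage is zero.  ``duration = c * v_max^2 / loading_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RampSchedule",
    "SyncPlan",
    "LinearityReport",
    "LookupResult",
    "design_ramp",
    "ramp_linearity",
    "frame_rate_for",
    "schedule_lookup",
    "schedule_to_csv",
    "schedule_from_csv",
]


@dataclass
class RampSchedule:
    """A digitized staircase realizing a force loading ramp.

    Arrays have length ``n_steps + 1``: entry k is the state after the k-th
    voltage update (entry 0 is the zero-voltage start).  Level k holds on
    [step_times[k], step_times[k+1]); the final entry is reached exactly at
    ``duration``.
    """

    loading_rate: float       # pN/s
    n_steps: int
    v_max: float              # V_pp
    calibration: float        # c, pN per V_pp^2
    duration: float           # s
    step_times: np.ndarray    # s
    step_voltages: np.ndarray # V_pp
    step_forces: np.ndarray   # pN
    mode: str = "force_linear"

    @property
    def f_max(self) -> float:
        return self.calibration * self.v_max ** 2

    @property
    def force_step(self) -> float:
        """Force resolution of the staircase (pN)."""
        return self.f_max / self.n_steps


@dataclass(frozen=True)
class SyncPlan:
    """Camera frame rate synchronized to the drive frequency."""

    signal_frequency: float   # Hz
    capture_rate: float       # frames/s
    samples_per_cycle: int
    frame_times: np.ndarray   # frame start times over one signal cycle (s)


@dataclass(frozen=True)
class LinearityReport:
    """How far a staircase deviates from the ideal linear force ramp."""

    max_abs_deviation: float      # sup_t |F_stair(t) - r t| (pN)
    rms_deviation: float          # RMS of the same over [0, duration] (pN)
    rate_min: float               # smallest per-step instantaneous rate (pN/s)
    rate_max: float               # largest per-step instantaneous rate (pN/s)

    @property
    def rate_spread(self) -> float:
        return self.rate_max - self.rate_min


@dataclass(frozen=True)
class LookupResult:
    step_index: int
    voltage: float   # V_pp
    force: float     # pN
    saturated: bool  # True when the query time is past the schedule end


def design_ramp(loading_rate: float, calibration: float, v_max: float,
                n_steps: int, mode: str = "force_linear") -> RampSchedule:
    """Design a staircase schedule for a target linear force loading rate.

    ``force_linear`` (default) spaces forces uniformly (voltages go as
    sqrt(k/N)); ``voltage_linear`` spaces voltages uniformly so the force ramp
    is quadratic in time (provided for comparison).
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be > 0")
    if calibration <= 0:
        raise ValueError("calibration must be > 0")
    if v_max <= 0:
        raise ValueError("v_max must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if mode not in ("force_linear", "voltage_linear"):
        raise ValueError(f"unknown mode {mode!r}")

    f_max = calibration * v_max ** 2
    duration = f_max / loading_rate
    k = np.arange(n_steps + 1)
    step_times = k * (duration / n_steps)
    if mode == "force_linear":
        step_forces = k * (f_max / n_steps)
        step_voltages = v_max * np.sqrt(k / n_steps)
    else:
        step_voltages = v_max * (k / n_steps)
        step_forces = calibration * step_voltages ** 2
    return RampSchedule(
        loading_rate=loading_rate, n_steps=n_steps, v_max=v_max,
        calibration=calibration, duration=duration, step_times=step_times,
        step_voltages=step_voltages, step_forces=step_forces, mode=mode,
    )


def ramp_linearity(schedule: RampSchedule) -> LinearityReport:
    """Deviation of the staircase force from the ideal ramp ``r * t``.

    Within each hold the deviation is linear in t, so the supremum and the
    RMS are computed in closed form per interval (the sup is approached at
    the right-open end of each hold).
    """
    r = schedule.loading_rate
    t = schedule.step_times
    f = schedule.step_forces
    # deviation d(t) = r t - F_k on [t_k, t_{k+1}); endpoints:
    a = r * t[:-1] - f[:-1]
    b = r * t[1:] - f[:-1]
    max_dev = float(np.max(np.abs(np.concatenate([a, b]))))
    dt = np.diff(t)
    # integral of d^2 over each interval: dt (a^2 + a b + b^2) / 3
    total = float(np.sum(dt * (a * a + a * b + b * b) / 3.0))
    rms = math.sqrt(total / schedule.duration)
    inst = np.diff(f) / dt
    return LinearityReport(
        max_abs_deviation=max_dev, rms_deviation=rms,
        rate_min=float(inst.min()), rate_max=float(inst.max()),
    )


def frame_rate_for(signal_frequency: float, samples_per_cycle: int = 2) -> SyncPlan:
    """Camera frame rate synchronized to the drive: capture = samples * frequency.

    With the default two samples per cycle the frame times fall at the start
    of alternating half-cycles, so each polarity is imaged exactly once per
    cycle (the LED synchronization check).
    """
    if signal_frequency <= 0:
        raise ValueError("signal_frequency must be > 0")
    if samples_per_cycle < 1:
        raise ValueError("samples_per_cycle must be >= 1")
    capture = samples_per_cycle * signal_frequency
    frame_times = np.arange(samples_per_cycle) / capture
    return SyncPlan(signal_frequency=signal_frequency, capture_rate=capture,
                    samples_per_cycle=samples_per_cycle, frame_times=frame_times)


def schedule_lookup(schedule: RampSchedule, time: float | None = None, *,
                    frame: int | None = None,
                    capture_rate: float | None = None) -> LookupResult:
    """Staircase state (step, voltage, force) at a time or camera frame.

    Frames are converted via ``time = frame / capture_rate`` (frame start
    times).  Queries past the schedule end return the final step with
    ``saturated = True``.
    """
    if (time is None) == (frame is None):
        raise ValueError("provide exactly one of time or frame")
    if frame is not None:
        if capture_rate is None or capture_rate <= 0:
            raise ValueError("frame lookup requires capture_rate > 0")
        time = frame / capture_rate
    if time < 0:
        raise ValueError("time must be >= 0")
    saturated = time > schedule.duration
    idx = int(np.searchsorted(schedule.step_times, time, side="right")) - 1
    idx = min(idx, schedule.n_steps)
    return LookupResult(
        step_index=idx,
        voltage=float(schedule.step_voltages[idx]),
        force=float(schedule.step_forces[idx]),
        saturated=bool(saturated),
    )


def schedule_to_csv(schedule: RampSchedule, path) -> None:
    """Write the schedule as CSV with a commented metadata header."""
    import pandas as pd

    header = (
        f"# depforce ramp schedule\n"
        f"# loading_rate_pN_per_s={schedule.loading_rate}\n"
        f"# n_steps={schedule.n_steps}\n"
        f"# v_max_Vpp={schedule.v_max}\n"
        f"# calibration_pN_per_Vpp2={schedule.calibration}\n"
        f"# duration_s={schedule.duration}\n"
        f"# mode={schedule.mode}\n"
    )
    df = pd.DataFrame({
        "step": np.arange(schedule.n_steps + 1),
        "t_start_s": schedule.step_times,
        "v_pp": schedule.step_voltages,
        "force_pN": schedule.step_forces,
    })
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def schedule_from_csv(path) -> RampSchedule:
    import pandas as pd

    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for ln, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, val = line.lstrip("# ").strip().split("=", 1)
                meta[key] = val
            body_start = ln + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return RampSchedule(
        loading_rate=float(meta["loading_rate_pN_per_s"]),
        n_steps=int(meta["n_steps"]),
        v_max=float(meta["v_max_Vpp"]),
        calibration=float(meta["calibration_pN_per_Vpp2"]),
        duration=float(meta["duration_s"]),
        step_times=df["t_start_s"].to_numpy(),
        step_voltages=df["v_pp"].to_numpy(),
        step_forces=df["force_pN"].to_numpy(),
        mode=meta.get("mode", "force_linear"),
    )
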