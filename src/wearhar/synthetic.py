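"""Synthetic dual-rate inertial traces for a 9-activity recognition task.

The generator emulates a wrist-worn device with a triaxial accelerometer
sampled at 14 Hz (±8 g) and a triaxial gyroscope sampled at 17 Hz.  Nine
activities of daily life are modelled in three energy bands — Sedentary
(sitting, lying, standing), Moderate (walking, turning leftwards, turning
rightwards) and Rigorous (jumping, running, exercising).

The signal model is deliberately simple: per axis, acceleration is a gravity
component plus a sinusoid of activity-specific amplitude and frequency plus
white Gaussian noise; angular rate is a constant mean plus white noise.  The
defaults are chosen so that the *discriminative structure* of the task is
reproduced:

* the three energy bands are separable from accelerometer statistics alone
  (amplitudes ordered Sedentary < Moderate < Rigorous);
* sitting / lying / standing differ only in gravity orientation;
* turning leftwards and turning rightwards share all accelerometer
  parameters and differ only in the sign of the mean yaw (X-axis) angular
  rate, so they can be told apart chiefly through the gyroscope.

No attempt is made at biomechanically realistic gait synthesis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACCEL_RATE_HZ = 14.0
GYRO_RATE_HZ = 17.0

BANDS = ("Sedentary", "Moderate", "Rigorous")

#: fixed per-axis phase offsets of the sinusoidal component (radians)
_AXIS_PHASES = np.array([0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0])


@dataclass(frozen=True)
class ActivitySpec:
    """Parameters of the signal model for one activity class.

    Attributes
    ----------
    name:
        Activity label.
    energy_band:
        One of ``Sedentary``, ``Moderate``, ``Rigorous``.
    gravity_orientation:
        Unit 3-vector: the DC component of the accelerometer signal (g).
    accel_amplitude:
        Amplitude of the sinusoidal acceleration component (g).
    accel_frequency:
        Frequency of the sinusoidal component (Hz).
    accel_noise_sd:
        Standard deviation of the white accelerometer noise (g).
    gyro_mean_rate:
        Mean angular rate per axis (deg/s).
    gyro_noise_sd:
        Standard deviation of the white gyroscope noise (deg/s).
    """

    name: str
    energy_band: str
    gravity_orientation: tuple[float, float, float]
    accel_amplitude: float
    accel_frequency: float
    accel_noise_sd: float
    gyro_mean_rate: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity_orientation, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
            raise ValueError(f"gravity_orientation must have unit norm, got {g}")
        if self.accel_amplitude < 0:
            raise ValueError("accel_amplitude must be >= 0")
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.energy_band not in BANDS:
            raise ValueError(f"unknown energy band {self.energy_band!r}")


@dataclass
class LabelledTrace:
    """Dual-rate labelled sample streams from one recording session.

    ``labels`` carries one activity label per *accelerometer* sample (the
    accelerometer stream defines the processing timeline).
    """

    accel_times: np.ndarray  # (n,) seconds, strictly increasing
    accel_samples: np.ndarray  # (n, 3) in g
    gyro_times: np.ndarray  # (m,) seconds, strictly increasing
    gyro_samples: np.ndarray  # (m, 3) in deg/s
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.accel_times):
            raise ValueError("need exactly one label per accelerometer sample")
        if np.any(np.diff(self.accel_times) <= 0) or np.any(np.diff(self.gyro_times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def n_accel(self) -> int:
        return len(self.accel_times)


_SED = dict(accel_noise_sd=0.02, gyro_noise_sd=2.0)

_DEFAULT_SPECS = (
    ActivitySpec("sitting", "Sedentary", (0.0, 0.70710678, 0.70710678),
                 0.01, 0.3, **_SED),
    ActivitySpec("lying", "Sedentary", (1.0, 0.0, 0.0), 0.015, 0.25, **_SED),
    ActivitySpec("standing", "Sedentary", (0.0, 0.0, 1.0), 0.02, 0.35, **_SED),
    ActivitySpec("walking", "Moderate", (0.0, 0.0, 1.0), 0.40, 2.0, 0.05,
                 (0.0, 0.0, 0.0), 15.0),
    ActivitySpec("turning_left", "Moderate", (0.0, 0.0, 1.0), 0.25, 1.2, 0.05,
                 (40.0, 0.0, 0.0), 15.0),
    ActivitySpec("turning_right", "Moderate", (0.0, 0.0, 1.0), 0.25, 1.2, 0.05,
                 (-40.0, 0.0, 0.0), 15.0),
    ActivitySpec("jumping", "Rigorous", (0.0, 0.0, 1.0), 1.2, 2.5, 0.10,
                 (0.0, 0.0, 0.0), 60.0),
    ActivitySpec("running", "Rigorous", (0.0, 0.0, 1.0), 1.0, 2.8, 0.10,
                 (0.0, 0.0, 0.0), 60.0),
    ActivitySpec("exercising", "Rigorous", (0.0, 0.0, 1.0), 1.5, 2.2, 0.10,
                 (0.0, 0.0, 0.0), 60.0),
)


def default_activity_specs() -> list[ActivitySpec]:
    """Return the nine default activity specifications (three per band)."""
    return list(_DEFAULT_SPECS)


def band_of(activity: str, specs: list[ActivitySpec] | None = None) -> str:
    """Energy band of an activity name under the given (or default) specs."""
    for s in specs or _DEFAULT_SPECS:
        if s.name == activity:
            return s.energy_band
    raise KeyError(activity)


def generate_trace(spec: ActivitySpec, duration: float, seed: int) -> LabelledTrace:
    """Simulate one single-activity recording of the given duration.

    Accelerometer: ``gravity + amplitude * sin(2*pi*f*t + phase_axis) + noise``
    per axis, sampled at 14 Hz.  Gyroscope: ``mean_rate + noise`` per axis at
    17 Hz.  Identical ``(spec, duration, seed)`` always produces an identical
    trace.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    n_acc = int(np.floor(duration * ACCEL_RATE_HZ))
    n_gyr = int(np.floor(duration * GYRO_RATE_HZ))
    if n_acc < 1 or n_gyr < 1:
        raise ValueError("duration too short for a single sample")

    t_acc = np.arange(n_acc) / ACCEL_RATE_HZ
    t_gyr = np.arange(n_gyr) / GYRO_RATE_HZ

    gravity = np.asarray(spec.gravity_orientation, dtype=float)
    sinus = spec.accel_amplitude * np.sin(
        2.0 * np.pi * spec.accel_frequency * t_acc[:, None] + _AXIS_PHASES[None, :]
    )
    accel = gravity[None, :] + sinus + rng.normal(0.0, spec.accel_noise_sd, (n_acc, 3))

    gyro = np.asarray(spec.gyro_mean_rate, dtype=float)[None, :] + rng.normal(
        0.0, spec.gyro_noise_sd, (n_gyr, 3)
    )

    labels = np.array([spec.name] * n_acc, dtype=object)
    return LabelledTrace(t_acc, accel, t_gyr, gyro, labels)


def concat_traces(traces: list[LabelledTrace]) -> LabelledTrace:
    """Concatenate single-activity traces into one session, shifting times."""
    if not traces:
        raise ValueError("no traces to concatenate")
    at, av, gt, gv, lab = [], [], [], [], []
    offset = 0.0
    for tr in traces:
        at.append(tr.accel_times + offset)
        av.append(tr.accel_samples)
        gt.append(tr.gyro_times + offset)
        gv.append(tr.gyro_samples)
        lab.append(tr.labels)
        end = max(tr.accel_times[-1], tr.gyro_times[-1])
        offset += end + 1.0 / GYRO_RATE_HZ
    return LabelledTrace(
        np.concatenate(at), np.vstack(av), np.concatenate(gt), np.vstack(gv),
        np.concatenate(lab),
    )


def generate_dataset(
    specs: list[ActivitySpec], windows_per_class: int, seed: int
):
    """Generate a class-balanced set of feature-ready sample windows.

    For each activity a single long trace is simulated and cut into
    32-sample windows with 16-sample overlap (both sensor streams attached,
    as during off-line training).  Returns ``(windows, labels)`` with exactly
    ``windows_per_class`` windows per activity; nine default classes at 1000
    windows per class give the 9000-window dataset shape.
    """
    from .windowing import fifo_windows  # deferred: avoid import cycle

    if not specs:
        raise ValueError("empty spec list")
    if windows_per_class < 1:
        raise ValueError("windows_per_class must be >= 1")

    seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
    windows, labels = [], []
    for spec, s in zip(specs, seeds):
        n_samples = 32 + 16 * (windows_per_class - 1)
        duration = (n_samples + 16) / ACCEL_RATE_HZ  # margin for flooring
        trace = generate_trace(spec, duration, int(s))
        ws = fifo_windows(trace, lambda i, span: True)
        took = 0
        for w in ws:
            if took >= windows_per_class:
                break
            windows.append(w)
            labels.append(spec.name)
            took += 1
        if took < windows_per_class:
            raise RuntimeError("trace too short for requested window count")
    return windows, np.array(labels, dtype=object)


# --- CSV trace round-trip -------------------------------------------------
# One row per sample epoch: time_s, sensor in {acc, gyr}, x, y, z, label.
# Values are written with 6 decimal places and round-trip exactly at that
# precision.

def write_trace_csv(trace: LabelledTrace, path, config_hash: str | None = None) -> None:
    rows = []
    for t, (x, y, z), lab in zip(trace.accel_times, trace.accel_samples, trace.labels):
        rows.append((t, "acc", x, y, z, lab))
    for t, (x, y, z) in zip(trace.gyro_times, trace.gyro_samples):
        rows.append((t, "gyr", x, y, z, ""))
    rows.sort(key=lambda r: (r[0], r[1]))
    buf = io.StringIO()
    if config_hash:
        buf.write(f"# config_hash: {config_hash}\n")
    buf.write("time_s,sensor,x,y,z,label\n")
    for t, sensor, x, y, z, lab in rows:
        buf.write(f"{t:.6f},{sensor},{x:.6f},{y:.6f},{z:.6f},{lab}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trace_csv(path) -> LabelledTrace:
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    acc = df[df.sensor == "acc"]
    gyr = df[df.sensor == "gyr"]
    return LabelledTrace(
        acc.time_s.to_numpy(float),
        acc[["x", "y", "z"]].to_numpy(float),
        gyr.time_s.to_numpy(float),
        gyr[["x", "y", "z"]].to_numpy(float),
        acc.label.to_numpy(object),
    )


__all__ = [
    "ACCEL_RATE_HZ",
    "GYRO_RATE_HZ",
    "BANDS",
    "ActivitySpec",
    "LabelledTrace",
    "default_activity_specs",
    "band_of",
    "generate_trace",
    "concat_traces",
    "generate_dataset",
    "write_trace_csv",
    "read_trace_csv",
]
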