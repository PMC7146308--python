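"""FIFO windowing of dual-rate inertial streams.

The accelerometer's on-chip FIFO holds 32 samples; the device processes one
window per FIFO interrupt with a 16-sample overlap between adjacent windows,
so windows start at accelerometer sample indices 0, 16, 32, ...  The window
time span is defined by the accelerometer (32 samples at 14 Hz, ~2.29 s).

The gyroscope runs at its own rate (17 Hz); its samples are aligned to the
accelerometer window by taking those that fall inside the window span,
repeating the last one when fewer than 32 are available and truncating to
the earliest 32 when more are.

Byte accounting uses the converted 16-bit-per-axis representation, under
which a 32-sample triaxial window is 192 bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .synthetic import ACCEL_RATE_HZ, LabelledTrace

WINDOW_SAMPLES = 32
WINDOW_STRIDE = 16
BYTES_PER_AXIS_VALUE = 2  # samples are converted to 16-bit integers


@dataclass
class SampleWindow:
    """One 32-sample processing window (accelerometer mandatory, gyro optional)."""

    accel: np.ndarray  # (32, 3) in g
    gyro: np.ndarray | None  # (32, 3) in deg/s, present only when gated on
    start_time: float
    window_index: int
    label: str | None = None  # majority ground-truth label, if known

    def __post_init__(self) -> None:
        if self.accel.shape != (WINDOW_SAMPLES, 3):
            raise ValueError(f"accel window must be ({WINDOW_SAMPLES}, 3)")
        if self.gyro is not None and self.gyro.shape != (WINDOW_SAMPLES, 3):
            raise ValueError(f"gyro window must be ({WINDOW_SAMPLES}, 3)")


def window_fill_seconds(n_samples: int = WINDOW_SAMPLES,
                        rate_hz: float = ACCEL_RATE_HZ) -> float:
    """Sensing latency: time to fill one FIFO window (32/14 Hz ~ 2.3 s)."""
    return n_samples / rate_hz


def majority_label(labels: np.ndarray) -> str:
    """Majority label of a window; ties broken by earliest occurrence."""
    first_seen: dict = {}
    counts: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    return max(counts, key=lambda lab: (counts[lab], -first_seen[lab]))


def align_gyro(window_span: tuple[float, float], gyro_times: np.ndarray,
               gyro_samples: np.ndarray) -> np.ndarray:
    """Resample the gyro stream onto one window by repetition padding.

    Takes the gyro samples whose timestamps fall in the half-open span
    ``[t0, t1)``; if fewer than 32, the last is repeated; if more, the
    earliest 32 are kept.
    """
    t0, t1 = window_span
    lo = int(np.searchsorted(gyro_times, t0, side="left"))
    hi = int(np.searchsorted(gyro_times, t1, side="left"))
    if hi <= lo:
        raise ValueError("no gyro sample falls inside the window span")
    chunk = gyro_samples[lo:hi]
    if len(chunk) >= WINDOW_SAMPLES:
        return np.array(chunk[:WINDOW_SAMPLES])
    pad = np.repeat(chunk[-1][None, :], WINDOW_SAMPLES - len(chunk), axis=0)
    return np.vstack([chunk, pad])


GatePolicy = Callable[[int, tuple[float, float]], bool]


def fifo_windows(trace: LabelledTrace,
                 with_gyro_policy: GatePolicy) -> Iterator[SampleWindow]:
    """Cut a trace into 32-sample FIFO windows with 16-sample overlap.

    ``with_gyro_policy(window_index, span)`` is consulted lazily as each
    window is built; when it returns True the gyro stream is aligned onto the
    window and attached.  This laziness is what allows a classifier-driven
    gate to decide, window by window, whether gyro data exists.

    A trace shorter than one window yields an empty sequence.
    """
    n = trace.n_accel
    dt = 1.0 / ACCEL_RATE_HZ
    index = 0
    for start in range(0, n - WINDOW_SAMPLES + 1, WINDOW_STRIDE):
        t0 = trace.accel_times[start]
        span = (t0, t0 + WINDOW_SAMPLES * dt)
        gyro = None
        if with_gyro_policy(index, span):
            gyro = align_gyro(span, trace.gyro_times, trace.gyro_samples)
        yield SampleWindow(
            accel=np.array(trace.accel_samples[start:start + WINDOW_SAMPLES]),
            gyro=gyro,
            start_time=t0,
            window_index=index,
            label=majority_label(trace.labels[start:start + WINDOW_SAMPLES]),
        )
        index += 1


def raw_window_bytes(window: SampleWindow | None = None,
                     n_samples: int | None = None) -> int:
    """Byte size of a raw window in the 16-bit converted representation.

    32 samples x 3 axes x 2 bytes = 192 bytes for the standard FIFO window.
    """
    if n_samples is None:
        n_samples = WINDOW_SAMPLES if window is None else len(window.accel)
    return n_samples * 3 * BYTES_PER_AXIS_VALUE


# quantization helpers -- used for debug dumps and byte accounting only;
# feature math runs on the continuous values
def quantize_accel_12bit(values_g: np.ndarray, full_scale_g: float = 8.0) -> np.ndarray:
    """Quantize accelerations to 12-bit codes over +/- full_scale_g."""
    clipped = np.clip(values_g, -full_scale_g, full_scale_g)
    return np.round((clipped + full_scale_g) / (2 * full_scale_g) * 4095).astype(int)


def quantize_gyro_16bit(values_dps: np.ndarray, full_scale_dps: float = 2000.0) -> np.ndarray:
    """Quantize angular rates to 16-bit codes over +/- full_scale_dps."""
    clipped = np.clip(values_dps, -full_scale_dps, full_scale_dps)
    return np.round((clipped + full_scale_dps) / (2 * full_scale_dps) * 65535).astype(int)


__all__ = [
    "WINDOW_SAMPLES",
    "WINDOW_STRIDE",
    "SampleWindow",
    "window_fill_seconds",
    "majority_label",
    "align_gyro",
    "fifo_windows",
    "raw_window_bytes",
    "quantize_accel_12bit",
    "quantize_gyro_16bit",
]
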