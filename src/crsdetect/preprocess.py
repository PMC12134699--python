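"""Gravity separation for raw wrist accelerometer streams.

Wrist-worn IMUs report *total* acceleration: the gesture's linear
acceleration superimposed on the ~9.81 m/s² gravity vector, whose
orientation in the sensor frame drifts slowly as the wrist rotates.
A first-order recursive low-pass filter tracks that slow component,

    g_t = alpha * g_{t-1} + (1 - alpha) * a_t        (per axis)
    linear_t = a_t - g_t

with ``alpha`` controlling responsiveness (0.8 by default, matching the
deployed detector).  Gyroscope channels pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io import ImuSample

__all__ = [
    "GravityFilterState",
    "ProcessedSample",
    "filter_step",
    "process_stream",
    "process_recording_array",
]

DEFAULT_ALPHA = 0.8


@dataclass(frozen=True)
class GravityFilterState:
    """Per-axis gravity estimate and the smoothing constant alpha."""

    alpha: float = DEFAULT_ALPHA
    gravity_estimate: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=float)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        g = np.asarray(self.gravity_estimate, dtype=float)
        if g.shape != (3,):
            raise ValueError(f"gravity_estimate must be a 3-vector, got shape {g.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("gravity_estimate must be finite")
        object.__setattr__(self, "gravity_estimate", g)


@dataclass(frozen=True)
class ProcessedSample:
    """One gravity-free sensor reading: linear acceleration + gyro pass-through."""

    timestamp_s: float
    linear_accel: np.ndarray  # 3-vector, m/s²
    gyro: np.ndarray  # 3-vector, pass-through units


def filter_step(
    state: GravityFilterState, raw_accel: Sequence[float] | np.ndarray
) -> tuple[GravityFilterState, np.ndarray]:
    """Advance the gravity filter by one sample.

    Returns the updated state and the linear acceleration
    ``raw - g_new`` where ``g_new = alpha*g_old + (1-alpha)*raw`` on each
    of the x, y, z axes independently.
    """
    raw = np.asarray(raw_accel, dtype=float)
    if raw.shape != (3,):
        raise ValueError(f"raw_accel must be a 3-vector, got shape {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw_accel must be finite")
    g_new = state.alpha * state.gravity_estimate + (1.0 - state.alpha) * raw
    linear = raw - g_new
    return replace(state, gravity_estimate=g_new), linear


def process_stream(
    samples: Iterable[ImuSample],
    alpha: float = DEFAULT_ALPHA,
    init: str = "first_sample",
) -> list[ProcessedSample]:
    """Run the gravity filter over a time-ordered stream of raw samples.

    The filter state is initialized from the first raw accelerometer
    reading (``init="first_sample"``, the default — the stream then starts
    with zero linear acceleration instead of a decaying g-sized transient)
    or from zeros (``init="zeros"``).  Gyro channels are copied through
    unchanged.  State is owned by the caller's stream: callers processing
    independent recordings should call this once per recording.

    Raises ``ValueError`` naming the offending index if timestamps
    decrease.
    """
    if init not in ("first_sample", "zeros"):
        raise ValueError(f"unknown init mode {init!r}")
    samples = list(samples)
    if not samples:
        return []
    g0 = (
        np.asarray(samples[0].accel, dtype=float)
        if init == "first_sample"
        else np.zeros(3)
    )
    state = GravityFilterState(alpha=alpha, gravity_estimate=g0)
    out: list[ProcessedSample] = []
    prev_t = -np.inf
    for i, s in enumerate(samples):
        if s.timestamp_s < prev_t:
            raise ValueError(
                f"timestamps must be non-decreasing: sample {i} has "
                f"t={s.timestamp_s} after t={prev_t}"
            )
        prev_t = s.timestamp_s
        state, linear = filter_step(state, s.accel)
        out.append(
            ProcessedSample(
                timestamp_s=s.timestamp_s,
                linear_accel=linear,
                gyro=np.asarray(s.gyro, dtype=float).copy(),
            )
        )
    return out


def process_recording_array(
    accel: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    init: str = "first_sample",
) -> np.ndarray:
    """Vectorized gravity removal for an (n, 3) raw-acceleration array.

    Identical to folding :func:`filter_step` over the rows; used by the
    windowing pipeline where samples are already dense arrays.
    """
    a = np.asarray(accel, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"accel must be (n, 3), got {a.shape}")
    if a.shape[0] == 0:
        return a.copy()
    if init == "first_sample":
        g = a[0].copy()
    elif init == "zeros":
        g = np.zeros(3)
    else:
        raise ValueError(f"unknown init mode {init!r}")
    out = np.empty_like(a)
    alpha = float(alpha)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    for i in range(a.shape[0]):
        g = alpha * g + (1.0 - alpha) * a[i]
        out[i] = a[i] - g
    return out
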