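"""Synthetic wrist-IMU gesture simulator.

Emulates the confounding-gesture collection protocol: 16 activities
(15 smoking confounders + smoking itself), each performed for 5 s at
~20 Hz in up to 3 postures (seated / standing / walking) by a cohort of
participants with individual amplitude, tempo and noise variability.

Every gesture is modelled as a phase sequence — rest, raise, a plateau
(mouth-proximal "hold" for hand-to-mouth gestures, "active" otherwise),
lower — repeated ``cycle_count`` times per trial.  Wrist orientation
(pitch toward the mouth, roll for lateral motion) rotates the 9.81 m/s²
gravity vector through the sensor frame; linear acceleration is the
second derivative of the hand trajectory; walking superimposes a ~2 Hz
gait oscillation.  The gyroscope channel is emitted either as angular
rate (default) or as the orientation angles themselves.

The per-class template table (`GESTURE_CLASSES`) is the tunable model of
signal morphology; everything downstream is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GestureClass",
    "ParticipantProfile",
    "ProtocolConfig",
    "GestureRecording",
    "GESTURE_CLASSES",
    "GESTURE_NAMES",
    "SMOKING_CLASS",
    "POSTURES",
    "make_participants",
    "synthesize_trial",
    "synthesize_dataset",
    "trajectory_features",
]

POSTURES = ("seated", "standing", "walking")

GRAVITY = 9.81  # m/s²
_ARM_LEN = 0.28  # m, effective wrist travel scale


@dataclass(frozen=True)
class GestureClass:
    """Kinematic template for one protocol activity."""

    name: str
    is_smoking: bool
    cycle_count_range: tuple[int, int]  # hand-to-mouth repetitions per 5 s trial
    amplitude_scale: float  # unitless, scales linear-acceleration excursion
    rotation_signature: tuple[float, float, float]  # (pitch, roll, yaw) ranges, rad
    hold_fraction: float  # fraction of a cycle spent at the plateau
    lateral_hz: float  # oscillation frequency at the plateau (0 = none)
    mouth_proximal: bool  # plateau is at the mouth/face → phase label "hold"

    def __post_init__(self) -> None:
        lo, hi = self.cycle_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad cycle_count_range {self.cycle_count_range}")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if not (0.0 <= self.hold_fraction < 0.85):
            raise ValueError("hold_fraction must lie in [0, 0.85)")


def _gc(name, smoking, cycles, amp, rot, hold, lat_hz, proximal):
    return GestureClass(name, smoking, cycles, amp, rot, hold, lat_hz, proximal)


# Template table: protocol activity list, lower-cased and underscored.
# Columns: cycles/trial, amplitude, (pitch, roll, yaw) rad, plateau
# fraction, plateau oscillation Hz, mouth-proximal plateau.
GESTURE_CLASSES: dict[str, GestureClass] = {
    g.name: g
    for g in [
        _gc("drinking_without_straw", False, (1, 2), 1.00, (0.95, 0.15, 0.05), 0.45, 0.0, True),
        _gc("drinking_with_straw",    False, (1, 2), 0.80, (0.75, 0.10, 0.05), 0.60, 0.0, True),
        _gc("eating_with_fork",       False, (4, 6), 1.10, (1.05, 0.20, 0.10), 0.20, 0.0, True),
        _gc("eating_without_fork",    False, (3, 5), 1.00, (1.10, 0.30, 0.10), 0.25, 0.0, True),
        _gc("talking_with_hand_gesture", False, (3, 5), 0.90, (0.45, 0.55, 0.25), 0.30, 1.6, False),
        _gc("using_a_phone",          False, (1, 1), 0.90, (1.30, 0.45, 0.20), 0.75, 0.0, True),
        _gc("adjusting_glasses",      False, (1, 2), 0.70, (1.25, 0.20, 0.05), 0.20, 0.0, True),
        _gc("arm_cross",              False, (1, 1), 0.80, (0.40, 0.35, 0.10), 0.70, 0.0, False),
        _gc("scratching_face",        False, (1, 2), 0.80, (1.20, 0.12, 0.05), 0.55, 4.0, True),
        _gc("applying_chapstick",     False, (1, 2), 0.70, (1.18, 0.18, 0.08), 0.50, 3.0, True),
        _gc("yawning",                False, (1, 1), 0.90, (1.05, 0.05, 0.02), 0.50, 0.0, True),
        _gc("pinching_chin",          False, (1, 1), 0.60, (0.95, 0.08, 0.03), 0.65, 0.0, True),
        _gc("wiping_nose",            False, (2, 3), 0.90, (1.22, 0.12, 0.05), 0.15, 0.0, True),
        _gc("messaging_head",         False, (1, 2), 0.80, (1.45, 0.30, 0.15), 0.60, 2.2, True),
        _gc("waving",                 False, (1, 1), 1.00, (0.35, 0.80, 0.10), 0.55, 2.6, False),
        _gc("smoking",                True,  (2, 4), 1.00, (1.15, 0.10, 0.05), 0.35, 0.0, True),
    ]
}

GESTURE_NAMES: tuple[str, ...] = tuple(GESTURE_CLASSES)
SMOKING_CLASS = "smoking"

assert len(GESTURE_NAMES) == 16
assert sum(g.is_smoking for g in GESTURE_CLASSES.values()) == 1


@dataclass(frozen=True)
class ParticipantProfile:
    """Individual variability knobs for one simulated participant."""

    participant_id: str
    amplitude_multiplier: float = 1.0
    tempo_multiplier: float = 1.0
    noise_sd: float = 0.3  # m/s², accelerometer additive noise
    available_postures: tuple[str, ...] = POSTURES

    def __post_init__(self) -> None:
        if self.amplitude_multiplier <= 0 or self.tempo_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.available_postures:
            raise ValueError("available_postures must be non-empty")
        bad = set(self.available_postures) - set(POSTURES)
        if bad:
            raise ValueError(f"unknown postures {sorted(bad)}")


@dataclass(frozen=True)
class ProtocolConfig:
    """Collection-protocol parameters for one synthetic session."""

    n_participants: int = 21
    trial_duration_s: float = 5.0
    sampling_rate_hz: float = 20.0
    seed: int = 0
    noise_sd: float = 0.3  # cohort-level baseline accelerometer noise, m/s²
    gyro_mode: str = "rate"  # "rate" (angular velocity) or "orientation"
    timestamp_jitter: bool = False  # emulate "approximately 20 Hz" timing
    trial_repeats: int = 2  # tiling factor used when windowing 5 s trials

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1, got {self.n_participants}")
        if round(self.trial_duration_s * self.sampling_rate_hz) < 1:
            raise ValueError("trial must contain at least 1 sample")
        if self.gyro_mode not in ("rate", "orientation"):
            raise ValueError(f"gyro_mode must be 'rate' or 'orientation', got {self.gyro_mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class GestureRecording:
    """One labelled trial: dense sample arrays plus metadata.

    ``phases`` holds the generator's own per-sample phase annotation
    (rest / raise / hold / active / lower), used by downstream tests to
    reason about gesture structure without re-deriving kinematics.
    """

    participant_id: str
    activity: str
    posture: str
    timestamps_s: np.ndarray  # (n,)
    accel: np.ndarray  # (n, 3) total acceleration, m/s²
    gyro: np.ndarray  # (n, 3)
    phases: tuple[str, ...] = ()
    sampling_rate_hz: float = 20.0

    @property
    def n_samples(self) -> int:
        return int(self.timestamps_s.shape[0])

    @property
    def is_smoking(self) -> bool:
        return self.activity == SMOKING_CLASS


def trajectory_features(windows: np.ndarray, sampling_rate_hz: float = 20.0) -> np.ndarray:
    """Phase-invariant kinematic summaries of 200×6 windows.

    Reconstructs the pitch trajectory by integrating the pitch-rate gyro
    channel, then summarizes it: peak pitch, elevated duty cycle,
    raise-cycle count, roll energy and roughness, and linear-acceleration
    energy — the coordinates in which the gesture templates differ.
    Used by simple reference classifiers (e.g. nearest-centroid) to
    check that the simulated classes are separable at low noise.
    """
    x = np.asarray(windows, dtype=float)
    gx = x[:, :, 3]
    pitch = np.cumsum(gx, axis=1) / sampling_rate_hz
    rel = pitch / (pitch.max(axis=1, keepdims=True) + 1e-9)
    duty = (rel > 0.7).mean(axis=1)
    cycles = ((rel[:, 1:] > 0.5) & (rel[:, :-1] <= 0.5)).sum(axis=1)
    roll_energy = x[:, :, 4].std(axis=1)
    roll_roughness = np.abs(np.diff(x[:, :, 4], axis=1)).mean(axis=1)
    accel_energy = np.linalg.norm(x[:, :, :3], axis=2).std(axis=1)
    return np.stack(
        [pitch.max(axis=1), duty, cycles, roll_energy, roll_roughness, accel_energy],
        axis=1,
    )


def make_participants(config: ProtocolConfig) -> list[ParticipantProfile]:
    """Draw a deterministic cohort of participant profiles.

    Amplitude and tempo multipliers are log-normal around 1 (sd ≈ 0.12
    and 0.10 on the log scale); per-participant noise scales the
    cohort-level ``config.noise_sd`` log-normally.  IDs follow the study
    convention "SQ01", "SQ02", …  All participants are generated with
    all three postures available; restricted cohorts are constructed by
    replacing profiles explicitly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    out = []
    for i in range(config.n_participants):
        out.append(
            ParticipantProfile(
                participant_id=f"SQ{i + 1:02d}",
                amplitude_multiplier=float(np.exp(rng.normal(0.0, 0.12))),
                tempo_multiplier=float(np.exp(rng.normal(0.0, 0.10))),
                noise_sd=float(config.noise_sd * np.exp(rng.normal(0.0, 0.25))),
                available_postures=POSTURES,
            )
        )
    return out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _phase_schedule(
    n: int, cycles: int, hold_fraction: float, tempo: float
) -> tuple[np.ndarray, list[str]]:
    """Elevation profile e(t) in [0,1] and per-sample phase labels.

    Each cycle is raise → plateau → lower → rest; the plateau takes
    ``hold_fraction`` of the cycle (tempo-scaled), the trailing rest a
    fixed 15%, and raise/lower split the remainder evenly.
    """
    hold = float(np.clip(hold_fraction * tempo, 0.0, 0.8))
    rest = 0.15
    ramp = (1.0 - hold - rest) / 2.0
    e = np.zeros(n)
    labels = ["rest"] * n
    per_cycle = n / cycles
    for c in range(cycles):
        start = c * per_cycle
        u = (np.arange(n) - start) / per_cycle  # position within this cycle
        in_cycle = (u >= 0) & (u < 1)
        raise_m = in_cycle & (u < ramp)
        hold_m = in_cycle & (u >= ramp) & (u < ramp + hold)
        lower_m = in_cycle & (u >= ramp + hold) & (u < ramp + hold + ramp)
        e[raise_m] = _smoothstep(u[raise_m] / ramp)
        e[hold_m] = 1.0
        e[lower_m] = 1.0 - _smoothstep((u[lower_m] - ramp - hold) / ramp)
        for idx in np.nonzero(raise_m)[0]:
            labels[idx] = "raise"
        for idx in np.nonzero(hold_m)[0]:
            labels[idx] = "hold"
        for idx in np.nonzero(lower_m)[0]:
            labels[idx] = "lower"
    return e, labels


def synthesize_trial(
    participant: ParticipantProfile,
    gesture: GestureClass,
    posture: str,
    config: ProtocolConfig,
    seed: int,
) -> GestureRecording:
    """Generate one labelled 5 s trial for (participant, gesture, posture).

    Deterministic given its arguments.  Raises ``ValueError`` if the
    posture is not available to the participant.
    """
    if posture not in participant.available_postures:
        raise ValueError(
            f"posture {posture!r} not available for participant "
            f"{participant.participant_id} (has {participant.available_postures})"
        )
    rng = np.random.default_rng(seed)
    n = config.n_samples_per_trial
    dt = 1.0 / config.sampling_rate_hz
    t = np.arange(n) * dt

    cyc_lo, cyc_hi = gesture.cycle_count_range
    cycles = int(rng.integers(cyc_lo, cyc_hi + 1))
    e, labels = _phase_schedule(n, cycles, gesture.hold_fraction, participant.tempo_multiplier)
    if not gesture.mouth_proximal:
        labels = ["active" if lab == "hold" else lab for lab in labels]

    pitch_max, roll_max, yaw_max = gesture.rotation_signature
    amp = gesture.amplitude_scale * participant.amplitude_multiplier
    pitch = e * pitch_max * participant.amplitude_multiplier
    # plateau oscillation (wave strokes, scratching tremor, …) rides on roll
    osc = np.sin(2.0 * np.pi * gesture.lateral_hz * t) if gesture.lateral_hz > 0 else np.zeros(n)
    roll = roll_max * participant.amplitude_multiplier * (0.3 * e + 0.7 * e * osc)
    yaw = yaw_max * participant.amplitude_multiplier * e * 0.5

    # gravity rotated through the sensor frame; |g| stays exactly 9.81
    grav = GRAVITY * np.stack(
        [
            -np.sin(roll) * np.cos(pitch),
            np.sin(pitch),
            np.cos(roll) * np.cos(pitch),
        ],
        axis=1,
    )

    # linear acceleration from the hand trajectory: second derivatives,
    # peak-normalized so excursions stay in a plausible ±2.5·amp m/s² band
    # (the raw ramp curvature at 20 Hz would otherwise spike unphysically)
    def _accel_profile(pos: np.ndarray, peak: float) -> np.ndarray:
        a = np.gradient(np.gradient(pos, dt), dt)
        m = np.abs(a).max()
        return a * (peak / m) if m > 0 else a

    a_z = _accel_profile(_ARM_LEN * e, 2.2 * amp)
    a_y = _accel_profile(_ARM_LEN * 0.5 * (roll / max(roll_max, 1e-9)), 1.2 * amp)
    linear = np.stack([np.zeros(n), a_y, a_z], axis=1)

    gait = np.zeros((n, 3))
    if posture == "walking":
        stride = 2.0 * np.pi * 1.9 * t + float(rng.uniform(0, 2 * np.pi))
        gait[:, 2] = 1.2 * np.sin(stride)  # vertical bounce, ~2 Hz
        gait[:, 0] = 0.5 * np.sin(0.5 * stride)  # arm swing at stride rate
    elif posture == "standing":
        gait[:, 0] = 0.12 * np.sin(2.0 * np.pi * 0.3 * t + float(rng.uniform(0, 2 * np.pi)))

    accel = grav + linear + gait + rng.normal(0.0, participant.noise_sd, (n, 3))

    angles = np.stack([pitch, roll, yaw], axis=1)
    if config.gyro_mode == "rate":
        gyro = np.gradient(angles, dt, axis=0)
        # light smoothing: a real rate signal is band-limited
        kernel = np.array([0.25, 0.5, 0.25])
        gyro = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, gyro)
    else:
        gyro = angles
    gyro = gyro + rng.normal(0.0, participant.noise_sd * 0.2, (n, 3))

    ts = t.copy()
    if config.timestamp_jitter:
        jitter = rng.uniform(-0.2 * dt, 0.2 * dt, n)
        jitter[0] = abs(jitter[0])  # keep t[0] >= 0
        ts = np.sort(t + jitter)

    return GestureRecording(
        participant_id=participant.participant_id,
        activity=gesture.name,
        posture=posture,
        timestamps_s=ts,
        accel=accel,
        gyro=gyro,
        phases=tuple(labels),
        sampling_rate_hz=config.sampling_rate_hz,
    )


def synthesize_dataset(
    config: ProtocolConfig,
    participants: Sequence[ParticipantProfile] | None = None,
) -> tuple[list[GestureRecording], dict]:
    """Generate one trial per (participant × gesture × available posture).

    Returns the recordings and a manifest dict (per-recording metadata
    plus the label set).  Per-trial seeds are derived from the config
    seed and the trial's cohort coordinates, so the dataset is
    byte-identical across runs for a fixed config.
    """
    if participants is None:
        participants = make_participants(config)
    recordings: list[GestureRecording] = []
    for p_idx, participant in enumerate(participants):
        for g_idx, name in enumerate(GESTURE_NAMES):
            gesture = GESTURE_CLASSES[name]
            for posture in participant.available_postures:
                post_idx = POSTURES.index(posture)
                ss = np.random.SeedSequence([int(config.seed), 7, p_idx, g_idx, post_idx])
                trial_seed = int(ss.generate_state(1)[0] % (2**31))
                recordings.append(
                    synthesize_trial(participant, gesture, posture, config, trial_seed)
                )
    manifest = {
        "n_recordings": len(recordings),
        "activities": sorted({r.activity for r in recordings}),
        "smoking_class": SMOKING_CLASS,
        "recordings": [
            {
                "participant_id": r.participant_id,
                "activity": r.activity,
                "posture": r.posture,
                "n_samples": r.n_samples,
            }
            for r in recordings
        ],
    }
    return recordings, manifest
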