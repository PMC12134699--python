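"""Real-time detection loop and watch↔phone link emulation.

The deployed detector buffers incoming processed samples into two
queues (accelerometer and gyroscope); once both accumulate 200 entries
the window is classified, the buffers drain (tumbling windows), and a
smoking classification emits a notification — unless one was already
sent within the 450 s cooldown (≈ one cigarette per bout), in which
case the detection is logged as ``suppressed`` so the event stream
stays auditable.

The wireless link is modelled as a small state machine mirroring the
app's transport: a 3-way handshake (greeting → acknowledgment →
heartbeat) starts streaming; heartbeats every 3 s keep it alive; 6 s of
heartbeat silence drops the link.  No transport is real — scripts of
timed events drive the machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .preprocess import ProcessedSample

__all__ = [
    "StreamState",
    "LinkState",
    "DetectionEvent",
    "push_samples",
    "simulate_link",
    "link_phase_at",
    "heartbeat_script",
    "run_session",
]

DEFAULT_COOLDOWN_S = 450.0
DEFAULT_WINDOW_LEN = 200
DEFAULT_HEARTBEAT_INTERVAL_S = 3.0
DEFAULT_HEARTBEAT_TIMEOUT_S = 6.0

LINK_PHASES = ("idle", "greeted", "acknowledged", "streaming", "disconnected")


@dataclass(frozen=True)
class DetectionEvent:
    time_s: float
    kind: str  # notification | suppressed | disconnect | reconnect | dropped
    window_index: int
    score: float


@dataclass
class StreamState:
    """Detector buffers and cooldown bookkeeping."""

    window_len: int = DEFAULT_WINDOW_LEN
    cooldown_s: float = DEFAULT_COOLDOWN_S
    smoking_class: int = 1
    accel_queue: list = field(default_factory=list)
    gyro_queue: list = field(default_factory=list)
    last_notification_time_s: float | None = None
    windows_inferred: int = 0
    samples_pushed: int = 0
    last_time_s: float = -np.inf

    @property
    def buffered(self) -> int:
        return len(self.accel_queue)


def push_samples(
    state: StreamState, model, samples: Iterable[ProcessedSample]
) -> tuple[StreamState, list[DetectionEvent]]:
    """Feed processed samples through the tumbling-window detector.

    ``model`` is anything exposing ``classify(window) -> (label, score)``
    (module-level ``crsdetect.model.classify`` bound to a CrsModel, or a
    stub).  Each completed window — both queues at ``window_len`` —
    triggers exactly one inference and drains the buffers.  A smoking
    classification at window-completion time t emits ``notification``
    iff no notification occurred in (t − cooldown_s, t], else
    ``suppressed``.
    """
    events: list[DetectionEvent] = []
    for s in samples:
        if s.timestamp_s < state.last_time_s:
            raise ValueError(
                f"unsorted input: t={s.timestamp_s} after t={state.last_time_s}"
            )
        state.last_time_s = s.timestamp_s
        state.accel_queue.append(np.asarray(s.linear_accel, dtype=np.float32))
        state.gyro_queue.append(np.asarray(s.gyro, dtype=np.float32))
        state.samples_pushed += 1
        if (
            len(state.accel_queue) >= state.window_len
            and len(state.gyro_queue) >= state.window_len
        ):
            accel = np.stack(state.accel_queue[: state.window_len])
            gyro = np.stack(state.gyro_queue[: state.window_len])
            del state.accel_queue[: state.window_len]
            del state.gyro_queue[: state.window_len]
            window = np.concatenate([accel, gyro], axis=1)
            label, score = model.classify(window)
            widx = state.windows_inferred
            state.windows_inferred += 1
            if label == state.smoking_class:
                t = float(s.timestamp_s)
                last = state.last_notification_time_s
                if last is None or t - last >= state.cooldown_s:
                    state.last_notification_time_s = t
                    events.append(DetectionEvent(t, "notification", widx, score))
                else:
                    events.append(DetectionEvent(t, "suppressed", widx, score))
    return state, events


class _BoundModel:
    """Adapts a CrsModel to the classify-duck expected by push_samples."""

    def __init__(self, model):
        self._model = model

    def classify(self, window: np.ndarray) -> tuple[int, float]:
        from .model import classify as _classify

        return _classify(self._model, window)


@dataclass
class LinkState:
    phase: str = "idle"
    heartbeat_interval_s: float = DEFAULT_HEARTBEAT_INTERVAL_S
    heartbeat_timeout_s: float = DEFAULT_HEARTBEAT_TIMEOUT_S
    last_heartbeat_rx_s: float | None = None


def heartbeat_script(
    start_s: float, end_s: float, interval_s: float = DEFAULT_HEARTBEAT_INTERVAL_S
) -> list[tuple[float, str]]:
    """Phone-side keep-alives: one heartbeat every ``interval_s`` seconds."""
    times = np.arange(start_s, end_s, interval_s)
    return [(float(t), "heartbeat") for t in times]


_SCRIPT_EVENTS = {"greeting", "ack", "heartbeat"}


def simulate_link(
    script: Sequence[tuple[float, str]],
    end_time_s: float | None = None,
    heartbeat_timeout_s: float = DEFAULT_HEARTBEAT_TIMEOUT_S,
    heartbeat_interval_s: float = DEFAULT_HEARTBEAT_INTERVAL_S,
) -> list[tuple[float, str]]:
    """Replay a timed protocol script; return the phase-transition trace.

    The trace is a list of (time_s, phase) entries, one per transition,
    starting with (first script time or 0, "idle") implicit — the first
    entry is emitted at the first transition.  Streaming requires the
    full greeting → ack → heartbeat sequence; heartbeat silence longer
    than ``heartbeat_timeout_s`` drops the link at exactly
    ``last_heartbeat + timeout``.  A later greeting restarts the
    handshake (reconnect).
    """
    state = LinkState(
        heartbeat_interval_s=heartbeat_interval_s,
        heartbeat_timeout_s=heartbeat_timeout_s,
    )
    trace: list[tuple[float, str]] = []
    prev_t = -np.inf
    for item in script:
        try:
            t, kind = item
            t = float(t)
        except (TypeError, ValueError):
            raise ValueError(f"malformed script entry {item!r}") from None
        if kind not in _SCRIPT_EVENTS:
            raise ValueError(f"unknown script event {kind!r}")
        if t < prev_t:
            raise ValueError(f"script not time-ordered at t={t}")
        prev_t = t
        _expire(state, t, trace)
        if kind == "greeting" and state.phase in ("idle", "disconnected"):
            state.phase = "greeted"
            trace.append((t, "greeted"))
        elif kind == "ack" and state.phase == "greeted":
            state.phase = "acknowledged"
            trace.append((t, "acknowledged"))
        elif kind == "heartbeat":
            if state.phase == "acknowledged":
                state.phase = "streaming"
                state.last_heartbeat_rx_s = t
                trace.append((t, "streaming"))
            elif state.phase == "streaming":
                state.last_heartbeat_rx_s = t
    if end_time_s is not None:
        _expire(state, float(end_time_s), trace)
    return trace


def _expire(state: LinkState, now: float, trace: list[tuple[float, str]]) -> None:
    if (
        state.phase == "streaming"
        and state.last_heartbeat_rx_s is not None
        and now - state.last_heartbeat_rx_s > state.heartbeat_timeout_s
    ):
        t_drop = state.last_heartbeat_rx_s + state.heartbeat_timeout_s
        state.phase = "disconnected"
        trace.append((t_drop, "disconnected"))


def link_phase_at(trace: Sequence[tuple[float, str]], t: float) -> str:
    """Phase in effect at time t given a transition trace (idle before any)."""
    phase = "idle"
    for tt, p in trace:
        if tt <= t:
            phase = p
        else:
            break
    return phase


def run_session(
    recordings,
    model,
    link_script: Sequence[tuple[float, str]] | None = None,
    window_len: int = DEFAULT_WINDOW_LEN,
    cooldown_s: float = DEFAULT_COOLDOWN_S,
    alpha: float = 0.8,
    smoking_class: int = 1,
) -> dict:
    """Replay recordings end-to-end through link + detector.

    Recordings are concatenated on a single session timeline (each
    trial's samples shifted after the previous trial).  Samples arriving
    while the link is not streaming are dropped and logged.  Returns the
    event log, the smoking count (= notifications), and conservation
    counters.
    """
    from .preprocess import process_stream  # local import avoids cycle at module load
    from .io import recording_to_samples

    if hasattr(model, "classify"):
        bound = model
    else:
        bound = _BoundModel(model)

    state = StreamState(
        window_len=window_len, cooldown_s=cooldown_s, smoking_class=smoking_class
    )
    always_on = link_script is None
    trace = [] if always_on else simulate_link(link_script, end_time_s=None)

    events: list[DetectionEvent] = []
    dropped = 0
    t_offset = 0.0
    total = 0
    for rec in recordings:
        processed = process_stream(recording_to_samples(rec), alpha=alpha)
        for ps in processed:
            t = t_offset + ps.timestamp_s
            total += 1
            if not always_on and link_phase_at(trace, t) != "streaming":
                dropped += 1
                continue
            shifted = ProcessedSample(t, ps.linear_accel, ps.gyro)
            state, evs = push_samples(state, bound, [shifted])
            events.extend(evs)
        t_offset += rec.n_samples / rec.sampling_rate_hz
    smoking_count = sum(1 for e in events if e.kind == "notification")
    return {
        "events": events,
        "smoking_count": smoking_count,
        "windows_inferred": state.windows_inferred,
        "samples_pushed": state.samples_pushed,
        "samples_dropped": dropped,
        "residual_buffered": state.buffered,
        "samples_total": total,
    }
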