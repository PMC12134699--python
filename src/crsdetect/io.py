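"""Sensor-log and manifest file formats.

One recording = one CSV (or JSONL) file with columns
``timestamp_s, ax, ay, az, gx, gy, gz, participant_id, activity, posture``
— the cloud record schema flattened to a local file.  Timestamps are
seconds from stream start, decimal point '.', UTF-8.  A dataset manifest
is a JSON document listing per-recording metadata.

Parsing is strict: a missing column is a schema error, a non-numeric or
non-finite channel value is a parse error naming the line number.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImuSample",
    "SCHEMA_VERSION",
    "SENSOR_LOG_COLUMNS",
    "read_sensor_log",
    "write_sensor_log",
    "write_manifest",
    "read_manifest",
]

SCHEMA_VERSION = "1"

SENSOR_LOG_COLUMNS = (
    "timestamp_s",
    "ax",
    "ay",
    "az",
    "gx",
    "gy",
    "gz",
    "participant_id",
    "activity",
    "posture",
)

_NUMERIC = ("timestamp_s", "ax", "ay", "az", "gx", "gy", "gz")


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped 6-channel reading with metadata.

    ``accel`` is *total* acceleration in m/s² (gravity-inclusive, as the
    watch reports it); ``gyro`` is the 3-axis rotation signal.
    """

    timestamp_s: float
    accel: tuple[float, float, float]
    gyro: tuple[float, float, float]
    participant_id: str = ""
    activity: str = ""
    posture: str = ""

    def __post_init__(self) -> None:
        if self.timestamp_s < 0 or not math.isfinite(self.timestamp_s):
            raise ValueError(f"timestamp_s must be finite and >= 0, got {self.timestamp_s}")
        for name in ("accel", "gyro"):
            v = getattr(self, name)
            if len(v) != 3 or not all(math.isfinite(x) for x in v):
                raise ValueError(f"{name} must be a finite 3-vector, got {v}")


def _sample_to_row(s: ImuSample) -> dict[str, str]:
    return {
        "timestamp_s": repr(float(s.timestamp_s)),
        "ax": repr(float(s.accel[0])),
        "ay": repr(float(s.accel[1])),
        "az": repr(float(s.accel[2])),
        "gx": repr(float(s.gyro[0])),
        "gy": repr(float(s.gyro[1])),
        "gz": repr(float(s.gyro[2])),
        "participant_id": s.participant_id,
        "activity": s.activity,
        "posture": s.posture,
    }


def _row_to_sample(row: dict[str, str], lineno: int) -> ImuSample:
    values = {}
    for col in _NUMERIC:
        raw = row.get(col)
        if raw is None:
            raise ValueError(f"line {lineno}: missing value for column {col!r}")
        try:
            x = float(raw)
        except ValueError:
            raise ValueError(
                f"line {lineno}: non-numeric value {raw!r} in column {col!r}"
            ) from None
        if not math.isfinite(x):
            raise ValueError(f"line {lineno}: non-finite value {raw!r} in column {col!r}")
        values[col] = x
    return ImuSample(
        timestamp_s=values["timestamp_s"],
        accel=(values["ax"], values["ay"], values["az"]),
        gyro=(values["gx"], values["gy"], values["gz"]),
        participant_id=row.get("participant_id", ""),
        activity=row.get("activity", ""),
        posture=row.get("posture", ""),
    )


def write_sensor_log(samples: Iterable[ImuSample], path: str | Path) -> None:
    """Write samples to CSV (or JSONL when the path ends in .jsonl)."""
    path = Path(path)
    samples = list(samples)
    if path.suffix == ".jsonl":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(json.dumps({"schema_version": SCHEMA_VERSION}) + "\n")
            for s in samples:
                rec = {k: (float(v) if k in _NUMERIC else v) for k, v in _sample_to_row(s).items()}
                fh.write(json.dumps(rec) + "\n")
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        writer = csv.DictWriter(fh, fieldnames=SENSOR_LOG_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for s in samples:
            writer.writerow(_sample_to_row(s))


def read_sensor_log(path: str | Path) -> list[ImuSample]:
    """Read a sensor log, preserving order; strict validation.

    Accepts shuffled column order (parsing is header-keyed).  Raises
    ``FileNotFoundError`` for a missing file, ``ValueError`` for a bad
    header or a malformed row (with its line number).
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        out = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                if lineno == 1 and "schema_version" in rec and "timestamp_s" not in rec:
                    continue
                out.append(_row_to_sample({k: str(v) for k, v in rec.items()}, lineno))
        return out
    with open(path, encoding="utf-8", newline="") as fh:
        first = fh.readline()
        offset = 1
        if not first.startswith("#"):
            fh.seek(0)
            offset = 0
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(SENSOR_LOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"schema error: missing columns {sorted(missing)}")
        out = []
        for i, row in enumerate(reader):
            # header occupies one line after the optional '#' comment
            out.append(_row_to_sample(row, lineno=i + 2 + offset))
    return out


def write_manifest(recordings: Sequence, path: str | Path) -> None:
    """Write a JSON manifest: one entry per recording with its metadata.

    ``recordings`` are objects exposing participant_id / activity /
    posture / n_samples (duck-typed; GestureRecording qualifies).
    """
    entries = [
        {
            "participant_id": r.participant_id,
            "activity": r.activity,
            "posture": r.posture,
            "n_samples": int(r.n_samples),
        }
        for r in recordings
    ]
    doc = {"schema_version": SCHEMA_VERSION, "n_recordings": len(entries), "recordings": entries}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_dataset_dir(recordings: Sequence, out_dir: str | Path, fmt: str = "csv") -> Path:
    """Write one sensor log per recording plus manifest.json into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"format must be 'csv' or 'jsonl', got {fmt!r}")
    for rec in recordings:
        name = f"{rec.participant_id}_{rec.activity}_{rec.posture}.{fmt}"
        write_sensor_log(recording_to_samples(rec), out_dir / name)
    write_manifest(recordings, out_dir / "manifest.json")
    return out_dir


def read_dataset_dir(in_dir: str | Path):
    """Rebuild GestureRecording objects from a dataset directory.

    Phase annotations are generator-side only and are not persisted, so
    recordings read back carry empty ``phases``.
    """
    from .gestures import GestureRecording  # avoid import cycle at module load

    in_dir = Path(in_dir)
    manifest = read_manifest(in_dir / "manifest.json")
    recordings = []
    for entry in manifest["recordings"]:
        stem = f"{entry['participant_id']}_{entry['activity']}_{entry['posture']}"
        path = in_dir / f"{stem}.csv"
        if not path.exists():
            path = in_dir / f"{stem}.jsonl"
        samples = read_sensor_log(path)
        ts = np.array([s.timestamp_s for s in samples])
        dt = np.median(np.diff(ts)) if len(ts) > 1 else 0.05
        recordings.append(
            GestureRecording(
                participant_id=entry["participant_id"],
                activity=entry["activity"],
                posture=entry["posture"],
                timestamps_s=ts,
                accel=np.array([s.accel for s in samples]),
                gyro=np.array([s.gyro for s in samples]),
                phases=(),
                sampling_rate_hz=float(1.0 / dt) if dt else 20.0,
            )
        )
    return recordings


def recording_to_samples(recording) -> list[ImuSample]:
    """Flatten a GestureRecording's arrays into ImuSample rows."""
    out = []
    for i in range(recording.n_samples):
        out.append(
            ImuSample(
                timestamp_s=float(recording.timestamps_s[i]),
                accel=tuple(np.asarray(recording.accel[i], dtype=float)),
                gyro=tuple(np.asarray(recording.gyro[i], dtype=float)),
                participant_id=recording.participant_id,
                activity=recording.activity,
                posture=recording.posture,
            )
        )
    return out
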