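"""Dynamic acquisition schedules and time-activity curves.

The dynamic Rb-82 rest acquisition is represented as an ordered list of
contiguous frames.  All curves are *frame-average* activity concentrations
(kBq/mL): list-mode data re-binned into frames are averages over the frame,
not instantaneous samples, so integration over a window is the rectangle
rule on frames.

Time is carried in seconds throughout; clinical flow units (mL/min/g) appear
only at the kinetic reporting boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FramingSchedule",
    "TimeActivityCurve",
    "build_default_schedule",
    "frame_window_sum",
    "read_tac",
    "write_tac",
    "AlignmentError",
    "TacParseError",
]

_BOUNDARY_TOL = 1e-9


class AlignmentError(ValueError):
    """A window or companion curve does not align with the frame grid."""


class TacParseError(ValueError):
    """A TAC file is malformed; the message names the offending line/field."""


@dataclass(frozen=True)
class FramingSchedule:
    """Ordered, contiguous, non-overlapping frame grid.

    ``frames`` is a tuple of ``(start_s, duration_s)`` pairs with
    ``start[0] == 0`` and ``start[i+1] == start[i] + duration[i]``.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("schedule needs at least one frame")
        frames = tuple((float(s), float(d)) for s, d in self.frames)
        object.__setattr__(self, "frames", frames)
        if abs(frames[0][0]) > _BOUNDARY_TOL:
            raise ValueError("first frame must start at 0 s")
        for i, (start, dur) in enumerate(frames):
            if dur <= 0:
                raise ValueError(f"frame {i} has non-positive duration {dur}")
            if i and abs(start - (frames[i - 1][0] + frames[i - 1][1])) > _BOUNDARY_TOL:
                raise ValueError(f"frame {i} is not contiguous with frame {i - 1}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def durations(self) -> np.ndarray:
        return np.array([d for _, d in self.frames])

    @property
    def mids(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def total_duration_s(self) -> float:
        s, d = self.frames[-1]
        return s + d

    def boundary_index(self, t: float) -> int:
        """Index of the frame starting at time ``t`` (or n_frames for the end)."""
        if abs(t - self.total_duration_s) <= _BOUNDARY_TOL:
            return self.n_frames
        hits = np.nonzero(np.abs(self.starts - t) <= _BOUNDARY_TOL)[0]
        if hits.size == 0:
            raise AlignmentError(f"time {t} s is not a frame boundary")
        return int(hits[0])


def build_default_schedule() -> FramingSchedule:
    """The 40-frame rest protocol: 28 x 5 s then 12 x 10 s (260 s total)."""
    frames = []
    t = 0.0
    for dur in [5.0] * 28 + [10.0] * 12:
        frames.append((t, dur))
        t += dur
    return FramingSchedule(tuple(frames))


@dataclass
class TimeActivityCurve:
    """Frame-average activity concentration (kBq/mL) for one region."""

    schedule: FramingSchedule
    values: np.ndarray
    region_label: str = ""
    decay_corrected: bool = True
    noisy: bool = False  # negative excursions are legal only when set

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"values length {self.values.size} != schedule frames "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if not self.noisy and np.any(self.values < 0):
            raise ValueError("negative TAC values require an active noise model")

    def with_values(self, values: Sequence[float], **changes) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


def frame_window_sum(tac: TimeActivityCurve, t0: float, t1: float) -> float:
    """Rectangle-rule integral (kBq*s/mL) of a TAC over the window [t0, t1).

    The window must be aligned to frame boundaries; only frames fully inside
    the window contribute.  No silent interpolation is performed.
    """
    if t1 <= t0:
        raise ValueError("window must have t1 > t0")
    i0 = tac.schedule.boundary_index(t0)
    i1 = tac.schedule.boundary_index(t1)
    dur = tac.schedule.durations[i0:i1]
    return float(np.sum(tac.values[i0:i1] * dur))


# ---------------------------------------------------------------------------
# I/O.  One pinned CSV dialect (header row, comma separator, '.' decimal,
# UTF-8, 6-decimal values) and a JSON dialect that round-trips bit-exactly.
# ---------------------------------------------------------------------------

_CSV_HEADER = ["start_s", "duration_s", "value_kBq_per_mL"]


def write_tac(tac: TimeActivityCurve, path: str | Path, dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        payload = {
            "region_label": tac.region_label,
            "decay_corrected": tac.decay_corrected,
            "noisy": tac.noisy,
            "frames": [[s, d] for s, d in tac.schedule.frames],
            "values": [float(v) for v in tac.values],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")
    elif dialect == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for (s, d), v in zip(tac.schedule.frames, tac.values):
                writer.writerow([f"{s:.6f}", f"{d:.6f}", f"{v:.6f}"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_tac(path: str | Path, dialect: str | None = None) -> TimeActivityCurve:
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "json"
    if dialect == "json":
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise TacParseError(f"{path}: invalid JSON: {exc}") from exc
        for key in ("frames", "values"):
            if key not in payload:
                raise TacParseError(f"{path}: missing field {key!r}")
        if len(payload["values"]) != len(payload["frames"]):
            raise TacParseError(
                f"{path}: {len(payload['values'])} values for "
                f"{len(payload['frames'])} frames"
            )
        schedule = FramingSchedule(tuple((s, d) for s, d in payload["frames"]))
        return TimeActivityCurve(
            schedule=schedule,
            values=np.array(payload["values"], dtype=float),
            region_label=payload.get("region_label", ""),
            decay_corrected=bool(payload.get("decay_corrected", True)),
            noisy=bool(payload.get("noisy", False)),
        )
    if dialect == "csv":
        frames: list[tuple[float, float]] = []
        values: list[float] = []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != _CSV_HEADER:
                raise TacParseError(f"{path}: line 1: expected header {_CSV_HEADER}")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    raise TacParseError(
                        f"{path}: line {lineno}: expected 3 fields, got {len(row)}"
                    )
                parsed = []
                for name, token in zip(_CSV_HEADER, row):
                    try:
                        parsed.append(float(token))
                    except ValueError:
                        raise TacParseError(
                            f"{path}: line {lineno}: field {name!r}: "
                            f"non-numeric token {token!r}"
                        ) from None
                frames.append((parsed[0], parsed[1]))
                values.append(parsed[2])
        if not frames:
            raise TacParseError(f"{path}: no frame rows")
        try:
            schedule = FramingSchedule(tuple(frames))
        except ValueError as exc:
            raise TacParseError(f"{path}: inconsistent frame rows: {exc}") from exc
        vals = np.array(values)
        return TimeActivityCurve(
            schedule=schedule, values=vals, noisy=bool(np.any(vals < 0))
        )
    raise ValueError(f"unknown dialect {dialect!r}")
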