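"""Domain types and on-disk I/O for tele-operation trial recordings.

A *trial* is one surgeon performing one simulation exercise on a
tele-operated surgical console.  It consists of a fixed-rate kinematic
stream (hand-controller, instrument-tip and endoscope positions, in
meters, in a common console frame) and a sparse stream of discrete
system events (camera movement, master clutch, head sensor).  Trials are
stored as a directory of three plain-text files so the streams stay
independently inspectable and diff-able::

    trial_dir/
        kinematics.csv   t,lx,ly,lz,rx,ry,rz,ex,ey,ez,i1x,i1y,i1z[,i2x,...]
        events.csv       t,kind
        meta.json        surgeon_id, group, exercise_id, sample_rate_hz,
                         units ("m"), overall_score (optional)

Time is seconds from trial start; all coordinates are meters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "EVENT_KINDS",
    "KinematicSample",
    "EventRecord",
    "CameraEpisode",
    "TrialRecording",
    "TelemetryFormatError",
    "TelemetryValidationError",
    "group_from_caseload",
    "read_trial",
    "write_trial",
]

#: Experience groups, ordered from least to most experienced.
GROUPS = ("new", "intermediate", "experienced")

#: Closed set of discrete system event kinds.
EVENT_KINDS = (
    "camera_start",
    "camera_stop",
    "clutch_start",
    "clutch_stop",
    "head_in",
    "head_out",
)


class TelemetryFormatError(ValueError):
    """A trial directory is missing files or a file is not parseable."""


class TelemetryValidationError(ValueError):
    """A parsed trial violates a domain invariant."""


def group_from_caseload(n_procedures: int) -> str:
    """Map a robot-assisted-surgery caseload to an experience group.

    Bands: up to 20 procedures -> ``new``, 21-150 -> ``intermediate``,
    above 150 -> ``experienced``.
    """
    if n_procedures < 0:
        raise ValueError("caseload must be non-negative")
    if n_procedures <= 20:
        return "new"
    if n_procedures <= 150:
        return "intermediate"
    return "experienced"


@dataclass(frozen=True)
class KinematicSample:
    """One synchronized kinematic sample (all positions in meters)."""

    t: float
    left_hand: np.ndarray
    right_hand: np.ndarray
    instrument_tips: tuple
    endoscope: np.ndarray


@dataclass(frozen=True)
class EventRecord:
    """One discrete system event at time ``t`` (seconds)."""

    t: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise TelemetryValidationError(
                f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}"
            )


@dataclass(frozen=True, order=True)
class CameraEpisode:
    """One contiguous endoscope movement, ``[start, end]`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise TelemetryValidationError(
                f"episode end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def _as_xyz(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise TelemetryValidationError(f"{name} must have shape (n, 3), got {arr.shape}")
    return arr


class TrialRecording:
    """One surgeon x one exercise: kinematic stream, events, metadata.

    Kinematics are stored as contiguous float arrays (``t``: shape (n,),
    ``left_hand``/``right_hand``/``endoscope``: (n, 3), ``instruments``:
    (n, k, 3) for k >= 1 instrument arms); ``samples`` offers a
    per-sample object view for convenience.  All invariants are checked
    on construction: strictly increasing timestamps, finite coordinates,
    positive duration, group and event kinds from their closed sets,
    events inside the trial span.
    """

    def __init__(
        self,
        surgeon_id: str,
        group: str,
        exercise_id: str,
        sample_rate: float,
        t: Sequence[float],
        left_hand,
        right_hand,
        instruments,
        endoscope,
        events: Sequence[EventRecord] = (),
        overall_score: float | None = None,
    ) -> None:
        if group not in GROUPS:
            raise TelemetryValidationError(
                f"group {group!r} not in {GROUPS}"
            )
        if not (sample_rate > 0):
            raise TelemetryValidationError("sample_rate must be positive")
        self.surgeon_id = str(surgeon_id)
        self.group = group
        self.exercise_id = str(exercise_id)
        self.sample_rate = float(sample_rate)
        self.t = np.asarray(t, dtype=float)
        self.left_hand = _as_xyz(left_hand, "left_hand")
        self.right_hand = _as_xyz(right_hand, "right_hand")
        inst = np.asarray(instruments, dtype=float)
        if inst.ndim == 2:
            inst = inst[:, None, :]
        if inst.ndim != 3 or inst.shape[2] != 3 or inst.shape[1] < 1:
            raise TelemetryValidationError(
                f"instruments must have shape (n, k>=1, 3), got {inst.shape}"
            )
        self.instruments = inst
        self.endoscope = _as_xyz(endoscope, "endoscope")
        self.events = tuple(
            e if isinstance(e, EventRecord) else EventRecord(*e) for e in events
        )
        self.overall_score = None if overall_score is None else float(overall_score)
        self._validate()

    # -- invariants ----------------------------------------------------

    def _validate(self) -> None:
        n = self.t.shape[0]
        if n < 2:
            raise TelemetryValidationError(
                f"trial needs at least 2 samples for a positive duration, got {n}"
            )
        for name, arr in (
            ("left_hand", self.left_hand),
            ("right_hand", self.right_hand),
            ("endoscope", self.endoscope),
            ("instruments", self.instruments),
        ):
            if arr.shape[0] != n:
                raise TelemetryValidationError(
                    f"{name} has {arr.shape[0]} rows but t has {n}"
                )
            if not np.all(np.isfinite(arr)):
                row = int(np.argwhere(~np.isfinite(arr).reshape(n, -1).all(axis=1))[0, 0])
                raise TelemetryValidationError(
                    f"non-finite coordinate in {name} at row {row}"
                )
        if not np.all(np.isfinite(self.t)):
            raise TelemetryValidationError("non-finite timestamp")
        if self.t[0] < 0:
            raise TelemetryValidationError("timestamps must be >= 0")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise TelemetryValidationError(
                f"timestamps not strictly increasing at row {row} "
                f"(t={self.t[row]!r} after t={self.t[row - 1]!r})"
            )
        t_end = float(self.t[-1])
        last = -math.inf
        for i, ev in enumerate(self.events):
            if not (0.0 <= ev.t <= t_end):
                raise TelemetryValidationError(
                    f"event {i} at t={ev.t} outside trial span [0, {t_end}]"
                )
            if ev.t < last:
                raise TelemetryValidationError(f"events not time-ordered at index {i}")
            last = ev.t

    # -- derived views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def n_instruments(self) -> int:
        return int(self.instruments.shape[1])

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])

    @property
    def samples(self) -> Iterator[KinematicSample]:
        for i in range(self.n_samples):
            yield KinematicSample(
                t=float(self.t[i]),
                left_hand=self.left_hand[i],
                right_hand=self.right_hand[i],
                instrument_tips=tuple(self.instruments[i]),
                endoscope=self.endoscope[i],
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecording):
            return NotImplemented
        return (
            self.surgeon_id == other.surgeon_id
            and self.group == other.group
            and self.exercise_id == other.exercise_id
            and self.sample_rate == other.sample_rate
            and self.overall_score == other.overall_score
            and self.events == other.events
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.left_hand, other.left_hand)
            and np.array_equal(self.right_hand, other.right_hand)
            and np.array_equal(self.instruments, other.instruments)
            and np.array_equal(self.endoscope, other.endoscope)
        )

    def __repr__(self) -> str:
        return (
            f"TrialRecording({self.surgeon_id!r}, {self.group!r}, "
            f"{self.exercise_id!r}, n={self.n_samples}, "
            f"duration={self.duration:.3f}s, events={len(self.events)})"
        )


# -- on-disk format -----------------------------------------------------

_META_KEYS = {"surgeon_id", "group", "exercise_id", "sample_rate_hz", "units"}


def _kin_columns(n_instruments: int) -> list[str]:
    cols = ["t", "lx", "ly", "lz", "rx", "ry", "rz", "ex", "ey", "ez"]
    for k in range(1, n_instruments + 1):
        cols += [f"i{k}x", f"i{k}y", f"i{k}z"]
    return cols


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    """Write ``trial`` to directory ``path`` (created if absent).

    Numeric fields are written at full precision (shortest round-trip
    float representation), so ``read_trial(write_trial(...))`` restores
    content exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n, k = trial.n_samples, trial.n_instruments
    data = np.hstack(
        [
            trial.t[:, None],
            trial.left_hand,
            trial.right_hand,
            trial.endoscope,
            trial.instruments.reshape(n, 3 * k),
        ]
    )
    kin = pd.DataFrame(data, columns=_kin_columns(k))
    # %.17g guarantees float64 round-trip to the exact same bits
    kin.to_csv(path / "kinematics.csv", index=False, lineterminator="\n", float_format="%.17g")
    ev = pd.DataFrame(
        {"t": [e.t for e in trial.events], "kind": [e.kind for e in trial.events]}
    )
    ev.to_csv(path / "events.csv", index=False, lineterminator="\n", float_format="%.17g")
    meta = {
        "surgeon_id": trial.surgeon_id,
        "group": trial.group,
        "exercise_id": trial.exercise_id,
        "sample_rate_hz": trial.sample_rate,
        "units": "m",
    }
    if trial.overall_score is not None:
        meta["overall_score"] = trial.overall_score
    (path / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_trial(path: str | Path) -> TrialRecording:
    """Read and validate a trial directory written by :func:`write_trial`."""
    path = Path(path)
    for fname in ("kinematics.csv", "events.csv", "meta.json"):
        if not (path / fname).is_file():
            raise TelemetryFormatError(f"missing {fname} in {path}")
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as exc:
        raise TelemetryFormatError(f"unparseable meta.json in {path}: {exc}") from exc
    missing = _META_KEYS - set(meta)
    if missing:
        raise TelemetryFormatError(f"meta.json missing keys {sorted(missing)}")
    if meta["units"] != "m":
        raise TelemetryValidationError(
            f"unsupported units {meta['units']!r}; positions must be meters ('m')"
        )
    try:
        kin = pd.read_csv(path / "kinematics.csv", float_precision="round_trip")
        ev = pd.read_csv(path / "events.csv", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TelemetryFormatError(f"unparseable CSV in {path}: {exc}") from exc
    fixed = _kin_columns(1)[:10]
    if list(kin.columns[:10]) != fixed:
        raise TelemetryFormatError(
            f"kinematics.csv must start with columns {fixed}, got {list(kin.columns[:10])}"
        )
    extra = list(kin.columns[10:])
    n_inst = len(extra) // 3
    if n_inst < 1 or extra != _kin_columns(n_inst)[10:]:
        raise TelemetryFormatError(
            f"instrument columns malformed: {extra} (expected i1x,i1y,i1z,...)"
        )
    if list(ev.columns) != ["t", "kind"]:
        raise TelemetryFormatError(
            f"events.csv must have columns ['t', 'kind'], got {list(ev.columns)}"
        )
    vals = kin.to_numpy(dtype=float)
    events = [EventRecord(float(t), str(kind)) for t, kind in ev.itertuples(index=False)]
    return TrialRecording(
        surgeon_id=meta["surgeon_id"],
        group=meta["group"],
        exercise_id=meta["exercise_id"],
        sample_rate=float(meta["sample_rate_hz"]),
        t=vals[:, 0],
        left_hand=vals[:, 1:4],
        right_hand=vals[:, 4:7],
        endoscope=vals[:, 7:10],
        instruments=vals[:, 10:].reshape(len(kin), n_inst, 3),
        events=events,
        overall_score=meta.get("overall_score"),
    )
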