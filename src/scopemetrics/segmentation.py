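"""Camera-episode segmentation.

An episode is one contiguous endoscope movement.  Two paths produce the
episode list for a trial:

* **event path** (primary): pair the system's ``camera_start`` /
  ``camera_stop`` markers.  This is the ground truth whenever the
  platform records camera events.
* **kinematic path** (fallback): threshold the smoothed endoscope speed.
  Useful for data sources that log positions but no console events; the
  detector is an approximation and is opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .telemetry import CameraEpisode, EventRecord, TrialRecording

__all__ = [
    "SegmentationConfig",
    "episodes_from_events",
    "episodes_from_kinematics",
    "detect_episodes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tuning knobs of the kinematic fallback detector.

    speed_threshold
        Endoscope speed above which the camera counts as moving (m/s).
        Default 2 mm/s, well below deliberate repositioning speeds but
        above sensor noise at typical sampling rates.
    min_episode
        Candidate episodes shorter than this are discarded (s).
    merge_gap
        Candidate episodes separated by less than this are merged (s).
    smoothing_window
        Odd moving-average window (samples) applied to the speed trace.
    """

    speed_threshold: float = 0.002
    min_episode: float = 0.10
    merge_gap: float = 0.20
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0 or self.min_episode <= 0 or self.merge_gap <= 0:
            raise ValueError("all SegmentationConfig durations/thresholds must be > 0")
        if self.smoothing_window <= 0 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd sample count")


def episodes_from_events(
    events: Sequence[EventRecord], duration: float
) -> list[CameraEpisode]:
    """Pair camera_start/camera_stop markers into episodes.

    Each ``camera_start`` opens an episode closed by the next
    ``camera_stop``.  A stop with no open episode is skipped, a start
    that is never closed is clamped to ``duration``; both log a warning.
    Output is sorted, non-overlapping and clipped to ``[0, duration]``.
    """
    episodes: list[CameraEpisode] = []
    open_start: float | None = None
    for ev in events:
        if ev.kind == "camera_start":
            if open_start is not None:
                logger.warning(
                    "camera_start at t=%.3f while episode open since t=%.3f; ignored",
                    ev.t,
                    open_start,
                )
                continue
            open_start = ev.t
        elif ev.kind == "camera_stop":
            if open_start is None:
                logger.warning(
                    "camera_stop at t=%.3f with no open episode; skipped", ev.t
                )
                continue
            if ev.t > open_start:
                episodes.append(CameraEpisode(open_start, min(ev.t, duration)))
            open_start = None
    if open_start is not None:
        if open_start < duration:
            logger.warning(
                "camera_start at t=%.3f never closed; clamping episode to trial "
                "end t=%.3f",
                open_start,
                duration,
            )
            episodes.append(CameraEpisode(open_start, duration))
        else:
            logger.warning(
                "camera_start at t=%.3f at/after trial end; dropped", open_start
            )
    return episodes


def detect_episodes(
    t: np.ndarray, positions: np.ndarray, config: SegmentationConfig | None = None
) -> list[CameraEpisode]:
    """Detect movement episodes from a sampled 3-D position trace.

    Speed is the centered finite difference of position (edge samples
    replicate their neighbour's value, avoiding the half-sample bias of
    one-sided differences), smoothed by a centered moving average of
    ``smoothing_window`` samples.  Maximal runs with speed above
    ``speed_threshold`` become candidates; candidates separated by less
    than ``merge_gap`` are merged, then candidates shorter than
    ``min_episode`` are discarded.
    """
    config = config or SegmentationConfig()
    t = np.asarray(t, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = t.shape[0]
    if n < 2:
        return []
    speed = np.empty(n)
    # centered differences over [i-1, i+1]; replicate at the two edges
    speed[1:-1] = np.linalg.norm(
        positions[2:] - positions[:-2], axis=1
    ) / (t[2:] - t[:-2])
    speed[0] = speed[1] if n > 2 else np.linalg.norm(
        positions[1] - positions[0]
    ) / (t[1] - t[0])
    speed[-1] = speed[-2]
    w = min(config.smoothing_window, n if n % 2 == 1 else n - 1)
    if w >= 3:
        speed = uniform_filter1d(speed, size=w, mode="nearest")
    moving = speed > config.speed_threshold
    if not moving.any():
        return []
    edges = np.diff(moving.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1)
    if moving[0]:
        starts = np.r_[0, starts]
    if moving[-1]:
        stops = np.r_[stops, n - 1]
    # candidate intervals in time, then merge close ones, then drop short ones
    cand = [(t[i0], t[i1]) for i0, i1 in zip(starts, stops) if t[i1] > t[i0]]
    merged: list[list[float]] = []
    for s, e in cand:
        if merged and s - merged[-1][1] < config.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        CameraEpisode(s, e) for s, e in merged if e - s >= config.min_episode
    ]


def episodes_from_kinematics(
    trial: TrialRecording, config: SegmentationConfig | None = None
) -> list[CameraEpisode]:
    """Run :func:`detect_episodes` on a trial's endoscope trace."""
    return detect_episodes(trial.t, trial.endoscope, config)
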