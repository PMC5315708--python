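"""Per-trial performance metrics.

Camera metrics quantify endoscope control:

* **CFrq** — camera movement frequency: episodes per second over the
  whole exercise.
* **CDur** — mean duration (s) of the camera movements.
* **CInt** — mean interval (s) between consecutive camera movements,
  i.e. the idle viewpoint-hold time from one movement's end to the next
  movement's start.

Conventional efficiency metrics:

* **CompTime** — total exercise duration (s).
* **EOM** — economy of motion: total 3-D path length of all instrument
  tips (m).
* **MWR** — master workspace range: 85 % of the larger of the two
  hand-controller radii, where a hand's radius summarizes the distance
  between its mean position and each sampled position (m).

Trials with no camera episodes have undefined CDur/CInt (reported as
missing, not zero — zero would fake instantaneous movements and bias
group means); downstream statistics exclude missing values pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .telemetry import CameraEpisode, TrialRecording

__all__ = [
    "MetricSet",
    "METRIC_NAMES",
    "CAMERA_METRICS",
    "camera_movement_frequency",
    "camera_movement_duration",
    "camera_movement_interval",
    "completion_time",
    "economy_of_motion",
    "master_workspace_range",
    "compute_metric_set",
    "metric_table",
]

#: All per-trial metric column names, in report order.
METRIC_NAMES = ("cfrq", "cdur", "cint", "comp_time", "eom", "mwr", "overall_score")

#: The three endoscope-control metrics.
CAMERA_METRICS = ("cfrq", "cdur", "cint")


@dataclass(frozen=True)
class MetricSet:
    """The seven per-trial scalars plus the episode count.

    ``cdur``/``cint`` are ``None`` when undefined (no episodes / fewer
    than two episodes).  Invariant: ``cfrq == n_episodes / comp_time``.
    """

    cfrq: float
    cdur: float | None
    cint: float | None
    comp_time: float
    eom: float
    mwr: float
    overall_score: float | None
    n_episodes: int

    def as_dict(self) -> dict:
        return {
            "cfrq": self.cfrq,
            "cdur": self.cdur,
            "cint": self.cint,
            "comp_time": self.comp_time,
            "eom": self.eom,
            "mwr": self.mwr,
            "overall_score": self.overall_score,
            "n_episodes": self.n_episodes,
        }


def camera_movement_frequency(
    episodes: Sequence[CameraEpisode], comp_time: float
) -> float:
    """Episodes per second over the exercise: ``len(episodes) / comp_time``."""
    if not comp_time > 0:
        raise ValueError(f"comp_time must be positive, got {comp_time}")
    return len(episodes) / comp_time


def camera_movement_duration(episodes: Sequence[CameraEpisode]) -> float | None:
    """Mean episode duration in seconds; ``None`` if there are no episodes."""
    if not episodes:
        return None
    return float(np.mean([ep.duration for ep in episodes]))


def camera_movement_interval(episodes: Sequence[CameraEpisode]) -> float | None:
    """Mean end-to-start gap between consecutive episodes.

    ``None`` with fewer than two episodes.  The end-to-start convention
    measures the time during which the endoscope is *not* moving; the
    start-to-start period would double-count durations already captured
    by CDur (use ``cint_mode="period"`` in :func:`compute_metric_set`
    for that convention).
    """
    if len(episodes) < 2:
        return None
    eps = sorted(episodes)
    gaps = [b.start - a.end for a, b in zip(eps, eps[1:])]
    return float(np.mean(gaps))


def _start_to_start_interval(episodes: Sequence[CameraEpisode]) -> float | None:
    if len(episodes) < 2:
        return None
    starts = sorted(ep.start for ep in episodes)
    return float(np.mean(np.diff(starts)))


def completion_time(trial: TrialRecording) -> float:
    """Total exercise duration: last minus first sample timestamp (s)."""
    if trial.n_samples < 2:
        raise ValueError("completion time needs at least 2 samples")
    return trial.duration


def economy_of_motion(trial: TrialRecording) -> float:
    """Total 3-D path length of all instrument tips, in meters.

    Sum over instruments of the Euclidean polyline length of the sampled
    tip trajectory.
    """
    if trial.n_samples < 2:
        raise ValueError("economy of motion needs at least 2 samples")
    steps = np.diff(trial.instruments, axis=0)  # (n-1, k, 3)
    return float(np.linalg.norm(steps, axis=2).sum())


def master_workspace_range(trial: TrialRecording, mode: str = "scaled_max") -> float:
    """Workspace radius of the hand controllers, in meters.

    For each hand, distances from its mean (centroid) position to every
    sample are computed.  ``mode="scaled_max"`` (default, the literal
    definition): 85 % of the larger of the two maximum distances.
    ``mode="percentile"``: the larger of the two 85th-percentile
    distances — the alternative reading in which "85 %" denotes a
    sample-coverage radius.
    """
    if mode not in ("scaled_max", "percentile"):
        raise ValueError(f"unknown MWR mode {mode!r}")
    radii = []
    for hand in (trial.left_hand, trial.right_hand):
        d = np.linalg.norm(hand - hand.mean(axis=0), axis=1)
        radii.append(float(np.max(d)) if mode == "scaled_max" else float(np.percentile(d, 85)))
    r = max(radii)
    return 0.85 * r if mode == "scaled_max" else r


def compute_metric_set(
    trial: TrialRecording,
    episodes: Sequence[CameraEpisode],
    mwr_mode: str = "scaled_max",
    cint_mode: str = "gap",
) -> MetricSet:
    """Assemble the full :class:`MetricSet` for one trial.

    ``episodes`` must come from the same trial (event pairing or the
    kinematic detector).  ``cint_mode``: ``"gap"`` (end-to-start, the
    default) or ``"period"`` (start-to-start).  ``overall_score`` is
    passed through from trial metadata when present.
    """
    if cint_mode not in ("gap", "period"):
        raise ValueError(f"unknown cint_mode {cint_mode!r}")
    ct = completion_time(trial)
    cint = (
        camera_movement_interval(episodes)
        if cint_mode == "gap"
        else _start_to_start_interval(episodes)
    )
    return MetricSet(
        cfrq=camera_movement_frequency(episodes, ct),
        cdur=camera_movement_duration(episodes),
        cint=cint,
        comp_time=ct,
        eom=economy_of_motion(trial),
        mwr=master_workspace_range(trial, mode=mwr_mode),
        overall_score=trial.overall_score,
        n_episodes=len(episodes),
    )


def metric_table(
    trials: Iterable[TrialRecording],
    episodes_for: "callable | None" = None,
    mwr_mode: str = "scaled_max",
    cint_mode: str = "gap",
) -> pd.DataFrame:
    """Compute one metric row per trial and return a tidy DataFrame.

    ``episodes_for`` maps a trial to its episode list; the default pairs
    camera events (see :func:`scopemetrics.segmentation.episodes_from_events`).
    Columns: ``surgeon_id, group, exercise_id`` + :data:`METRIC_NAMES` +
    ``n_episodes``; missing CDur/CInt become NaN.
    """
    from .segmentation import episodes_from_events

    if episodes_for is None:
        episodes_for = lambda tr: episodes_from_events(tr.events, tr.duration)
    rows = []
    for tr in trials:
        ms = compute_metric_set(
            tr, episodes_for(tr), mwr_mode=mwr_mode, cint_mode=cint_mode
        )
        rows.append(
            {
                "surgeon_id": tr.surgeon_id,
                "group": tr.group,
                "exercise_id": tr.exercise_id,
                **{k: (math.nan if v is None else v) for k, v in ms.as_dict().items()},
            }
        )
    cols = ["surgeon_id", "group", "exercise_id", *METRIC_NAMES, "n_episodes"]
    return pd.DataFrame(rows, columns=cols)
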