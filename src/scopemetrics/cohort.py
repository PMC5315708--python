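"""Synthetic surgeon-cohort generator.

Emulates the telemetry statistics of a virtual-reality simulation study
cohort — three experience groups (18 new, 8 intermediate, 13
experienced), one trial per surgeon per exercise — so the full metric +
construct-validity pipeline is testable without access to recorded
human data.

Camera behaviour is an alternating renewal process: idle gaps and
movement durations are independent Gamma variables with means
``target_cint`` and ``target_cdur``, so movement frequency, duration and
interval are independently tunable and the long-run episode rate is
``1/(target_cint + target_cdur)``.  Completion times are lognormal
(strictly positive, right-skewed, as novice timing data are).  A
per-surgeon lognormal skill multiplier (mean one, shared across a
surgeon's exercises) scales gap/duration/completion targets jointly,
producing the between-surgeon spread real groups show and the
within-group correlation implied by a common underlying skill.

Default group profiles are calibrated so group means and dispersions sit
at the scales observed for published simulator cohorts: experienced
surgeons make more frequent, shorter, more closely spaced camera
movements and finish faster than new surgeons.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .telemetry import GROUPS, EventRecord, TrialRecording

__all__ = [
    "EXERCISES",
    "DEFAULT_EXERCISES",
    "GroupProfile",
    "CohortSpec",
    "ScoreBounds",
    "generate_trial",
    "generate_cohort",
    "default_cohort_spec",
    "surrogate_overall_score",
    "attach_surrogate_scores",
    "manifest_hash",
]

logger = logging.getLogger(__name__)

#: The 25 virtual-reality exercise names.
EXERCISES = (
    "Camera Targeting—Level 1",
    "Camera Targeting—Level 2",
    "Dots and Needles—Level 1",
    "Dots and Needles—Level 2",
    "Energy Dissection—Level 1",
    "Energy Dissection—Level 2",
    "Energy Switching—Level 1",
    "Match Board—Level 1",
    "Match Board—Level 2",
    "Match Board—Level 3",
    "Needle Targeting",
    "Peg Board—Level 1",
    "Peg Board—Level 2",
    "Pick and Place",
    "Ring and Rail—Level 1",
    "Ring and Rail—Level 2",
    "Ring Walk—Level 1",
    "Ring Walk—Level 2",
    "Ring Walk—Level 3",
    "Scaling",
    "Suture Sponge—Level 1",
    "Suture Sponge—Level 2",
    "Suture Sponge—Level 3",
    "Thread the Rings",
    "Tubes",
)


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters for one experience group on one exercise.

    ``target_cdur`` / ``target_cint`` are the mean movement duration and
    mean inter-movement gap (s) of the renewal process; ``gap_shape`` /
    ``dur_shape`` are the Gamma shapes (2 by default: mild right skew,
    SD comparable to the mean as observed cohorts show).
    ``mean_comp_time`` / ``cv_comp_time`` parameterize the lognormal
    completion time.  ``path_speed`` is the instrument-tip speed (m/s),
    ``hand_sigma`` the per-axis SD of hand-controller positions about
    their centroid (m), ``endo_speed`` the endoscope speed during
    movements (m/s).  ``between_sd`` is the log-SD of the mean-one
    per-surgeon skill multiplier applied to the timing targets.
    """

    group: str
    mean_comp_time: float
    cv_comp_time: float
    target_cint: float
    target_cdur: float
    gap_shape: float = 2.0
    dur_shape: float = 2.0
    path_speed: float = 0.012
    hand_sigma: float = 0.05
    endo_speed: float = 0.01
    between_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group {self.group!r} not in {GROUPS}")
        positive = {
            "mean_comp_time": self.mean_comp_time,
            "cv_comp_time": self.cv_comp_time,
            "target_cint": self.target_cint,
            "target_cdur": self.target_cdur,
            "gap_shape": self.gap_shape,
            "dur_shape": self.dur_shape,
            "path_speed": self.path_speed,
            "hand_sigma": self.hand_sigma,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.endo_speed < 0 or self.between_sd < 0:
            raise ValueError("endo_speed and between_sd must be >= 0")
        if self.target_cint + self.target_cdur > self.mean_comp_time:
            raise ValueError(
                "mean renewal cycle exceeds mean completion time: "
                f"{self.target_cint} + {self.target_cdur} > {self.mean_comp_time}"
            )

    def scaled(self, z: float) -> "GroupProfile":
        """Profile for a surgeon with latent skill deviation ``z``.

        ``z > 0`` means slower/less practiced: gap, duration and
        completion targets scale by mean-one lognormal multipliers
        ``exp(s·z − s²/2)``; instrument speed and hand spread get
        weaker couplings in the same direction (log-SDs 0.4·s and
        0.2·s, so ``between_sd = 0`` yields a fully homogeneous group).
        """
        s = self.between_sd
        sp, sh = 0.4 * s, 0.2 * s
        m_time = math.exp(s * z - s * s / 2.0)
        m_path = math.exp(sp * z - sp * sp / 2.0)
        m_hand = math.exp(sh * z - sh * sh / 2.0)
        return replace(
            self,
            mean_comp_time=self.mean_comp_time * m_time,
            target_cint=self.target_cint * m_time,
            target_cdur=self.target_cdur * m_time,
            path_speed=self.path_speed * m_path,
            hand_sigma=self.hand_sigma * m_hand,
            between_sd=0.0,
        )


# Default exemplar exercises with timing targets (CDur, CInt means in
# seconds) at the scales observed for new / intermediate / experienced
# groups on simulator cohorts; completion times and motion parameters
# are plausible console dynamics.  hand_base varies per exercise
# (different tasks occupy different workspaces); the new group works a
# slightly wider workspace.
_DEFAULTS: dict[str, dict[str, tuple[float, float, float]]] = {
    # exercise: group -> (target_cdur, target_cint, mean_comp_time)
    "Match Board—Level 1": {
        "new": (1.42, 34.91, 300.0),
        "intermediate": (0.91, 9.99, 200.0),
        "experienced": (0.80, 8.22, 160.0),
    },
    "Peg Board—Level 2": {
        "new": (2.05, 17.65, 300.0),
        "intermediate": (1.05, 5.74, 200.0),
        "experienced": (1.00, 5.75, 160.0),
    },
    "Ring Walk—Level 2": {
        "new": (2.20, 8.36, 240.0),
        "intermediate": (1.62, 5.82, 180.0),
        "experienced": (1.40, 4.75, 150.0),
    },
    "Camera Targeting—Level 2": {
        "new": (1.91, 5.01, 180.0),
        "intermediate": (1.40, 3.19, 140.0),
        "experienced": (1.30, 2.86, 120.0),
    },
    "Suture Sponge—Level 3": {
        "new": (1.36, 37.81, 420.0),
        "intermediate": (0.91, 18.73, 300.0),
        "experienced": (0.71, 20.30, 240.0),
    },
}

_HAND_BASE = {
    "Match Board—Level 1": 0.050,
    "Peg Board—Level 2": 0.060,
    "Ring Walk—Level 2": 0.040,
    "Camera Targeting—Level 2": 0.035,
    "Suture Sponge—Level 3": 0.055,
}

_PATH_SPEED = {"new": 0.015, "intermediate": 0.012, "experienced": 0.011}
_HAND_MULT = {"new": 1.07, "intermediate": 1.02, "experienced": 1.00}

#: Exercises with shipped default profiles.
DEFAULT_EXERCISES = tuple(_DEFAULTS)


def default_profiles() -> dict[str, dict[str, GroupProfile]]:
    """The shipped calibrated profiles: exercise -> group -> profile."""
    out: dict[str, dict[str, GroupProfile]] = {}
    for ex, groups in _DEFAULTS.items():
        out[ex] = {}
        for g, (cdur, cint, comp) in groups.items():
            out[ex][g] = GroupProfile(
                group=g,
                mean_comp_time=comp,
                cv_comp_time=0.15,
                target_cint=cint,
                target_cdur=cdur,
                path_speed=_PATH_SPEED[g],
                hand_sigma=_HAND_BASE[ex] * _HAND_MULT[g],
            )
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``profiles``: exercise -> group -> :class:`GroupProfile`; every
    listed exercise needs a profile for every group.  ``group_sizes``
    follow :data:`~scopemetrics.telemetry.GROUPS` order and default to
    18/8/13.  ``seed`` is mandatory — every downstream sample derives
    from it.
    """

    exercises: tuple[str, ...]
    profiles: Mapping[str, Mapping[str, GroupProfile]]
    seed: int
    group_sizes: tuple[int, int, int] = (18, 8, 13)
    sample_rate: float = 50.0
    n_instruments: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.exercises:
            raise ValueError("at least one exercise required")
        if len(self.group_sizes) != len(GROUPS) or any(
            s < 2 for s in self.group_sizes
        ):
            raise ValueError("each group needs size >= 2 (groups enter t-tests)")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        for ex in self.exercises:
            if ex not in self.profiles:
                raise ValueError(f"no profiles for exercise {ex!r}")
            for g in GROUPS:
                if g not in self.profiles[ex]:
                    raise ValueError(f"no {g!r} profile for exercise {ex!r}")


def default_cohort_spec(
    seed: int,
    exercises: Sequence[str] | None = None,
    group_sizes: tuple[int, int, int] = (18, 8, 13),
    sample_rate: float = 50.0,
) -> CohortSpec:
    """The shipped study conditions: 18/8/13 surgeons, exemplar exercises."""
    profs = default_profiles()
    exercises = tuple(exercises) if exercises is not None else DEFAULT_EXERCISES
    unknown = [e for e in exercises if e not in profs]
    if unknown:
        raise ValueError(
            f"no default profiles for {unknown}; available: {list(profs)}"
        )
    return CohortSpec(
        exercises=exercises,
        profiles=profs,
        seed=int(seed),
        group_sizes=group_sizes,
        sample_rate=sample_rate,
    )


def _draw_episodes(
    rng: np.random.Generator, profile: GroupProfile, duration: float
) -> list[tuple[float, float]]:
    """Alternating renewal process truncated at ``duration``."""
    episodes: list[tuple[float, float]] = []
    t = 0.0
    gap_scale = profile.target_cint / profile.gap_shape
    dur_scale = profile.target_cdur / profile.dur_shape
    while True:
        t += rng.gamma(profile.gap_shape, gap_scale)
        if t >= duration:
            break
        start = t
        t += rng.gamma(profile.dur_shape, dur_scale)
        end = min(t, duration)
        if end > start:
            episodes.append((start, end))
        if t >= duration:
            break
    return episodes


def _smooth_unit_directions(
    rng: np.random.Generator, n: int, window: int
) -> np.ndarray:
    raw = rng.standard_normal((n, 3))
    if window >= 3:
        raw = uniform_filter1d(raw, size=window, axis=0, mode="nearest")
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return raw / norms


def generate_trial(
    profile: GroupProfile,
    surgeon_id: str,
    exercise_id: str,
    seed: "int | np.random.Generator",
    sample_rate: float = 50.0,
    n_instruments: int = 2,
) -> TrialRecording:
    """Generate one synthetic trial from ``profile``.

    Completion time is lognormal with mean ``mean_comp_time`` and CV
    ``cv_comp_time``; camera episodes follow the Gamma alternating
    renewal process truncated at the trial end, with camera_start /
    camera_stop events at episode boundaries.  The endoscope integrates
    ``endo_speed`` along a random constant heading inside each episode
    and is stationary outside; instrument tips move at constant
    ``path_speed`` along smoothly wandering directions (so the path
    length equals speed x duration); hand positions are i.i.d. Gaussian
    about fixed per-hand centroids.  All randomness derives from
    ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig2 = math.log(1.0 + profile.cv_comp_time**2)
    mu = math.log(profile.mean_comp_time) - sig2 / 2.0
    comp_time = float(rng.lognormal(mu, math.sqrt(sig2)))
    dt = 1.0 / sample_rate
    n = max(2, int(math.floor(comp_time * sample_rate)) + 1)
    t = np.arange(n) * dt
    duration = float(t[-1])

    episodes = _draw_episodes(rng, profile, duration)
    events: list[EventRecord] = []
    for s, e in episodes:
        events.append(EventRecord(s, "camera_start"))
        events.append(EventRecord(e, "camera_stop"))

    # endoscope: constant random heading per episode, stationary otherwise
    endo = np.zeros((n, 3))
    endo[:] = (0.0, 0.0, 0.10)
    if episodes and profile.endo_speed > 0:
        starts = np.array([s for s, _ in episodes])
        ends = np.array([e for _, e in episodes])
        headings = rng.standard_normal((len(episodes), 3))
        headings /= np.linalg.norm(headings, axis=1, keepdims=True)
        idx = np.searchsorted(starts, t, side="right") - 1
        safe = np.clip(idx, 0, len(episodes) - 1)
        inside = (idx >= 0) & (t < ends[safe])
        vel = headings[safe] * profile.endo_speed * inside[:, None]
        endo[1:] += np.cumsum(vel[:-1] * dt, axis=0)
    elif episodes:
        # endo_speed 0: events exist but the endoscope never moves
        rng.standard_normal((len(episodes), 3))  # keep stream alignment

    # instruments: constant speed along smoothly wandering unit directions
    window = max(3, int(round(sample_rate)) | 1)
    inst = np.empty((n, n_instruments, 3))
    offsets = np.array([[-0.05, 0.0, 0.0], [0.05, 0.0, 0.0], [0.0, 0.05, 0.0]])
    for k in range(n_instruments):
        dirs = _smooth_unit_directions(rng, n, window)
        pos = np.empty((n, 3))
        pos[0] = offsets[k % 3]
        pos[1:] = pos[0] + np.cumsum(dirs[:-1] * profile.path_speed * dt, axis=0)
        inst[:, k, :] = pos

    left = np.array([-0.15, 0.0, 0.0]) + profile.hand_sigma * rng.standard_normal((n, 3))
    right = np.array([0.15, 0.0, 0.0]) + profile.hand_sigma * rng.standard_normal((n, 3))

    return TrialRecording(
        surgeon_id=surgeon_id,
        group=profile.group,
        exercise_id=exercise_id,
        sample_rate=sample_rate,
        t=t,
        left_hand=left,
        right_hand=right,
        instruments=inst,
        endoscope=endo,
        events=events,
    )


def _profile_dict(p: GroupProfile) -> dict:
    return {
        "group": p.group,
        "mean_comp_time": p.mean_comp_time,
        "cv_comp_time": p.cv_comp_time,
        "target_cint": p.target_cint,
        "target_cdur": p.target_cdur,
        "gap_shape": p.gap_shape,
        "dur_shape": p.dur_shape,
        "path_speed": p.path_speed,
        "hand_sigma": p.hand_sigma,
        "endo_speed": p.endo_speed,
        "between_sd": p.between_sd,
    }


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[TrialRecording], dict]:
    """Generate one trial per surgeon per exercise, plus a manifest.

    Surgeons keep their group assignment (and latent skill multiplier)
    across exercises.  The manifest records the seed, the generating
    parameters of every trial, and a content hash; identical specs give
    identical manifests and byte-identical trials.
    """
    ss = np.random.SeedSequence(spec.seed)
    skill_rng = np.random.default_rng(ss.spawn(1)[0])
    surgeons: list[tuple[str, str, float]] = []  # (id, group, z)
    for g, size in zip(GROUPS, spec.group_sizes):
        for i in range(size):
            z = float(skill_rng.standard_normal())
            surgeons.append((f"{g[:3]}{i + 1:02d}", g, z))
    ids = [s for s, _, _ in surgeons]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate surgeon ids in cohort: {ids}")

    n_trials = len(surgeons) * len(spec.exercises)
    children = ss.spawn(n_trials)
    trials: list[TrialRecording] = []
    manifest_trials = []
    i = 0
    for sid, g, z in surgeons:
        for ex in spec.exercises:
            prof = spec.profiles[ex][g].scaled(z)
            trial = generate_trial(
                prof,
                surgeon_id=sid,
                exercise_id=ex,
                seed=np.random.default_rng(children[i]),
                sample_rate=spec.sample_rate,
                n_instruments=spec.n_instruments,
            )
            trials.append(trial)
            manifest_trials.append(
                {
                    "surgeon_id": sid,
                    "group": g,
                    "exercise_id": ex,
                    "skill_z": z,
                    "spawn_index": i,
                    "profile": _profile_dict(prof),
                }
            )
            i += 1
    manifest = {
        "seed": spec.seed,
        "group_sizes": list(spec.group_sizes),
        "sample_rate": spec.sample_rate,
        "n_instruments": spec.n_instruments,
        "exercises": list(spec.exercises),
        "trials": manifest_trials,
    }
    manifest["config_hash"] = manifest_hash(manifest)
    return trials, manifest


def manifest_hash(manifest: Mapping) -> str:
    """Stable SHA-256 content hash of a manifest (hash field excluded)."""
    clean = {k: v for k, v in manifest.items() if k != "config_hash"}
    blob = json.dumps(clean, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class ScoreBounds:
    """Cohort min/max of completion time and economy of motion."""

    comp_min: float
    comp_max: float
    eom_min: float
    eom_max: float


def surrogate_overall_score(
    comp_time: float, eom: float, bounds: ScoreBounds
) -> float:
    """Documented surrogate composite score in [0, 100].

    The average of ``100·(1 − minmax(comp_time))`` and
    ``100·(1 − minmax(eom))`` over the cohort ranges: fastest, most
    economical trial scores 100; slowest, least economical scores 0.
    This is NOT the simulator vendor's proprietary composite — it is a
    transparent stand-in that correlates positively with skill by
    construction.  A degenerate cohort range contributes a neutral 50
    (with a warning).
    """
    parts = []
    for x, lo, hi, name in (
        (comp_time, bounds.comp_min, bounds.comp_max, "comp_time"),
        (eom, bounds.eom_min, bounds.eom_max, "eom"),
    ):
        if hi > lo:
            parts.append(100.0 * (1.0 - (x - lo) / (hi - lo)))
        else:
            logger.warning("degenerate cohort range for %s; scoring 50", name)
            parts.append(50.0)
    return float(np.mean(parts))


def attach_surrogate_scores(table: "pd.DataFrame") -> "pd.DataFrame":
    """Fill missing ``overall_score`` values with the surrogate.

    Bounds are computed per exercise over the whole cohort (all groups
    pooled), mirroring how a simulator normalizes scores within an
    exercise.  Rows that already carry a recorded score keep it.
    """
    import pandas as pd  # local: keep cohort importable without pandas cost

    table = table.copy()
    if "overall_score" not in table.columns:
        table["overall_score"] = np.nan
    for ex, sub in table.groupby("exercise_id"):
        bounds = ScoreBounds(
            comp_min=float(sub["comp_time"].min()),
            comp_max=float(sub["comp_time"].max()),
            eom_min=float(sub["eom"].min()),
            eom_max=float(sub["eom"].max()),
        )
        mask = sub["overall_score"].isna()
        scores = [
            surrogate_overall_score(ct, e, bounds)
            for ct, e in zip(sub.loc[mask, "comp_time"], sub.loc[mask, "eom"])
        ]
        table.loc[sub.index[mask], "overall_score"] = scores
    return table
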