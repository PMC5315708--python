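"""Pipeline configuration and the simulate → metrics → validity stages.

The YAML config mirrors the library defaults::

    cohort:
      exercises: [...]          # default: the shipped exemplar exercises
      group_sizes: [18, 8, 13]
      sample_rate: 50
      profiles:                 # optional override, exercise -> group -> params
        "Match Board—Level 1":
          new: {mean_comp_time: 300, cv_comp_time: 0.15, ...}
    segmentation:
      speed_threshold: 0.002
      min_episode: 0.10
      merge_gap: 0.20
      smoothing_window: 5
    metrics:
      mwr_mode: scaled_max      # or percentile
      cint_mode: gap            # or period
      kinematic_fallback: false
      surrogate_score: true
    validity:
      alpha: 0.05
      t_variant: student        # or welch

Flags on the CLI override config values; the config hash and seed are
recorded in every output directory's sidecar manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import (
    CohortSpec,
    GroupProfile,
    attach_surrogate_scores,
    default_cohort_spec,
    default_profiles,
    generate_cohort,
    manifest_hash,
)
from .metrics import metric_table
from .report import write_reports
from .segmentation import (
    SegmentationConfig,
    episodes_from_events,
    episodes_from_kinematics,
)
from .telemetry import GROUPS, TrialRecording, read_trial, write_trial

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "cmd_simulate",
    "cmd_metrics",
    "cmd_validity",
    "read_cohort_dir",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline settings (config file + flag overrides)."""

    exercises: tuple[str, ...] | None = None
    group_sizes: tuple[int, int, int] = (18, 8, 13)
    sample_rate: float = 50.0
    profiles: dict | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mwr_mode: str = "scaled_max"
    cint_mode: str = "gap"
    kinematic_fallback: bool = False
    surrogate_score: bool = True
    alpha: float = 0.05
    t_variant: str = "student"

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()

    def cohort_spec(self, seed: int) -> CohortSpec:
        if self.profiles is not None:
            profiles = {
                ex: {
                    g: GroupProfile(group=g, **params)
                    for g, params in by_group.items()
                }
                for ex, by_group in self.profiles.items()
            }
            exercises = self.exercises or tuple(profiles)
            return CohortSpec(
                exercises=tuple(exercises),
                profiles=profiles,
                seed=int(seed),
                group_sizes=self.group_sizes,
                sample_rate=self.sample_rate,
            )
        return default_cohort_spec(
            seed,
            exercises=self.exercises,
            group_sizes=self.group_sizes,
            sample_rate=self.sample_rate,
        )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config, falling back to defaults per key."""
    raw = {}
    if path is not None:
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
    co = raw.get("cohort", {}) or {}
    seg = raw.get("segmentation", {}) or {}
    me = raw.get("metrics", {}) or {}
    va = raw.get("validity", {}) or {}
    try:
        return PipelineConfig(
            exercises=tuple(co["exercises"]) if "exercises" in co else None,
            group_sizes=tuple(co.get("group_sizes", (18, 8, 13))),
            sample_rate=float(co.get("sample_rate", 50.0)),
            profiles=co.get("profiles"),
            segmentation=SegmentationConfig(
                speed_threshold=float(seg.get("speed_threshold", 0.002)),
                min_episode=float(seg.get("min_episode", 0.10)),
                merge_gap=float(seg.get("merge_gap", 0.20)),
                smoothing_window=int(seg.get("smoothing_window", 5)),
            ),
            mwr_mode=me.get("mwr_mode", "scaled_max"),
            cint_mode=me.get("cint_mode", "gap"),
            kinematic_fallback=bool(me.get("kinematic_fallback", False)),
            surrogate_score=bool(me.get("surrogate_score", True)),
            alpha=float(va.get("alpha", 0.05)),
            t_variant=va.get("t_variant", "student"),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def cmd_simulate(
    config: PipelineConfig, seed: int, out_dir: str | Path
) -> tuple[list[TrialRecording], dict]:
    """Generate a cohort and write it as ``out_dir/<surgeon>/<exercise>/``."""
    try:
        spec = config.cohort_spec(seed)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    trials, manifest = generate_cohort(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for tr in trials:
        write_trial(tr, out_dir / tr.surgeon_id / _slug(tr.exercise_id))
    manifest["pipeline_config_hash"] = config.config_hash()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info(
        "simulated %d trials (%d surgeons x %d exercises) into %s",
        len(trials),
        sum(spec.group_sizes),
        len(spec.exercises),
        out_dir,
    )
    return trials, manifest


def read_cohort_dir(cohort_dir: str | Path) -> list[TrialRecording]:
    """Read every ``*/*/`` trial directory under ``cohort_dir``.

    Unreadable trials are skipped with a logged warning; raises only if
    no trial loads.
    """
    cohort_dir = Path(cohort_dir)
    trial_dirs = sorted(p.parent for p in cohort_dir.glob("*/*/meta.json"))
    if not trial_dirs:
        raise ConfigError(f"no trial directories under {cohort_dir}")
    trials = []
    for d in trial_dirs:
        try:
            trials.append(read_trial(d))
        except ValueError as exc:
            logger.warning("skipping unreadable trial %s: %s", d, exc)
    if not trials:
        raise ConfigError(f"all {len(trial_dirs)} trials under {cohort_dir} failed to load")
    return trials


def cmd_metrics(
    config: PipelineConfig,
    trials: Sequence[TrialRecording],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Compute the per-trial metric table (and optionally write it).

    Episodes come from camera events; trials without camera events fall
    back to the kinematic detector only when ``kinematic_fallback`` is
    enabled, otherwise they get zero episodes (CFrq 0, CDur/CInt
    missing) with a logged warning.
    """

    def episodes_for(tr: TrialRecording):
        eps = episodes_from_events(tr.events, tr.duration)
        if not eps and not any(e.kind == "camera_start" for e in tr.events):
            if config.kinematic_fallback:
                eps = episodes_from_kinematics(tr, config.segmentation)
            else:
                logger.warning(
                    "trial %s/%s has no camera events and kinematic fallback is off",
                    tr.surgeon_id,
                    tr.exercise_id,
                )
        return eps

    table = metric_table(
        trials,
        episodes_for=episodes_for,
        mwr_mode=config.mwr_mode,
        cint_mode=config.cint_mode,
    )
    if config.surrogate_score:
        table = attach_surrogate_scores(table)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_path, index=False, lineterminator="\n")
    return table


def cmd_validity(
    config: PipelineConfig,
    table: pd.DataFrame,
    out_dir: str | Path,
    run_info: dict | None = None,
) -> dict:
    """Run the construct-validity analysis and write the report CSVs."""
    present = set(table["group"].unique())
    if len(present & set(GROUPS)) < 2:
        raise ConfigError(
            f"validity analysis needs at least 2 groups, found {sorted(present)}"
        )
    info = dict(run_info or {})
    info["pipeline_config_hash"] = config.config_hash()
    written = write_reports(
        table,
        out_dir,
        alpha=config.alpha,
        variant=config.t_variant,
        run_info=info,
    )
    return {name: str(p) for name, p in written.items()}
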