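"""CSV report writers.

Reports are pure CSV (language-agnostic downstream); provenance (config
hash, seed, comparison counts) goes in a ``run_info.json`` sidecar next
to them rather than in-band, so every report file stays strictly
parseable.

Per camera metric, ``table_<metric>.csv`` mirrors the classical
construct-validity table layout: one row per exercise with group
mean/SD/n, the three pairwise p-values with significance flags, and the
Pearson r (with p) against completion time and overall score.
``discrimination.csv`` carries the normalized new-vs-experienced
difference d per metric with its dispersion, rank, and the pairwise
metric-vs-metric p-value matrix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .metrics import CAMERA_METRICS
from .validity import (
    GROUP_PAIRS,
    discrimination,
    group_comparisons,
    metric_target_correlations,
    validity_summary,
)

__all__ = ["group_table", "discrimination_table", "write_reports"]


def group_table(
    table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    variant: str = "student",
    targets: Sequence[str] = ("comp_time", "overall_score"),
) -> pd.DataFrame:
    """One construct-validity report row per exercise for ``metric``."""
    corr = {
        (c.exercise_id, c.target): c
        for c in metric_target_correlations(table, [metric], targets)
    }
    rows = []
    for ex in sorted(table["exercise_id"].unique()):
        gc = group_comparisons(table, metric, ex, variant=variant)
        row: dict = {"exercise_id": ex, "metric": metric}
        for g in ("new", "intermediate", "experienced"):
            row[f"{g}_mean"] = gc.means[g]
            row[f"{g}_sd"] = gc.sds[g]
            row[f"{g}_n"] = gc.ns[g]
        for a, b in GROUP_PAIRS:
            res = gc.tests[(a, b)]
            row[f"p_{a}_vs_{b}"] = res.p
            row[f"sig_{a}_vs_{b}"] = bool(res.ok and res.p < alpha)
        for tgt in targets:
            c = corr[(ex, tgt)]
            row[f"r_{tgt}"] = c.r
            row[f"p_{tgt}"] = c.p
            row[f"sig_{tgt}"] = bool(c.ok and c.p < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def discrimination_table(
    table: pd.DataFrame,
    metrics: Sequence[str] = ("cfrq", "cdur", "cint", "comp_time", "eom", "mwr"),
    group_pair: tuple[str, str] = ("new", "experienced"),
) -> pd.DataFrame:
    """Ranked discrimination indices with the pairwise p matrix."""
    results = discrimination(table, metrics=metrics, group_pair=group_pair)
    present = [r.metric for r in results]
    rows = []
    for r in results:
        row = {
            "metric": r.metric,
            "d": r.d,
            "sd": r.sd,
            "rank": r.rank,
            "n_exercises": len(r.d_i),
        }
        for other in present:
            if other != r.metric:
                row[f"p_vs_{other}"] = r.pairwise_p.get(other)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(
    table: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = 0.05,
    variant: str = "student",
    camera_metrics: Sequence[str] = CAMERA_METRICS,
    run_info: Mapping | None = None,
) -> dict[str, Path]:
    """Write the full report set under ``out_dir``; returns written paths.

    Files: ``table_<metric>.csv`` per camera metric,
    ``discrimination.csv`` (skipped with a warning when fewer than two
    exercises are present), ``validity_summary.csv``, ``run_info.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    n_comparisons = 0
    for m in camera_metrics:
        gt = group_table(table, m, alpha=alpha, variant=variant)
        path = out_dir / f"table_{m}.csv"
        gt.to_csv(path, index=False, lineterminator="\n")
        written[f"table_{m}"] = path
        n_comparisons += len(gt) * (len(GROUP_PAIRS) + 2)
    n_exercises = table["exercise_id"].nunique()
    if n_exercises >= 2:
        dt = discrimination_table(table)
        path = out_dir / "discrimination.csv"
        dt.to_csv(path, index=False, lineterminator="\n")
        written["discrimination"] = path
    else:
        import logging

        logging.getLogger(__name__).warning(
            "discrimination skipped: needs >= 2 exercises, got %d", n_exercises
        )
    vs = validity_summary(table, alpha=alpha, variant=variant)
    path = out_dir / "validity_summary.csv"
    vs.to_csv(path, index=False, lineterminator="\n")
    written["validity_summary"] = path
    info = dict(run_info or {})
    info.update(
        {
            "alpha": alpha,
            "t_variant": variant,
            "n_exercises": int(n_exercises),
            "n_trials": int(len(table)),
            "n_group_comparisons": int(n_comparisons),
            "multiple_testing_correction": "none",
        }
    )
    (out_dir / "run_info.json").write_text(json.dumps(info, indent=2) + "\n")
    written["run_info"] = out_dir / "run_info.json"
    return written
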