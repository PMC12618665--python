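"""Per-participant accuracy, confidence, timing and feature-usage summaries.

MAE is computed in weeks internally and reported in days (x7). Aggregate
MAE across participants is the unweighted mean of per-participant MAEs,
with the across-participant SD alongside; the pooled per-estimate
dispersion is reported separately where asked for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import StudyTable, STAGES

__all__ = [
    "ParticipantStageMetrics",
    "FeatureUsage",
    "TimingSummary",
    "mae_days",
    "delta_mae",
    "aggregate_mae_days",
    "confidence_distribution",
    "feature_usage_summary",
    "timing_summary",
    "metrics_table",
]

WEEK_DAYS = 7.0


@dataclass(frozen=True)
class ParticipantStageMetrics:
    participant_id: str
    stage: int
    mae_days: float
    confidence_mean: float
    time_mean_sec: float
    n: int


def _stage_df(table: StudyTable, participant_id: str | None, stage: int) -> pd.DataFrame:
    df = table.estimates_df()
    mask = df["stage"] == stage
    if participant_id is not None:
        mask &= df["participant_id"] == participant_id
    sub = df[mask]
    if sub.empty:
        who = f"participant {participant_id!r}" if participant_id else "any participant"
        raise ValueError(f"no stage-{stage} records for {who}")
    return sub


def mae_days(table: StudyTable, participant_id: str, stage: int) -> float:
    """Mean absolute error of the participant's estimates at ``stage``,
    in days."""
    sub = _stage_df(table, participant_id, stage)
    return float((sub["estimate_weeks"] - sub["true_ga_weeks"]).abs().mean() * WEEK_DAYS)


def delta_mae(table: StudyTable, participant_id: str, stage_a: int, stage_b: int) -> float:
    """MAE(stage_b) - MAE(stage_a) in days; negative means stage_b
    improved on stage_a."""
    return mae_days(table, participant_id, stage_b) - mae_days(table, participant_id, stage_a)


def aggregate_mae_days(table: StudyTable, stage: int) -> dict[str, float]:
    """Participant-level aggregate MAE at ``stage``: the unweighted mean
    and SD (ddof=1) of per-participant MAEs, plus the pooled per-estimate
    mean and SD of absolute errors."""
    per = np.array([mae_days(table, pid, stage) for pid in table.participants()])
    sub = _stage_df(table, None, stage)
    abs_err_days = (sub["estimate_weeks"] - sub["true_ga_weeks"]).abs() * WEEK_DAYS
    return {
        "mean_days": float(per.mean()),
        "sd_days": float(per.std(ddof=1)) if len(per) > 1 else float("nan"),
        "pooled_mean_days": float(abs_err_days.mean()),
        "pooled_sd_days": float(abs_err_days.std(ddof=1)),
        "n_participants": float(len(per)),
    }


def confidence_distribution(
    table: StudyTable, stage: int, participant_subset: list[str] | None = None
) -> np.ndarray:
    """Histogram of confidence scores 1..5 at ``stage``, optionally
    restricted to a subset of participants. Returns a length-5 count
    vector (all zeros for an empty subset)."""
    df = table.estimates_df()
    mask = df["stage"] == stage
    if participant_subset is not None:
        mask &= df["participant_id"].isin(list(participant_subset))
    conf = df.loc[mask, "confidence"]
    return np.array([int((conf == level).sum()) for level in range(1, 6)])


@dataclass(frozen=True)
class FeatureUsage:
    """Stage-1 feature annotations: how many features back each estimate
    and how broad each participant's feature repertoire is."""

    per_image_mean: float
    per_image_sd: float
    repertoire: dict[str, int]

    @property
    def repertoire_mean(self) -> float:
        if not self.repertoire:
            return 0.0
        return float(np.mean(list(self.repertoire.values())))


def feature_usage_summary(table: StudyTable) -> FeatureUsage:
    stage1 = [r for r in table.estimates if r.stage == 1]
    counts = np.array([len(r.features) for r in stage1], dtype=float)
    repertoire: dict[str, set[str]] = {}
    for r in stage1:
        repertoire.setdefault(r.participant_id, set()).update(r.features)
    per_image_mean = float(counts.mean()) if counts.size else 0.0
    per_image_sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return FeatureUsage(
        per_image_mean=per_image_mean,
        per_image_sd=per_image_sd,
        repertoire={pid: len(feats) for pid, feats in sorted(repertoire.items())},
    )


@dataclass(frozen=True)
class TimingSummary:
    """Mean/SD of per-estimate times at one stage. Stage 1 is flagged
    non-comparable: participants did extra annotation work there."""

    stage: int
    mean_sec: float
    sd_sec: float
    n: int
    comparable: bool


def timing_summary(table: StudyTable, stage: int) -> TimingSummary:
    sub = _stage_df(table, None, stage)
    times = sub["time_sec"]
    return TimingSummary(
        stage=stage,
        mean_sec=float(times.mean()),
        sd_sec=float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        n=int(len(times)),
        comparable=stage != 1,
    )


def metrics_table(table: StudyTable) -> pd.DataFrame:
    """One row per participant x stage with the ParticipantStageMetrics
    fields (the metrics.csv payload)."""
    rows = []
    for pid in table.participants():
        for stage in STAGES:
            sub = _stage_df(table, pid, stage)
            rows.append(
                {
                    "participant_id": pid,
                    "stage": stage,
                    "mae_days": float(
                        (sub["estimate_weeks"] - sub["true_ga_weeks"]).abs().mean()
                        * WEEK_DAYS
                    ),
                    "confidence_mean": float(sub["confidence"].mean()),
                    "time_mean_sec": float(sub["time_sec"].mean()),
                    "n": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)
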