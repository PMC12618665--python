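"""Reliance metrics for advice-taking in the judge-advisor paradigm.

Three behavioural measures of how much a participant's revised estimate is
influenced by the model's advice:

* **Weight of Advice (WoA)** — the fraction of the distance from the prior
  estimate to the model's estimate that the participant moved::

      WoA = (prior - posterior) / (prior - model)

  0 means the estimate was unchanged, 1 that it matches the model, 0.5 that
  it is the mean of the two; negative values mean movement away, values
  above 1 overshoot. Images where the prior is already within 1 week of the
  model's estimate are excluded: the model's 2-week prediction intervals
  mean prior and model already agree there, and the ratio degenerates.

* **Agreement** — the proportion of a participant's estimates that fall
  inside the model's predicted GA bin. No exclusion rule applies.

* **Reliance type** — each image is classified as appropriate reliance,
  under-reliance, or over-reliance by comparing behaviour (did the revised
  estimate move strictly closer to the model?) against warrant (was the
  model strictly more accurate than the unaided estimate?). Ties in either
  comparison resolve to "did not rely" / "model not better".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data_model import StudyTable

__all__ = [
    "WoAResult",
    "MeanWoA",
    "RelianceLabel",
    "RelianceSummary",
    "weight_of_advice",
    "mean_woa",
    "classify_reliance",
    "reliance_proportions",
    "agreement",
    "log_ratio",
    "log_count_ratio",
    "APPROPRIATE",
    "UNDER",
    "OVER",
]

DEFAULT_EXCLUSION_WEEKS = 1.0

APPROPRIATE = "appropriate"
UNDER = "under"
OVER = "over"


@dataclass(frozen=True)
class WoAResult:
    """Weight of Advice for one image, or an explicit exclusion marker."""

    prior_weeks: float
    posterior_weeks: float
    model_weeks: float
    value: float | None
    excluded: bool


def weight_of_advice(
    prior: float,
    posterior: float,
    model: float,
    *,
    exclusion_weeks: float = DEFAULT_EXCLUSION_WEEKS,
) -> WoAResult:
    """WoA = (prior - posterior) / (prior - model); excluded when
    |prior - model| < ``exclusion_weeks`` (which also covers the zero
    denominator)."""
    if abs(prior - model) < exclusion_weeks:
        return WoAResult(prior, posterior, model, value=None, excluded=True)
    value = (prior - posterior) / (prior - model) + 0.0  # -0.0 -> 0.0
    return WoAResult(prior, posterior, model, value=value, excluded=False)


@dataclass(frozen=True)
class MeanWoA:
    """Per-participant mean WoA over non-excluded images at one stage.
    ``mean`` is None when every image was excluded."""

    participant_id: str
    stage: int
    mean: float | None
    n_included: int
    n_excluded: int


def _stage_rows(table: StudyTable, participant_id: str, stage: int, prior_stage: int):
    """Yield (image_id, y, prior, posterior, prediction) for one
    participant, pairing the prior-stage estimate with the target-stage
    estimate image by image."""
    if stage not in (2, 3):
        raise ValueError(f"posterior stage must be 2 or 3, got {stage}")
    prior_est = {
        r.image_id: r.estimate_weeks
        for r in table.estimates
        if r.participant_id == participant_id and r.stage == prior_stage
    }
    post = [
        r
        for r in table.estimates
        if r.participant_id == participant_id and r.stage == stage
    ]
    if not prior_est or not post:
        raise ValueError(
            f"participant {participant_id!r} lacks stage-{prior_stage} or "
            f"stage-{stage} records"
        )
    for r in sorted(post, key=lambda r: r.image_id):
        yield r.image_id, r.true_ga_weeks, prior_est[r.image_id], r.estimate_weeks, (
            table.prediction_for(r.image_id)
        )


def mean_woa(
    table: StudyTable,
    participant_id: str,
    stage: int,
    *,
    prior_stage: int = 1,
    exclusion_weeks: float = DEFAULT_EXCLUSION_WEEKS,
) -> MeanWoA:
    """Arithmetic mean of non-excluded per-image WoA values at ``stage``.

    The prior is the stage-1 estimate by default (the estimate made before
    any model information was seen), for stage-3 as well as stage-2;
    pass ``prior_stage=2`` to use the prediction-only estimate as the
    stage-3 prior instead.
    """
    values = []
    n_excluded = 0
    for _img, _y, prior, posterior, pred in _stage_rows(
        table, participant_id, stage, prior_stage
    ):
        res = weight_of_advice(
            prior, posterior, pred.point_weeks, exclusion_weeks=exclusion_weeks
        )
        if res.excluded:
            n_excluded += 1
        else:
            values.append(res.value)
    mean = sum(values) / len(values) if values else None
    return MeanWoA(participant_id, stage, mean, len(values), n_excluded)


@dataclass(frozen=True)
class RelianceLabel:
    """Reliance classification for one image.

    ``relied`` is 1 iff the revised estimate is strictly closer to the
    model (delta2 < delta1); ``model_better`` is 1 iff the model's error is
    strictly smaller than the unaided estimate's (eps_m < eps_p1). The
    label is appropriate when the two agree, under-reliance when warranted
    reliance did not happen, over-reliance when unwarranted reliance did.
    """

    relied: int
    model_better: int
    label: str
    eps_p1: float
    eps_p2: float
    eps_m: float
    delta1: float
    delta2: float


def classify_reliance(y: float, p1: float, p2: float, m: float) -> RelianceLabel:
    """Classify one image given truth ``y``, unaided estimate ``p1``,
    revised estimate ``p2`` and model estimate ``m`` (all weeks)."""
    eps_p1 = abs(p1 - y)
    eps_p2 = abs(p2 - y)
    eps_m = abs(m - y)
    delta1 = abs(p1 - m)
    delta2 = abs(p2 - m)
    relied = 1 if delta2 < delta1 else 0
    model_better = 1 if eps_m < eps_p1 else 0
    if relied == model_better:
        label = APPROPRIATE
    elif relied == 0:
        label = UNDER
    else:
        label = OVER
    return RelianceLabel(relied, model_better, label, eps_p1, eps_p2, eps_m, delta1, delta2)


@dataclass(frozen=True)
class RelianceSummary:
    """Per-participant reliance-type counts and proportions at one stage."""

    participant_id: str
    stage: int
    n_appropriate: int
    n_under: int
    n_over: int

    @property
    def n(self) -> int:
        return self.n_appropriate + self.n_under + self.n_over

    @property
    def p_appropriate(self) -> float:
        return self.n_appropriate / self.n

    @property
    def p_under(self) -> float:
        return self.n_under / self.n

    @property
    def p_over(self) -> float:
        return self.n_over / self.n


def reliance_proportions(
    table: StudyTable, participant_id: str, stage: int, *, prior_stage: int = 1
) -> RelianceSummary:
    """Reliance-type proportions over all of a participant's images at
    ``stage`` (2 or 3). Every image counts: the WoA exclusion rule does not
    apply to reliance typing."""
    counts = {APPROPRIATE: 0, UNDER: 0, OVER: 0}
    n = 0
    for _img, y, prior, posterior, pred in _stage_rows(
        table, participant_id, stage, prior_stage
    ):
        counts[classify_reliance(y, prior, posterior, pred.point_weeks).label] += 1
        n += 1
    if n == 0:
        raise ValueError(f"no stage-{stage} images for participant {participant_id!r}")
    return RelianceSummary(
        participant_id, stage, counts[APPROPRIATE], counts[UNDER], counts[OVER]
    )


def agreement(table: StudyTable, participant_id: str, stage: int) -> float:
    """Fraction of the participant's estimates at ``stage`` that lie inside
    the model's predicted bin (half-open bins; the scheme's last bin is
    closed on the right)."""
    records = [
        r
        for r in table.estimates
        if r.participant_id == participant_id and r.stage == stage
    ]
    if not records:
        raise ValueError(f"no stage-{stage} records for participant {participant_id!r}")
    hits = 0
    for r in records:
        pred = table.prediction_for(r.image_id)
        if table.bin_scheme.membership(pred.bin, r.estimate_weeks):
            hits += 1
    return hits / len(records)


def log_ratio(p_a: float, p_b: float) -> float:
    """Natural log of the ratio of two proportions.

    Raises ValueError when either proportion is non-positive; use
    :func:`log_count_ratio` when zero counts are possible.
    """
    if p_a <= 0 or p_b <= 0:
        raise ValueError(f"log_ratio requires positive proportions, got ({p_a}, {p_b})")
    return math.log(p_a / p_b)


def log_count_ratio(count_a: int, count_b: int) -> float:
    """ln((count_a + 1/2) / (count_b + 1/2)): the log ratio of the
    corresponding proportions with a Haldane half-count added to both
    counts, so zero counts stay finite. Undefined (ValueError) only when
    either count is negative."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    return math.log((count_a + 0.5) / (count_b + 0.5))
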