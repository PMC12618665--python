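"""Behavioral simulator for three-stage reader studies of AI advice-taking.

Generates study tables with the statistical structure of a real reader
study: ~uniform true GA over 13-42 weeks, a binned model whose point
predictions have heavy-tailed error (mostly accurate, occasionally far
off), and a heterogeneous population of participants who anchor on their
own unaided estimate and move a participant-specific fraction of the way
toward the model's advice.

Population structure
--------------------
* Advice-taking is bimodal: a *deferring* majority moves almost all the
  way to the model's estimate, a *sceptical* minority barely moves. This
  is what lets mean agreement (~0.70) and mean Weight of Advice (~0.65)
  coexist with a wide per-participant agreement spread.
* Explanation response is a binary per-participant latent (``helped``,
  half the population by default). In stage 3 helped participants refine
  their own assessment (their intrinsic error shrinks), lean slightly more
  toward an error-optimal blend with the advice, and discount advice whose
  explanation is visibly incoherent (catching the model's occasional gross
  failures). Hindered participants lean slightly less on the advice and
  pick up confusion noise both in their own reading and in how they read
  the advice.
* Confidence is an ordinal response: a latent participant anchor plus a
  stage effect, thresholded at fixed cutpoints; helped participants'
  stage-3 latent variance grows (confidence polarises away from the
  middle) rather than shifting in mean.

Randomness is a single integer seed: per-participant substreams are
spawned deterministically so adding a participant never perturbs the
records of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    BinScheme,
    EstimateRecord,
    LikertResponse,
    ModelPrediction,
    StudyTable,
    default_bin_scheme,
)

__all__ = [
    "ParticipantProfile",
    "ModelErrorConfig",
    "PopulationConfig",
    "ConfidenceConfig",
    "TimingConfig",
    "LikertConfig",
    "SimulationConfig",
    "SimulationResult",
    "default_config",
    "sample_images",
    "sample_population",
    "simulate_participant",
    "simulate_study",
    "generate_study",
]

ESTIMATE_CLIP = (10.0, 45.0)

FEATURE_VOCABULARY = (
    "skull_shape",
    "skull_ossification",
    "head_size",
    "brain_ventricles",
    "cavum_septi_pellucidi",
    "cerebellum",
    "choroid_plexus",
    "sylvian_fissure",
    "midline_falx",
    "cortical_folding",
    "orbits",
    "image_texture",
)


# ---------------------------------------------------------------------------
# Configuration


class ModelErrorConfig(BaseModel):
    """Two-component normal mixture for the model's raw prediction error
    (weeks): a tight core plus an occasional gross failure. The heavy tail
    is needed to combine a small MAE with a much larger per-estimate SD."""

    core_sd_weeks: float = Field(1.12, ge=0)
    gross_sd_weeks: float = Field(6.8, ge=0)
    gross_prob: float = Field(0.10, ge=0, le=1)


class PopulationConfig(BaseModel):
    """Hyperparameters of the participant population.

    Sceptical participants carry a noise multiplier on their unaided
    estimates: the population correlates low advice-taking with larger
    unaided error, which is what keeps group-mean aided error well above
    the model's own error even at high mean agreement.
    """

    bias_sd_weeks: float = Field(1.0, ge=0)
    noise_sd_mean_weeks: float = Field(3.75, ge=0)
    noise_sd_spread_weeks: float = Field(0.6, ge=0)

    # bimodal advice-taking
    deferring_fraction: float = Field(0.66, ge=0, le=1)
    advice_weight_deferring_mean: float = Field(0.97, ge=0, le=1)
    advice_weight_deferring_sd: float = Field(0.03, ge=0)
    advice_weight_sceptical_mean: float = Field(0.05, ge=0, le=1)
    advice_weight_sceptical_sd: float = Field(0.05, ge=0)
    sceptical_noise_multiplier: float = Field(1.35, ge=1)

    revision_noise_sd_weeks: float = Field(0.4, ge=0)

    # stage-3 explanation response: helped participants move their advice
    # weight part of the way toward an error-optimal blend, refine their
    # own reading, and discount advice whose explanation is visibly
    # incoherent (the model's gross failures); hindered participants lower
    # their weight and pick up confusion noise in both their own channel
    # and their perception of the advice.
    helped_weight_target: float = Field(0.75, ge=0, le=1)
    helped_weight_pull: float = Field(0.6, ge=0, le=1)
    helped_shift_cap: float = Field(0.3, ge=0)
    helped_shift_jitter: float = Field(0.03, ge=0)
    hindered_shift_mean: float = Field(-0.12)
    hindered_shift_sd: float = Field(0.04, ge=0)
    refine_fraction: float = Field(0.15, ge=0, le=1)
    confusion_sd_mean_weeks: float = Field(1.6, ge=0)
    confusion_sd_spread_weeks: float = Field(0.3, ge=0)
    gross_detection_prob: float = Field(0.8, ge=0, le=1)
    veto_discount: float = Field(0.25, ge=0, le=1)


class ConfidenceConfig(BaseModel):
    """Ordinal confidence model: score = 1 + #{cutpoints below latent}."""

    anchor_sd: float = Field(0.5, ge=0)
    stage_shifts: tuple[float, float, float] = (0.20, 0.36, 0.42)
    latent_sd: float = Field(0.9, ge=0)
    helped_stage3_polarisation: float = Field(1.8, ge=1)
    cutpoints: tuple[float, float, float, float] = (-1.5, -0.5, 0.5, 1.5)


class TimingConfig(BaseModel):
    """Lognormal per-estimate times (seconds). Stage 1 involved extra
    annotation work and is not comparable with stages 2-3."""

    stage_mean_sec: tuple[float, float, float] = (40.0, 17.2, 19.6)
    stage_sd_sec: tuple[float, float, float] = (20.0, 13.0, 10.5)


class LikertConfig(BaseModel):
    trust_post2_mean: float = 3.3
    trust_post2_sd: float = Field(0.95, ge=0)
    trust_drop_prob: float = Field(0.3, ge=0, le=1)
    distrust_post2_mean: float = 2.5
    distrust_post2_sd: float = Field(0.97, ge=0)
    distrust_rise_prob: float = Field(0.6, ge=0, le=1)
    comfort_pre_mean: float = 4.3
    comfort_pre_sd: float = Field(0.67, ge=0)
    comfort_drop_probs: tuple[float, float, float] = (0.35, 0.5, 0.15)  # drop 0/1/2
    helpful_mean_helped: float = 4.5
    helpful_mean_hindered: float = 1.8
    helpful_sd: float = Field(0.6, ge=0)

    @model_validator(mode="after")
    def _probs_sum(self):
        if abs(sum(self.comfort_drop_probs) - 1.0) > 1e-9:
            raise ValueError("comfort_drop_probs must sum to 1")
        return self


class FeatureConfig(BaseModel):
    repertoire_mean: float = 7.8
    repertoire_sd: float = Field(1.32, ge=0)
    per_image_mean: float = 2.76
    per_image_sd: float = Field(1.26, ge=0)


class SimulationConfig(BaseModel):
    """Full study-generation configuration. The defaults are the frozen
    calibration: they reproduce the headline aggregate statistics of a
    10-reader, 65-image, three-stage study (see docs/methods.md)."""

    n_participants: int = Field(10, gt=0)
    n_images: int = Field(65, gt=0)
    ga_range_weeks: tuple[float, float] = (13.0, 42.0)
    helped_fraction: float = Field(0.5, ge=0, le=1)
    model_error: ModelErrorConfig = Field(default_factory=ModelErrorConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    confidence: ConfidenceConfig = Field(default_factory=ConfidenceConfig)
    timing: TimingConfig = Field(default_factory=TimingConfig)
    likert: LikertConfig = Field(default_factory=LikertConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _range_ok(self):
        lo, hi = self.ga_range_weeks
        if not lo < hi:
            raise ValueError("ga_range_weeks must be increasing")
        return self


def default_config() -> SimulationConfig:
    """The shipped calibration: 10 participants x 65 images, model MAE
    ~9.4 days, unaided participant MAE ~23.5 days, aided ~15.7 days,
    explanation stage ~14.3 days, stage-2 agreement ~0.70 and mean WoA
    ~0.65, half the population helped by explanations."""
    return SimulationConfig()


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent behavioural parameters of one simulated participant."""

    participant_id: str
    bias_weeks: float
    noise_sd_weeks: float
    advice_weight: float
    helped: bool
    helpfulness_shift: float
    confusion_sd_weeks: float
    confidence_anchor: float

    def __post_init__(self) -> None:
        if self.noise_sd_weeks < 0 or self.confusion_sd_weeks < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.advice_weight <= 1:
            raise ValueError("advice_weight must be in [0, 1]")


# ---------------------------------------------------------------------------
# Sampling


def _systematic_flags(n: int, fraction: float, phase: float) -> np.ndarray:
    """Systematic (randomized-phase) group assignment: participant i is in
    the group iff the sequence phase + fraction*k crosses an integer at
    step i. The realised count is always floor(n*fraction) or the next
    integer (unbiased over the phase), and the assignment of participant i
    depends only on i — growing the population never reassigns anyone."""
    edges = phase + fraction * np.arange(n + 1, dtype=float)
    return np.floor(edges[1:]) > np.floor(edges[:-1])


def sample_images(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[ModelPrediction], BinScheme, np.ndarray]:
    """Draw true GAs ~ uniform over the study range and the model's binned
    predictions: raw output = truth + mixture error, clamped to the range,
    binned; the point value is the bin midpoint.

    Also returns the boolean gross-failure flags: on those images the
    explanation is visibly incoherent, which is what stage-3 helped
    participants can pick up on.
    """
    lo, hi = config.ga_range_weeks
    scheme = default_bin_scheme()
    truths = rng.uniform(lo, hi, size=config.n_images)
    me = config.model_error
    gross = rng.random(config.n_images) < me.gross_prob
    sd = np.where(gross, me.gross_sd_weeks, me.core_sd_weeks)
    raw = truths + rng.normal(0.0, 1.0, size=config.n_images) * sd
    raw = np.clip(raw, lo, hi)
    predictions = []
    for i, r in enumerate(raw):
        b = scheme.bin_for(float(r))
        predictions.append(
            ModelPrediction(image_id=f"img{i:03d}", bin=b, point_weeks=b.midpoint)
        )
    return truths, predictions, scheme, gross


def sample_population(
    config: SimulationConfig, rng: np.random.Generator
) -> list[ParticipantProfile]:
    """Draw the participant population: group memberships first (helped /
    deferring, with near-exact group fractions, independently shuffled),
    then the continuous per-participant parameters."""
    n = config.n_participants
    pop = config.population

    # group phases are drawn before any participant, so assignments depend
    # only on the participant index and the phases
    helped = _systematic_flags(n, config.helped_fraction, rng.random())
    deferring = _systematic_flags(n, pop.deferring_fraction, rng.random())

    profiles = []
    for i in range(n):
        if deferring[i]:
            w = rng.normal(pop.advice_weight_deferring_mean, pop.advice_weight_deferring_sd)
        else:
            w = rng.normal(pop.advice_weight_sceptical_mean, pop.advice_weight_sceptical_sd)
        w = float(np.clip(w, 0.0, 1.0))
        if helped[i]:
            # pull toward the error-optimal blend, capped
            shift = pop.helped_weight_pull * (pop.helped_weight_target - w)
            shift = float(np.clip(shift, -pop.helped_shift_cap, pop.helped_shift_cap))
            shift += rng.normal(0.0, pop.helped_shift_jitter)
            confusion = 0.0
        else:
            shift = rng.normal(pop.hindered_shift_mean, pop.hindered_shift_sd)
            confusion = max(
                0.0, rng.normal(pop.confusion_sd_mean_weeks, pop.confusion_sd_spread_weeks)
            )
        noise_sd = max(0.5, rng.normal(pop.noise_sd_mean_weeks, pop.noise_sd_spread_weeks))
        if not deferring[i]:
            noise_sd *= pop.sceptical_noise_multiplier
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i:02d}",
                bias_weeks=float(rng.normal(0.0, pop.bias_sd_weeks)),
                noise_sd_weeks=float(noise_sd),
                advice_weight=w,
                helped=bool(helped[i]),
                helpfulness_shift=float(shift),
                confusion_sd_weeks=float(confusion),
                confidence_anchor=float(rng.normal(0.0, config.confidence.anchor_sd)),
            )
        )
    return profiles


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _confidence_scores(
    latent_mean: np.ndarray, latent_sd: float, cutpoints, rng: np.random.Generator
) -> np.ndarray:
    latent = latent_mean + rng.normal(0.0, latent_sd, size=len(latent_mean))
    scores = np.ones(len(latent), dtype=int)
    for c in cutpoints:
        scores += (latent > c).astype(int)
    return scores


def simulate_participant(
    profile: ParticipantProfile,
    truths: np.ndarray,
    predictions: list[ModelPrediction],
    rng: np.random.Generator,
    config: SimulationConfig,
    model_gross: np.ndarray | None = None,
) -> list[EstimateRecord]:
    """Simulate one participant's estimates for all three stages.

    Stage 1: truth + personal bias + noise. Stage 2: move a fraction
    ``advice_weight`` of the way from the stage-1 estimate toward the
    model's point value. Stage 3: same anchoring with the explanation
    response applied — helped participants refine their own reading,
    shift their weight toward the error-optimal blend, and discount
    advice on images where they catch a visibly incoherent explanation
    (``model_gross`` flags); hindered participants shift their weight
    down and pick up confusion noise in both channels.
    """
    pop = config.population
    conf = config.confidence
    n = len(truths)
    m = np.array([p.point_weeks for p in predictions])
    lo, hi = ESTIMATE_CLIP

    # stage 1: unaided
    own_err = profile.bias_weeks + rng.normal(0.0, profile.noise_sd_weeks, size=n)
    p1 = np.clip(truths + own_err, lo, hi)

    # stage 2: linear anchoring toward the advice
    w2 = profile.advice_weight
    p2 = p1 + w2 * (m - p1) + rng.normal(0.0, pop.revision_noise_sd_weeks, size=n)
    p2 = np.clip(p2, lo, hi)

    # stage 3: explanation response
    w3 = float(np.clip(profile.advice_weight + profile.helpfulness_shift, 0.0, 1.0))
    if profile.helped:
        # explanations sharpen the participant's own reading; on the
        # model's gross failures the explanation is visibly incoherent
        # and the participant usually catches it and discounts the advice
        prior3 = np.clip(truths + own_err * (1.0 - pop.refine_fraction), lo, hi)
        perceived = m
        if model_gross is None:
            caught = np.zeros(n, dtype=bool)
        else:
            caught = model_gross & (rng.random(n) < pop.gross_detection_prob)
        w_eff = np.where(caught, w3 * pop.veto_discount, w3)
    else:
        # confusion corrupts both channels: the participant's own reading
        # and how they read the advice
        c = profile.confusion_sd_weeks
        prior3 = np.clip(p1 + rng.normal(0.0, c, size=n), lo, hi)
        perceived = m + rng.normal(0.0, c, size=n)
        w_eff = w3
    p3 = prior3 + w_eff * (perceived - prior3) + rng.normal(
        0.0, pop.revision_noise_sd_weeks, size=n
    )
    p3 = np.clip(p3, lo, hi)

    # confidence: latent anchor + stage shift, thresholded
    scores = {}
    for stage, shift in zip((1, 2, 3), conf.stage_shifts):
        latent_sd = conf.latent_sd
        if stage == 3 and profile.helped:
            latent_sd *= conf.helped_stage3_polarisation
        scores[stage] = _confidence_scores(
            np.full(n, profile.confidence_anchor + shift), latent_sd, conf.cutpoints, rng
        )

    # times
    times = {
        stage: _lognormal(
            rng, config.timing.stage_mean_sec[stage - 1], config.timing.stage_sd_sec[stage - 1], n
        )
        for stage in (1, 2, 3)
    }

    # stage-1 feature annotations
    feat = config.features
    repertoire_size = int(
        np.clip(round(rng.normal(feat.repertoire_mean, feat.repertoire_sd)), 1,
                len(FEATURE_VOCABULARY))
    )
    repertoire = list(
        rng.choice(len(FEATURE_VOCABULARY), size=repertoire_size, replace=False)
    )
    n_feats = np.clip(
        np.rint(rng.normal(feat.per_image_mean, feat.per_image_sd, size=n)),
        0,
        repertoire_size,
    ).astype(int)

    records = []
    estimates = {1: p1, 2: p2, 3: p3}
    for stage in (1, 2, 3):
        for i in range(n):
            if stage == 1 and n_feats[i] > 0:
                chosen = rng.choice(repertoire, size=n_feats[i], replace=False)
                feats = frozenset(FEATURE_VOCABULARY[j] for j in chosen)
            else:
                feats = frozenset()
            records.append(
                EstimateRecord(
                    participant_id=profile.participant_id,
                    image_id=predictions[i].image_id,
                    stage=stage,
                    true_ga_weeks=float(truths[i]),
                    estimate_weeks=float(estimates[stage][i]),
                    confidence=int(scores[stage][i]),
                    time_sec=float(times[stage][i]),
                    features=feats,
                )
            )
    return records


def _round_likert(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 1, 5))


def _participant_likert(
    profile: ParticipantProfile, rng: np.random.Generator, config: SimulationConfig
) -> list[LikertResponse]:
    lk = config.likert
    pid = profile.participant_id
    out = []

    comfort_pre = _round_likert(rng, lk.comfort_pre_mean, lk.comfort_pre_sd)
    out.append(LikertResponse(pid, "pre_study", "comfort_practice", comfort_pre))

    trust2 = _round_likert(rng, lk.trust_post2_mean, lk.trust_post2_sd)
    distrust2 = _round_likert(rng, lk.distrust_post2_mean, lk.distrust_post2_sd)
    out.append(LikertResponse(pid, "post_stage2", "trust", trust2))
    out.append(LikertResponse(pid, "post_stage2", "distrust", distrust2))

    trust3 = int(np.clip(trust2 - (1 if rng.random() < lk.trust_drop_prob else 0), 1, 5))
    distrust3 = int(
        np.clip(distrust2 + (1 if rng.random() < lk.distrust_rise_prob else 0), 1, 5)
    )
    helpful_mean = lk.helpful_mean_helped if profile.helped else lk.helpful_mean_hindered
    out.append(LikertResponse(pid, "post_stage3", "trust", trust3))
    out.append(LikertResponse(pid, "post_stage3", "distrust", distrust3))
    out.append(
        LikertResponse(
            pid, "post_stage3", "explanations_helpful",
            _round_likert(rng, helpful_mean, lk.helpful_sd),
        )
    )

    drop = int(rng.choice(3, p=list(lk.comfort_drop_probs)))
    out.append(
        LikertResponse(
            pid, "post_study", "comfort_practice", int(np.clip(comfort_pre - drop, 1, 5))
        )
    )
    return out


@dataclass
class SimulationResult:
    """A generated study plus the latent ground truth behind it (profiles
    and the image truths), for calibration and recovery checks."""

    table: StudyTable
    profiles: list[ParticipantProfile]
    truths: np.ndarray
    predictions: list[ModelPrediction]


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the full simulator. ``seed`` overrides ``config.seed``.

    Substream layout (SeedSequence spawn): child 0 draws the images and
    model predictions, child 1 the population, child 2+i everything for
    participant i (estimates, confidence, times, features, questionnaire).
    """
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 + config.n_participants)
    truths, predictions, scheme, gross = sample_images(
        config, np.random.default_rng(children[0])
    )
    profiles = sample_population(config, np.random.default_rng(children[1]))

    estimates: list[EstimateRecord] = []
    likert: list[LikertResponse] = []
    for i, profile in enumerate(profiles):
        rng = np.random.default_rng(children[2 + i])
        estimates.extend(
            simulate_participant(profile, truths, predictions, rng, config, gross)
        )
        likert.extend(_participant_likert(profile, rng, config))

    table = StudyTable(estimates, predictions, likert, scheme)
    return SimulationResult(table, profiles, truths, predictions)


def generate_study(config: SimulationConfig, seed: int | None = None) -> StudyTable:
    """Generate a reproducible study table (same seed, same table)."""
    return simulate_study(config, seed).table
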