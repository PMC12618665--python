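# Methods

`xai_reliance` analyses three-stage reader studies in which clinicians
estimate fetal gestational age (GA) from ultrasound images — first
unaided (stage 1), then with a model's binned GA prediction (stage 2),
then with the prediction plus its explanation (stage 3) — and provides a
behavioral simulator that generates such studies with realistic
statistical structure. This note records the models, the defaults and why
they are what they are, and what the simulator does and does not capture.

## Reliance metrics

**Weight of Advice.** For one image, with prior (stage-1) estimate
ŷ_p1, revised estimate ŷ_p2 and model estimate ŷ_m (all in weeks),

    WoA = (ŷ_p1 − ŷ_p2) / (ŷ_p1 − ŷ_m)

is the fraction of the distance to the advice that the judge moved:
0 = unchanged, 1 = adopted the advice, 0.5 = split the difference,
negative = moved away, >1 = overshot. Images with |ŷ_p1 − ŷ_m| < 1 week
are excluded from WoA means: the model predicts 2-week intervals, so a
prior within a week of the model's point value already agrees with it,
and the ratio degenerates as the denominator approaches zero. The
exclusion threshold is configurable; 1 week is the default. The exclusion
applies **only** to WoA — agreement and reliance typing use every image.

The prior used for stage-3 WoA is the stage-1 estimate (the only estimate
made before any model information); using the stage-2 estimate as the
stage-3 prior is available via `prior_stage=2`.

**Agreement** is the proportion of a participant's estimates falling
inside the model's predicted bin. Bins are half-open `[lo, hi)` with the
scheme's last bin closed, so every GA value belongs to exactly one bin.

**Reliance type.** Each image is classified from four absolute
differences: the participant moved toward the model (R = 1 iff
|ŷ_p2 − ŷ_m| < |ŷ_p1 − ŷ_m|, strictly) and the model was better than the
unaided estimate (E_m = 1 iff |ŷ_m − y| < |ŷ_p1 − y|, strictly).
Appropriate reliance is R = E_m; under-reliance is R = 0, E_m = 1;
over-reliance is R = 1, E_m = 0. Ties resolve to R = 0 and E_m = 0
(strict inequalities as defined), so an unchanged estimate is never
over-reliance and full adoption is never under-reliance. Prevalences are
reported per participant as proportions of images; log prevalence ratios
use a Haldane half-count on both counts (`ln((a+½)/(b+½))`) so empty
categories stay finite, with raw counts carried alongside.

## The GA bin scheme

The model discretises 13–42 weeks into 13 contiguous bins: interior bins
exactly 2 weeks, outer bins wider because extreme GAs are sparsely
represented. The exact edges of the outer bins are a free choice; the
canonical scheme here is `[13,16)`, eleven 2-week bins `[16,18)…[36,38)`,
and `[38,42]` (13 bins over a 29-week span force 3 + 22 + 4). Any scheme
satisfying the invariants can be passed in its place. The scalar "point"
standing in for a binned prediction defaults to the bin midpoint;
arithmetic (WoA, reliance typing) uses that point.

## Units

All computation is in weeks (fractional); MAEs are reported in days (×7).
Estimates outside 10–45 weeks are rejected as data errors rather than
clipped silently.

## Statistical battery

`run_full_battery` mirrors a specific published analysis style:
across-stage comparisons of per-participant summaries (MAE, agreement,
mean WoA, timing) use **independent** two-sample t-tests even though the
design is paired. The battery reproduces that choice by default and
additionally reports the paired t-test on the same per-participant
differences, labelled `(paired)`, for every such comparison. Per-estimate
confidence across stages uses the Wilcoxon signed-rank test on
participant×image pairs (n = 650 pairs, which is what makes very small
p-values attainable; participant-level n = 10 could not produce them);
the helped/not-helped confidence split uses the Mann-Whitney U test;
trust items use participant-paired signed-rank tests; reliance-type
prevalences use paired t-tests on per-participant log count ratios. No
multiple-testing correction is applied; the report carries raw p-values
and the number of tests run.

Participants count as "helped" when their post-stage-3 rating of the
explanations-helpful item is ≥ 4 on the 1–5 scale.

**Exact small-sample tests.** Ordinal data are full of ties, and common
exact routines are tie-free, so the exact paths are implemented here:

* Wilcoxon signed-rank: zero differences dropped (Wilcoxon's original
  procedure; the Pratt variant is not currently exposed), midranks on the
  remaining |d|, and the full 2^n sign-flip null computed by dynamic
  programming over doubled (integer) midranks for n ≤ 25. Beyond that,
  the tie-corrected normal approximation (scipy).
* Mann-Whitney U: U for group a counts a-above-b pairs plus half the
  ties; for n_a + n_b ≤ 12 the null is enumerated over all group
  assignments of the pooled sample. Beyond that, scipy's tie-corrected
  asymptotic with continuity correction.
* Two-sided exact p is `min(1, 2·min(P(T ≤ t), P(T ≥ t)))`.

t-tests and Pearson correlation go through scipy; Cohen's d uses the
pooled SD (ddof = 1 per group).

## The simulator

The generator emulates the study conditions: 65 images with true GA
~ uniform on 13–42 weeks, 10 participants, three stages, questionnaires.
One integer seed drives everything; per-participant substreams are
spawned from a `SeedSequence`, so adding a participant never changes the
records of existing ones. Group memberships (helped/hindered,
deferring/sceptical) use systematic assignment with a random phase: the
realised group fraction is within one participant of nominal, and a
participant's membership depends only on their index and the phase.

**Model.** Raw prediction = truth + error from a two-component normal
mixture (core SD 1.12 weeks; with probability 0.10 a gross failure,
SD 6.8 weeks), clamped to range and binned; the point value is the bin
midpoint. The heavy tail is needed to combine a small MAE (~9.4 days)
with a much larger per-estimate SD (~14 days), and it gives the
explanation stage something to catch: on gross failures the explanation
is incoherent.

**Stage 1.** Estimate = truth + participant bias (SD 1.0 weeks across
participants) + noise (per-participant SD drawn around 3.75 weeks),
clipped to 10–45.

**Stage 2.** Linear advice-taking: p2 = p1 + w·(ŷ_m − p1) + ε with small
revision noise (SD 0.4 weeks). The advice weight w is **bimodal**: a
deferring majority (fraction 0.66, w ≈ 0.97) and a sceptical minority
(w ≈ 0.05) whose unaided noise is 1.35× larger. This structure is forced
by the joint calibration targets: a unimodal population with mean w =
0.65 cannot reach 70% mean agreement (it tops out near 55%), while the
bimodal population reproduces mean WoA ~0.65, mean agreement ~0.70,
aided MAE ~15.7 days, and the wide per-participant agreement spread at
the same time. The sceptical-noisier correlation is what keeps aided MAE
well above the model's own error when two-thirds of the population
effectively adopts the model.

**Stage 3.** A binary per-participant latent `helped` (half the
population) controls the explanation response:

* Helped: their own reading sharpens (intrinsic error shrinks by 15%),
  their advice weight moves 60% of the way toward an error-optimal blend
  (target 0.75, shift capped at ±0.3), and on gross model failures they
  catch the incoherent explanation with probability 0.8 and cut their
  advice weight to a quarter. A simpler rule — discounting advice
  whenever it sits far from one's own prior — was evaluated and rejected:
  participant error is much larger than the model's core error, so a
  large discrepancy usually indicts the participant, and that rule makes
  helped participants *worse*.
* Hindered: advice weight drops slightly (−0.12) and confusion noise
  (SD ~1.6 weeks) corrupts both channels — their own reading and their
  perception of the advice.

**Confidence** is ordinal: latent = participant anchor + stage shift
(0.20/0.36/0.42), Gaussian noise (SD 0.9), thresholded at cutpoints
(−1.5, −0.5, 0.5, 1.5). Helped participants' stage-3 latent SD is
multiplied by 1.8: their confidence polarises (more 2s and 4s) rather
than shifting in mean. **Times** are lognormal per estimate
(means 40/17.2/19.6 s); stage 1 included extra annotation work and is
flagged non-comparable. **Questionnaires** emit trust/distrust items
after stages 2 and 3 (small downward trust drift), an
explanations-helpful item tracking the helped flag plus noise, and a
comfort-with-clinical-use item before and after the study with a mean
drop of ~0.8 points. **Stage-1 features** draw a per-participant
repertoire (~7.8 of 12 vocabulary terms) and ~2.76 features per image.

**Calibration.** The defaults were frozen after a Monte-Carlo
calibration (≥40 seeds per iteration) against the aggregate targets:
unaided MAE 23.5 d, aided 15.7 d, explanation-stage 14.3 d, model MAE
9.4 d, stage-2 agreement 0.70, stage-2 mean WoA 0.65. At the frozen
defaults the 60-seed means are within ~0.5 d / ~0.01 of every target.
Problem sizes throughout (65 images, 10 participants, 20–60 seeds per
check) are the study's own scale, so every check runs in seconds.

## What the simulator does not capture

* It generates behaviour, not images: no ultrasound content, no actual
  prototype explanations — only their behavioural consequences.
* Simulated **stage-3 agreement (~0.53) and WoA (~0.61) run below the
  stage-2 values**, whereas the emulated study reports slight
  (non-significant) increases (0.73, 0.71). Hindered-participant
  confusion necessarily pushes estimates out of the model's bin; making
  hindered participants meaningfully worse (ΔMAE +2–3 days) while mean
  agreement *rises* is not reachable under midpoint-anchored linear
  advice-taking. Tests that pass on simulated data therefore say nothing
  about stage-3 agreement levels in real data.
* Stage-1 agreement comes out ~0.21 versus ~0.35 in the emulated study:
  real unaided errors are more concentrated near zero than a Gaussian
  with matching MAE.
* Real populations need not be bimodal in advice weight; bimodality is
  one parsimonious structure consistent with the aggregate statistics,
  not an inference about clinicians.
* Likert items are generated marginally (plus the helped linkage); no
  full correlation structure between questionnaire items is modelled.

## Numerical choices

* Half-open bin membership, last bin closed: every value maps to exactly
  one bin; an estimate exactly on an interior upper edge does not agree.
* WoA exclusion strictly below the threshold (`< 1` week), matching the
  definition; the zero-denominator case is thereby unreachable.
* `-0.0` WoA values are normalised to `0.0`.
* Degenerate inputs (zero pooled variance, all-zero differences,
  constant series, all-excluded WoA) raise explicit errors or return
  explicit markers; the battery converts them into "not computed" rows
  rather than crashing.
* Proportion summaries store integer counts; proportions are derived, so
  mass conservation is exact.

## Known limitations

* Exact Mann-Whitney enumeration is O(C(n, n_a)) and capped at n = 12;
  the asymptotic path takes over beyond it.
* The battery's helped/not-helped split needs the explanations-helpful
  questionnaire item; without it those rows are reported as not computed.
* `delta_mae` and the reliance metrics assume the three stages share one
  image set per participant (enforced by table validation).
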