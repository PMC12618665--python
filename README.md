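# xai_reliance

Analysis toolkit and behavioral simulator for **three-stage reader
studies of clinician–AI advice-taking** — the study design in which
clinicians estimate gestational age (GA) from fetal ultrasound images
first unaided, then with an AI model's binned prediction, then with the
prediction plus its explanation. It is written for researchers evaluating
explainable-AI (XAI) tools with real readers: it quantifies not just
whether advice improves accuracy, but whether readers *rely* on it, and
whether that reliance is warranted.

## What it computes

For truth *y*, unaided estimate ŷ_p1, revised estimate ŷ_p2 and model
estimate ŷ_m (weeks):

* **Weight of Advice** — WoA = (ŷ_p1 − ŷ_p2)/(ŷ_p1 − ŷ_m), the fraction
  of the distance to the advice the reader moved (0 unchanged, 1 adopted,
  <0 moved away, >1 overshot). Images with |ŷ_p1 − ŷ_m| < 1 week are
  excluded from WoA means.
* **Agreement** — the proportion of estimates inside the model's
  predicted 2-week GA bin.
* **Reliance typing** — each image is *appropriate reliance*,
  *under-reliance* or *over-reliance* by comparing behaviour
  (𝓡 = 1 iff |ŷ_p2 − ŷ_m| < |ŷ_p1 − ŷ_m|) with warrant
  (𝓔_m = 1 iff |ŷ_m − y| < |ŷ_p1 − y|): appropriate iff 𝓡 = 𝓔_m.
* **Per-reader performance** — MAE in days, confidence distributions,
  feature usage, timing.
* **The full statistical battery** — t-tests with Cohen's d, exact
  (tie-aware) Wilcoxon signed-rank and Mann-Whitney U, Pearson
  correlation, and log prevalence ratios of reliance types, orchestrated
  into a labelled results report.
* **A calibrated simulator** — 10 readers × 65 images × 3 stages with
  heterogeneous (bimodal) advice-taking and a binary helped/hindered
  response to explanations, whose defaults reproduce realistic aggregate
  statistics (unaided MAE ≈ 23.5 d, aided ≈ 15.7 d, model ≈ 9.4 d,
  agreement ≈ 0.70, WoA ≈ 0.65). See `docs/methods.md`.

## Worked example

```python
import numpy as np
import xai_reliance as xr

cfg = xr.default_config()                 # the calibrated study conditions
table = xr.generate_study(cfg, seed=1)    # 10 x 65 x 3 = 1950 estimates

for stage in (1, 2, 3):
    agg = xr.aggregate_mae_days(table, stage)
    print(f"stage {stage}: MAE {agg['mean_days']:.1f} d (SD {agg['sd_days']:.1f})")

pids = table.participants()
print(f"stage-2 agreement {np.mean([xr.agreement(table, p, 2) for p in pids]):.2f},",
      f"mean WoA {np.mean([xr.mean_woa(table, p, 2).mean for p in pids]):.2f}")
```

prints

```
stage 1: MAE 21.9 d (SD 6.0)
stage 2: MAE 13.3 d (SD 8.8)
stage 3: MAE 13.0 d (SD 6.8)
stage-2 agreement 0.74, mean WoA 0.68
```

— access to the model's predictions cuts the readers' error by roughly a
third (this single seed draws slightly low; the across-seed means sit at
23.5/15.7/14.3 d), readers land inside the model's bin about 70% of the
time, and on average they move about two-thirds of the way toward the
advice. A single reader's reliance profile:

```python
s = xr.reliance_proportions(table, pids[0], 2)
print(f"appropriate {s.p_appropriate:.2f}, under {s.p_under:.2f}, over {s.p_over:.2f}")
# appropriate 0.78, under 0.03, over 0.18
```

and the core metric on a hand case — a reader at 20 weeks advised 30
who revises to 25 moved exactly halfway:

```python
xr.weight_of_advice(20, 25, 30).value   # 0.5
```

## Command line

```bash
xai-reliance simulate --seed 1 --out study/         # estimates/predictions/likert CSVs
xai-reliance analyze --study study/ --out results/  # metrics, reliance summary, battery
xai-reliance report --results results/              # single Markdown report
```

Outputs are deterministic per seed (byte-identical on re-run). Custom
populations are JSON configs (`--config`), validated against
`SimulationConfig`.

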