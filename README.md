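# kinecode

Single-trial kinematic coding analysis for occluded action prediction:
how is object-size information *encoded* in reach-to-grasp kinematics, and
how well does an individual observer *read it out*?

## The problem

In a two-alternative forced-choice (2AFC) size-discrimination task, an
observer watches two reach-to-grasp movies per trial — one toward a small
object, one toward a large object — truncated at one of eight temporal
occlusion levels (10–80% of movement duration), and reports which interval
contained the small (or large) object, followed by a 1–4 confidence rating.
A session has 240 trials in 8 blocks of 30, with all eight occlusion levels
balanced within every block.

Observers with psychosis show a distinctive signature on this task: a
*null-integration window* early in the movement (up to ~20% of movement
duration) in which their choices carry no kinematic information, paired
with confidence that fails to track the accuracy drop. `kinecode`
implements the full analysis pipeline needed to quantify that signature at
single-trial resolution, together with a calibrated synthetic-data
generator so every stage is testable without any proprietary motion-capture
data.

## The models

Let `ΔK` be the vector of first-interval minus second-interval kinematic
features (12 channels — grip aperture GA, index/thumb/wrist coordinates,
wrist and grip velocity — by the visible 10%-epochs of normalized movement
time). Two L2-regularized logistic models share this predictor:

* **Encoding model** (per occlusion level): predicts the true configuration,

  `P(small first) = σ(ΔK·β_enc + b_enc)`, choice `= H(σ(·) − ½)`,

  with σ the sigmoid and H the Heaviside step. Its cross-validated accuracy
  measures the size information available to an ideal observer. CV folds
  are grouped by agent so held-out trials show unseen actors.

* **Readout model** (per observer × occlusion level): the same form fitted
  to the observer's own choices, `P = σ(ΔK·β_read + b_read)`. `ΔK·β_read`
  captures how the observer integrates kinematic evidence; the intercept
  `b_read` is evidence-independent response bias, summarized as
  `|b| / (|b| + mean|ΔK·β|)`. Readout CV accuracy is referenced to a
  permutation chance level — the mean of the CV-accuracy distribution after
  shuffling the observer's responses.

Around these sit: empirical psychometric curves P(small first) vs signed
occlusion; a piecewise logistic mixed model (participant random intercepts,
Gauss–Hermite maximum likelihood) whose change point — selected by AIC over
a candidate grid and tested by LRT against a single slope — locates the
boundary of the two integration periods; confidence/accuracy calibration
ratios by period; and readout-vs-encoding weight alignment profiles that
show which features (e.g. GA) each group reads, and when.

## Worked example

```python
from kinecode import (DesignSpec, make_stimulus_set, simulate_cohort,
                      sessions_frame, fit_piecewise_psychometric,
                      accuracy_by_occlusion)
from kinecode.coding import fit_encoding

stim = make_stimulus_set(seed=0)                     # 60 reaching acts
sessions = simulate_cohort(stim, DesignSpec(), n_control=16, n_patient=16,
                           seed=42)
df = sessions_frame(sessions)

fit = fit_piecewise_psychometric(df, candidates=(10, 20, 30, 40, 50))
print("change point:", fit.change_point)

for occ in (10, 20, 60):
    e = fit_encoding(sessions[0].trials, stim, occ, seed=0)
    print(f"encoding CV accuracy @ {occ}%: {e.cv_accuracy:.3f}")

print(accuracy_by_occlusion(df).query("occlusion_level in (10, 20, 60)"))
```

prints

```
change point: 20.0
encoding CV accuracy @ 10%: 0.658
encoding CV accuracy @ 20%: 0.717
encoding CV accuracy @ 60%: 0.933
  group  occlusion_level  accuracy   sem  n_participants
control               10     0.558 0.029              16
control               20     0.748 0.022              16
control               60     0.948 0.009              16
patient               10     0.469 0.024              16
patient               20     0.465 0.027              16
patient               60     0.892 0.010              16
```

Reading: size information is present in the kinematics from 10% of movement
duration and exceeds 93% by 60%. Control observers use it throughout;
patient-preset observers sit at chance through 20% (their null-integration
window — which the piecewise fit recovers as the ±20% change point) and
catch up later. The companion analyses (`confidence_accuracy_ratio`,
`fit_readout`, `readout_chance_null`, `alignment_profile`) quantify the
accompanying confidence miscalibration and the missing early grip-aperture
readout.

The same pipeline runs from the shell:

```bash
kinecode simulate --seed 42 --out-dir run/
kinecode psychometrics --sessions run/sessions.csv --out run/psy.json
kinecode run --seed 42 --out-dir run/        # everything, one summary.json
```

## Layout

```
src/kinecode/
  types.py        # KinematicStimulus, TrialRecord schema, ObserverProfile, ...
  generator.py    # stimuli, balanced designs, observer presets, simulation
  _logistic.py    # ridge-logistic core + nested, grouped, seeded CV
  mixed.py        # random-intercept logistic GLMM (Gauss–Hermite ML) + fallback
  psychometrics.py# curves, piecewise change point, calibration ratios
  coding.py       # encoding/readout fits, permutation nulls, bias, predictions
  alignment.py    # readout-vs-encoding weight alignment, covariate screens
  pipeline.py     # config-driven end-to-end runs (seeded, byte-reproducible)
  cli.py          # `kinecode` command group
docs/methods.md   # model and generator assumptions, defaults, limitations
```
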