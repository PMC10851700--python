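# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `kinecode`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task and data model

The unit of analysis is a 2AFC temporal-occlusion trial: two reach-to-grasp
acts (one toward a small, one toward a large object), truncated at an
occlusion level `o ∈ {10, …, 80}` percent of movement duration. Kinematics
live on a grid of 10 equal epochs of normalized movement time; level `o`
exposes epochs `1..o/10`. A session holds 240 trials in 8 blocks of 30;
occlusion levels are exactly balanced over the session (30 trials each) and
every block contains every level; small-first/large-first configurations
are balanced within level (odd counts break toward small-first before
seeding the shuffle). The response instruction (report small vs report
large) switches between the first and last four blocks, with a
counterbalance flag.

## Synthetic stimuli

Each of 15 agents contributes 2 exemplars per object size (60 acts). For
feature `f` and epoch `e`,

    K[f, e] = trait_agent[f] + s · δ_f(e)/2 + ε[f, e]

with `s = +1` for small, `−1` for large; `trait ~ N(0, trait_sd²)` per
agent × feature (constant over epochs — actor idiosyncrasy);
`ε ~ N(0, noise_sd²)` i.i.d. per epoch (within-act variability). Defaults:
`trait_sd = 0.6`, `noise_sd = 1.0`, features on a z-like scale.

The size-effect profiles `δ_f(e)` encode the qualitative structure of real
reach-to-grasp kinematics: grip aperture (GA) is informative from the first
epoch with its maximum at epochs 2–3; index-finger height (IZ) grows
monotonically; wrist height (WZ) is time-constant; the remaining channels
mix late-growing, weakly stable, and uninformative profiles (WX, WY carry
no size signal). The absolute magnitudes were calibrated once so that the
encoding model's CV accuracy rises from roughly 0.65–0.70 at 10% occlusion
to above 0.95 at 60% — the operating range the analysis is designed for —
and were not revisited afterwards.

**Trial pairing.** The two acts of a trial come from the *same agent*
(uniformly drawn agent, then uniform exemplars of each size). With a fixed
pool of 60 reused acts, cross-agent pairing lets a classifier learn act
identity rather than size: every act recurs across many pairs, so no fold
grouping can isolate train from test and the zero-size-effect null rises
far above chance. Same-agent pairing plus agent-grouped CV folds makes
held-out actors genuinely unseen, drives the no-signal null to chance, and
additionally cancels the agent trait inside `ΔK` (the within-trial
difference), which is also how a real paired design controls actor
idiosyncrasy.

## Synthetic observers

An observer is a linear readout of the visible kinematic difference:

    d = ΔK_visible · w + bias + η,   η ~ N(0, noise_sd²)

choice = "small first" iff `d > 0` (the measure-zero tie `d = 0` goes to
"large first" for determinism), flipped with probability `lapse`
(default 0.02). Presets:

* **control** — `w` proportional to the generator's true size-effect
  direction over all epochs (unit L2 norm), `bias = 0`;
* **patient** — identical but exactly zero for epochs ≤ 20% of movement
  duration (the null-integration window) and attenuated by gain 0.7
  thereafter; within the same window, confidence is drawn from the
  observer's own overall confidence distribution, independent of `d`
  (confidence miscalibration).

Decision noise defaults to `noise_sd = 0.6` for both groups, chosen during
generator calibration so the control preset's accuracy spans ~0.6 (10%) to
~0.95+ (late) and the patient preset is at chance through 20% yet above
0.85 at 60% — the qualitative shape of human data on this task.

Confidence ratings 1–4 are quartile bins of `confidence_gain · |d|`. The
bin edges are calibrated once per stimulus-set/design from the *control*
preset (internal fixed seed), so control and patient ratings share a scale;
an observer-specific calibration would hide group differences in
confidence by construction.

## Estimation

**Ridge logistic core.** Both encoding and readout models minimize
`−loglik + (λ/2)·‖β‖²` (intercept unpenalized) by damped Newton iterations
with a backtracking line search. λ is selected by inner stratified CV
(default 5-fold) over the documented grid {0.01, 0.1, 1, 10, 100},
maximizing held-out accuracy; exact ties go to the larger λ (determinism,
stability). Predictive accuracy comes from an outer stratified 10-fold CV
with λ re-selected inside every training set; the reported coefficients are
a full-data fit at the full-data-selected λ. Encoding folds are grouped by
(unordered) agent pair; readout folds are plain stratified. Fold
construction is label-flip-invariant (classes processed in the order of the
first trial's label), which makes the 2AFC interval-swap symmetry exact:
swapping both intervals (`ΔK → −ΔK`, labels flipped) reproduces identical
CV accuracy, identical coefficients, and a negated intercept.

**Prediction rule.** `H(σ(ΔK·β + b) − ½)` with the `P = ½` tie resolved as
"large first".

**Permutation chance level.** Labels are shuffled within occlusion level
and the *entire* nested-CV pipeline re-run per permutation (default ≥100,
enforced); the chance level is the null-distribution mean. Note the chance
level tracks the label base rate: an observer who answered 21/30 "small
first" has a null mean near 0.7, not 0.5 — only balanced labels give ~0.5.

**Bias fraction.** `|b_read| / (|b_read| + mean_t |ΔK_t·β_read|)`, with a
group-level sign-flip permutation test on the raw intercepts. At 30 trials
per occlusion level the sampling noise of the ML intercept puts a hard
floor of roughly 0.1 (strong-signal levels) to 0.5 (no-signal levels)
under this per-observer definition even when the generative bias is exactly
zero; the fraction is consistent (→ 0) only as trials per level grow. The
group sign-flip test, by contrast, is correctly calibrated at this n. Both
are reported; consumers who need a group-level bias summary should rely on
the sign-flip test.

**Mixed models.** The piecewise psychometric model is a binomial GLMM:
logit P(small first) = intercept + s₁·f₁(x;c) + s₂·f₂(x;c) with
`f₁ = sign(x)·min(|x|, c)`, `f₂ = sign(x)·max(|x|−c, 0)` on signed
occlusion `x` (+o small-first, −o large-first, slopes per 10% of movement
duration), odd-symmetric and continuous at ±c, a participant random
intercept, and (with two groups) group × segment-slope interactions. The
marginal likelihood is maximized with 25-node Gauss–Hermite quadrature
(L-BFGS-B on fixed effects plus log-SD, bounded log-SD ∈ [−6, 3]); Wald
SEs come from the numerical Hessian. This route agrees with lme4's
adaptive-quadrature `glmer` to ~10⁻² on coefficients (cross-checked in the
test suite). A fallback with fixed per-participant intercepts (ordinary
logistic ML via statsmodels GLM) is exposed as `method="fixed"` for speed
and degenerate variance components. The change point is selected by AIC
(`−2·loglik + 2·(fixed effects + 1 variance parameter)`) over the candidate
grid; significance is the df-counted LRT of the two-segment model against
the single-slope model at the selected knot. Measured type-I rate of this
post-selection LRT on single-slope data is ≤ ~5% (tested). The continuous
confidence/accuracy ratio model (group × period, participant random
intercept) uses statsmodels `MixedLM` (ML, not REML).

**Calibration ratio.** Confidence is normalized to [0,1] as `(c−1)/3`, so
an all-correct, maximally confident observer has ratio exactly 1; the ratio
is undefined (excluded, counted) when a cell's accuracy is 0. Periods are
early = occlusions ≤ change point, late = the rest (default change point
20). Absolute ratio values depend on this normalization choice and are not
comparable across other scalings.

**Alignment.** Readout-weight fraction per feature × epoch is
`|β_read|/Σ|β_read|` at each level; alignment sign is
`sign(β_read · β_enc)`, set to "null" when either weight falls below 1% of
its level's total absolute weight (below the floor the sign is noise).
Group averages are means of per-observer fractions; features are ordered by
the encoding weight at the 80% level, descending; stacks are per-epoch.
Alignment is invariant to positive rescaling of either weight vector.

**Extracted-information proxy.** The per-observer fraction of encoded
information that was read is `clip₀₁((acc_obs − ½)/(acc_enc − ½))`,
undefined when the encoding model is at or below chance. This is an
explicit accuracy-ratio proxy, not a partial-information decomposition.

## Reproducibility

Every stochastic stage consumes a named seed. The pipeline derives stage
seeds from the master seed via `SeedSequence(master, spawn_key=(stage,))`
with fixed stage indices (stimuli=0, design=1, observers=2, cv=3,
permutations=4), so adding a stage never perturbs earlier streams.
Identical configs give byte-identical `summary.json` (sorted keys, NaN →
null).

## Problem sizes used in the shipped checks

The acceptance script and suite run at the study's native scale where that
is cheap (16+16 observers, 240-trial sessions, 60-act sets) and use 20
replicate cohorts for change-point recovery, 100 stimulus sets for the
encoding calibration, 500 permutations + 200 shuffled datasets for the
null calibration, and 200 single-observer sessions per group for the
qualitative group signatures.

## What the generator does and does not emulate

It reproduces the statistical skeleton the analyses rely on: balanced
design, size effects with feature-specific time courses, actor
idiosyncrasy, null-integration and confidence-decoupling windows. It does
not model real 3D marker trajectories, temporal autocorrelation within an
act beyond the constant trait, reaction times, response omissions (the
schema admits missing responses/confidence but no missingness process is
shipped), learning across blocks, or between-observer heterogeneity within
a group (all observers of a group share one profile). Passing tests
therefore certify the *pipeline* — recovery of known structure under
realistic noise — not any claim about new empirical data.

## Known limitations

* The per-observer bias fraction is upward-biased at 30 trials/level (see
  above); its group mean should not be read as an estimate of generative
  bias at this n.
* Readout fits at no-signal levels are fits to noise; their coefficient
  profiles are flat in expectation and only interpretable through the
  permutation null and the alignment magnitude floor.
* The GLMM assumes a scalar random intercept; random slopes are not
  implemented (the generator induces none).
* Encoding-model folds require ≥2 agents per label class at a level;
  degenerate designs fall back to fewer folds.
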