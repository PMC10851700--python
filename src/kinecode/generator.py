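"""Synthetic stimuli, session designs, and simulated observers.

The generator emulates the statistical structure of a motion-capture library
of reach-to-grasp movements toward a small or large object, and of observers
performing the 2AFC size-discrimination task on temporally occluded pairs of
those movements:

* 60 stimuli (2 exemplars x 15 agents x 2 object sizes), each a 12-feature x
  10-epoch matrix of normalized-movement-time kinematics.  Small and large
  grasps differ in expectation by a per-feature, per-epoch size effect
  ``delta_f(e)``: grip aperture (GA) is informative from the very first epoch
  and peaks at epochs 2-3, index-finger height (IZ) grows monotonically, and
  wrist height (WZ) carries a stable, time-constant effect.  Agents add a
  per-feature random trait (constant over epochs) and each act adds i.i.d.
  epoch noise.
* 240-trial sessions in 8 blocks of 30, with the eight occlusion levels
  (10-80%) exactly balanced within the session and represented in every
  block, and small-first/large-first configurations balanced within level.
* Observers (control / patient presets) whose choices follow a noisy linear
  readout of the visible kinematic difference, with the patient preset
  carrying a null-integration window (zero weight up to 20% of movement
  duration), attenuated later weights, and confidence decoupled from the
  evidence inside that window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_FEATURES,
    N_EPOCHS,
    DesignSpec,
    KinematicStimulus,
    ObserverProfile,
    ObserverSession,
    StimulusSet,
    TRIAL_COLUMNS,
)

# ---------------------------------------------------------------------------
# generative size-effect profiles (units: z-scored feature values)

_EPOCH_AXIS = np.arange(1, N_EPOCHS + 1)


def _default_size_effect(feature_names: tuple[str, ...],
                         effect_scale: float) -> np.ndarray:
    """Expected small-minus-large difference per feature and epoch."""
    profiles = {}
    # early-peaking: informative at epoch 1, maximal at epochs 2-3
    profiles["GA"] = np.array([0.6, 1.4, 1.4, 0.8, 0.7, 0.7, 0.6, 0.6, 0.6, 0.6])
    # monotone growth across the movement
    profiles["IZ"] = np.linspace(0.1, 1.8, N_EPOCHS)
    # stable, time-constant encoding
    profiles["WZ"] = np.full(N_EPOCHS, 0.5)
    # remaining channels: a mix of late-growing, weakly stable and
    # uninformative profiles, mirroring a realistic kinematic battery
    profiles["WV"] = np.linspace(0.0, 1.2, N_EPOCHS)
    profiles["IX"] = np.linspace(0.0, 1.1, N_EPOCHS)
    profiles["IY"] = np.linspace(0.05, 0.9, N_EPOCHS)
    profiles["TX"] = np.full(N_EPOCHS, 0.3)
    profiles["TY"] = np.full(N_EPOCHS, 0.3)
    profiles["TZ"] = np.linspace(0.05, 1.2, N_EPOCHS)
    profiles["WX"] = np.zeros(N_EPOCHS)
    profiles["WY"] = np.zeros(N_EPOCHS)
    profiles["GV"] = np.array([0.25, 0.5, 0.45, 0.35, 0.3, 0.3, 0.25, 0.2, 0.2, 0.2])
    out = np.zeros((len(feature_names), N_EPOCHS))
    for i, f in enumerate(feature_names):
        out[i] = profiles.get(f, np.zeros(N_EPOCHS))
    return effect_scale * out


@dataclass
class GeneratorParams:
    """Stimulus-generator settings.

    ``size_effect`` defaults to the calibrated profile giving encoding-model
    CV accuracies that rise from ~0.65 at 10% occlusion to >0.95 at 60%.
    ``trait_sd`` is the between-agent SD of each feature (constant across
    epochs within an act); ``noise_sd`` is the within-act per-epoch SD.
    """

    n_agents: int = 15
    n_exemplars: int = 2
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    effect_scale: float = 1.0
    size_effect: np.ndarray | None = None
    trait_sd: float = 0.6
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_agents <= 0 or self.n_exemplars <= 0:
            raise ValueError("agent and exemplar counts must be positive")
        if len(self.feature_names) < 3:
            raise ValueError("need at least 3 kinematic features")
        if self.size_effect is None:
            self.size_effect = _default_size_effect(
                self.feature_names, self.effect_scale
            )
        self.size_effect = np.asarray(self.size_effect, dtype=float)
        if self.size_effect.shape != (len(self.feature_names), N_EPOCHS):
            raise ValueError("size_effect must be (F, N_EPOCHS)")
        if not np.all(np.isfinite(self.size_effect)):
            raise ValueError("size_effect must be finite")
        for name, v in (("trait_sd", self.trait_sd), ("noise_sd", self.noise_sd)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


def make_stimulus_set(params: GeneratorParams | None = None,
                      seed: int = 0) -> StimulusSet:
    """Generate ``2 * n_exemplars * n_agents`` reaching acts (default 60)."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    F = len(params.feature_names)
    stimuli = []
    for agent in range(1, params.n_agents + 1):
        trait = rng.normal(0.0, params.trait_sd, size=F)
        for size, sgn in (("small", +1.0), ("large", -1.0)):
            for ex in range(1, params.n_exemplars + 1):
                noise = rng.normal(0.0, params.noise_sd, size=(F, N_EPOCHS))
                feats = trait[:, None] + 0.5 * sgn * params.size_effect + noise
                stimuli.append(
                    KinematicStimulus(
                        stimulus_id=f"a{agent:02d}_{size[0]}{ex}",
                        agent_id=agent,
                        exemplar=ex,
                        object_size=size,
                        features=feats,
                        feature_names=params.feature_names,
                        duration_ms=float(rng.normal(1000.0, 80.0)),
                    )
                )
    return StimulusSet(stimuli=stimuli,
                       feature_names=params.feature_names,
                       size_effect=params.size_effect.copy())


# ---------------------------------------------------------------------------
# experimental design


def make_design(spec: DesignSpec | None = None,
                stimuli: StimulusSet | None = None) -> pd.DataFrame:
    """Trial stubs (no responses) for one session.

    Occlusion levels are exactly balanced across the session, every block
    contains every level, and small_first / large_first configurations are
    balanced within level (odd counts break toward small_first).  The two
    acts of a trial always have opposite object size and come from the same
    agent (a uniformly drawn agent, then uniform exemplars), so that
    cross-validation grouped by agent never leaks act-specific idiosyncrasy
    between folds.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng(spec.seed)
    levels = list(spec.occlusion_levels)
    L, B = len(levels), spec.n_blocks
    per_level = spec.n_trials // L
    per_block = spec.n_trials // B

    # allocation matrix: levels x blocks, row sums per_level, col sums
    # per_block, every entry >= 1 (round-robin spread of the remainder)
    base = per_level // B
    extra = per_level - base * B
    alloc = np.full((L, B), base, dtype=int)
    for li in range(L):
        for j in range(extra):
            alloc[li, (li + j) % B] += 1
    if base == 0 and extra < B:
        raise ValueError("cannot place every occlusion level in every block")

    # configuration assignment balanced within level
    config_pool: dict[int, list[str]] = {}
    for li, lev in enumerate(levels):
        n_small = (per_level + 1) // 2  # ties toward small_first
        pool = ["small_first"] * n_small + ["large_first"] * (per_level - n_small)
        rng.shuffle(pool)
        config_pool[lev] = pool

    by_agent: dict[int, dict[str, list[str]]] = {}
    if stimuli is not None:
        for s in stimuli.stimuli:
            by_agent.setdefault(s.agent_id, {"small": [], "large": []})[
                s.object_size].append(s.stimulus_id)
        agents = sorted(a for a, d in by_agent.items()
                        if d["small"] and d["large"])
        if not agents:
            raise ValueError(
                "stimulus set must contain both object sizes for some agent")

    rows = []
    trial_id = 0
    for b in range(1, B + 1):
        block_levels: list[int] = []
        for li, lev in enumerate(levels):
            block_levels.extend([lev] * alloc[li, b - 1])
        rng.shuffle(block_levels)
        if spec.instruction_order == "small_first_half":
            instruction = "report_small" if b <= B // 2 else "report_large"
        else:
            instruction = "report_large" if b <= B // 2 else "report_small"
        for lev in block_levels:
            trial_id += 1
            config = config_pool[lev].pop()
            if stimuli is not None:
                agent = agents[rng.integers(len(agents))]
                pool = by_agent[agent]
                s_id = pool["small"][rng.integers(len(pool["small"]))]
                l_id = pool["large"][rng.integers(len(pool["large"]))]
                first, second = (
                    (s_id, l_id) if config == "small_first" else (l_id, s_id)
                )
            else:
                first = second = ""
            rows.append(
                dict(trial_id=trial_id, block=b, occlusion_level=lev,
                     first_stimulus_id=first, second_stimulus_id=second,
                     configuration=config, instruction=instruction,
                     response_interval=None, chose_small_first=None,
                     correct=None, confidence=None)
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# observer presets

#: Decision-noise SD shared by both presets; calibrated so the control
#: preset's accuracy rises from ~0.6 at 10% occlusion to ~0.95 late while
#: the patient preset stays at chance through its null window yet exceeds
#: 0.85 at 60%, matching the shape of human data on this task.
DEFAULT_OBSERVER_NOISE_SD = 0.6
#: Multiplicative attenuation of patient readout weights after the null
#: window.
PATIENT_GAIN = 0.7
PATIENT_NULL_WINDOW_PCT = 20


def observer_preset(group: str, stimuli: StimulusSet,
                    noise_sd: float = DEFAULT_OBSERVER_NOISE_SD,
                    lapse: float = 0.02) -> ObserverProfile:
    """Control or patient observer for a given stimulus set.

    Both presets read the generator's true size-effect direction (unit L2
    norm over feature x epoch).  The patient preset zeroes all weights for
    epochs at or below 20% of movement duration, attenuates the remainder
    by ``PATIENT_GAIN``, and reports confidence unrelated to the evidence
    within that same window.
    """
    if group not in ("control", "patient"):
        raise ValueError(f"unknown group label: {group}")
    w = np.asarray(stimuli.size_effect, dtype=float).copy()
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    if group == "control":
        return ObserverProfile(group="control", weights=w, bias=0.0,
                               noise_sd=noise_sd, lapse=lapse,
                               null_window_pct=0, confidence_gain=1.0,
                               confidence_miscalibrated_window_pct=0)
    n_null = PATIENT_NULL_WINDOW_PCT // 10
    w = w * PATIENT_GAIN
    w[:, :n_null] = 0.0
    return ObserverProfile(group="patient", weights=w, bias=0.0,
                           noise_sd=noise_sd, lapse=lapse,
                           null_window_pct=PATIENT_NULL_WINDOW_PCT,
                           confidence_gain=1.0,
                           confidence_miscalibrated_window_pct=PATIENT_NULL_WINDOW_PCT)


# ---------------------------------------------------------------------------
# observer simulation


def _delta_matrix_full(design: pd.DataFrame, stimuli: StimulusSet) -> np.ndarray:
    """Per-trial first-minus-second feature difference, all epochs (n, F, E)."""
    out = np.empty((len(design), len(stimuli.feature_names), N_EPOCHS))
    for i, row in enumerate(design.itertuples(index=False)):
        if row.first_stimulus_id not in stimuli or row.second_stimulus_id not in stimuli:
            raise KeyError(
                f"trial {row.trial_id} references unknown stimuli "
                f"({row.first_stimulus_id!r}, {row.second_stimulus_id!r})"
            )
        out[i] = (stimuli[row.first_stimulus_id].features
                  - stimuli[row.second_stimulus_id].features)
    return out


def _decision_variables(design: pd.DataFrame, stimuli: StimulusSet,
                        profile: ObserverProfile,
                        rng: np.random.Generator) -> np.ndarray:
    """Noisy decision variable d per trial, using visible epochs only."""
    dk = _delta_matrix_full(design, stimuli)
    occ = design["occlusion_level"].to_numpy(dtype=int)
    n_vis = occ // 10
    evidence = np.empty(len(design))
    for i in range(len(design)):
        k = n_vis[i]
        evidence[i] = float(np.sum(dk[i, :, :k] * profile.weights[:, :k]))
    d = evidence + profile.bias + rng.normal(0.0, profile.noise_sd, len(design))
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite decision variable")
    return d


#: Internal seed used to calibrate confidence bins from the control preset,
#: fixed so that every observer of a cohort rates on a common scale.
_CONFIDENCE_CALIBRATION_SEED = 20240110


def calibrate_confidence_bins(stimuli: StimulusSet, design: pd.DataFrame,
                              noise_sd: float = DEFAULT_OBSERVER_NOISE_SD,
                              confidence_gain: float = 1.0,
                              n_draws: int = 25) -> np.ndarray:
    """Quartile edges of |gain * d| under the control preset.

    Confidence ratings 1-4 are the quartile bins of the rescaled absolute
    decision variable; calibrating the edges once, from the control preset,
    puts control and patient ratings on a common scale.
    """
    control = observer_preset("control", stimuli, noise_sd=noise_sd, lapse=0.0)
    rng = np.random.default_rng(_CONFIDENCE_CALIBRATION_SEED)
    samples = []
    for _ in range(n_draws):
        d = _decision_variables(design, stimuli, control, rng)
        samples.append(np.abs(confidence_gain * d))
    pooled = np.concatenate(samples)
    return np.quantile(pooled, [0.25, 0.5, 0.75])


def simulate_observer(profile: ObserverProfile, design: pd.DataFrame,
                      stimuli: StimulusSet, seed: int,
                      observer_id: str = "obs",
                      confidence_bins: np.ndarray | None = None) -> ObserverSession:
    """Complete a session of trial stubs for one synthetic observer.

    Choice: ``small first`` iff d > 0 (exact tie -> large first), flipped
    with probability ``lapse``.  Confidence: quartile bin of
    ``confidence_gain * |d|`` against control-calibrated edges; on trials
    within the miscalibrated window, confidence is redrawn from the
    observer's own overall confidence distribution, independent of d.
    """
    rng = np.random.default_rng(seed)
    if confidence_bins is None:
        confidence_bins = calibrate_confidence_bins(
            stimuli, design, noise_sd=profile.noise_sd,
            confidence_gain=profile.confidence_gain)
    d = _decision_variables(design, stimuli, profile, rng)
    chose_small = d > 0  # tie d == 0 -> large_first
    flips = rng.random(len(d)) < profile.lapse
    chose_small = np.where(flips, ~chose_small, chose_small)

    conf = 1 + np.searchsorted(confidence_bins,
                               profile.confidence_gain * np.abs(d))
    occ = design["occlusion_level"].to_numpy(dtype=int)
    window = occ <= profile.confidence_miscalibrated_window_pct
    if np.any(window):
        # draw from the observer's own overall confidence distribution
        conf = conf.copy()
        conf[window] = rng.choice(conf, size=int(np.sum(window)))

    trials = design.copy()
    trials["chose_small_first"] = chose_small
    trials["correct"] = chose_small == (trials["configuration"] == "small_first")
    small_interval = np.where(trials["configuration"] == "small_first",
                              "first", "second")
    large_interval = np.where(trials["configuration"] == "small_first",
                              "second", "first")
    trials["response_interval"] = np.where(
        trials["instruction"] == "report_small",
        np.where(chose_small, small_interval, large_interval),
        np.where(chose_small, large_interval, small_interval),
    )
    trials["confidence"] = conf.astype(int)
    return ObserverSession(observer_id=observer_id, group=profile.group,
                           trials=trials, profile=profile)


def simulate_cohort(stimuli: StimulusSet, design_spec: DesignSpec,
                    n_control: int, n_patient: int, seed: int,
                    noise_sd: float = DEFAULT_OBSERVER_NOISE_SD,
                    lapse: float = 0.02) -> list[ObserverSession]:
    """Simulate a two-group cohort, one fresh design per observer."""
    ss = np.random.SeedSequence(seed)
    sessions = []
    bins = None
    idx = 0
    for group, n in (("control", n_control), ("patient", n_patient)):
        profile = observer_preset(group, stimuli, noise_sd=noise_sd, lapse=lapse)
        for j in range(n):
            child = ss.spawn(1)[0]
            obs_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            design = make_design(
                replace(design_spec, seed=obs_seed), stimuli
            )
            if bins is None:
                bins = calibrate_confidence_bins(stimuli, design,
                                                 noise_sd=noise_sd)
            sessions.append(
                simulate_observer(profile, design, stimuli, seed=obs_seed,
                                  observer_id=f"{group[0]}{j + 1:02d}",
                                  confidence_bins=bins)
            )
            idx += 1
    return sessions
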