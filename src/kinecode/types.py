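"""Core domain types for the occluded action-prediction analysis.

The task being modelled is a two-alternative forced-choice (2AFC) object-size
discrimination: on each trial the observer watches two reach-to-grasp movies
(one toward a small object, one toward a large object), truncated at one of
eight temporal-occlusion levels (10--80% of movement duration), and reports
which interval contained the small (or large, depending on block instruction)
object, followed by a 1--4 confidence rating.

Kinematics are represented on a grid of ``N_EPOCHS`` equal bins of normalized
movement time; occlusion level ``o`` exposes the first ``o / 10`` bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_EPOCHS = 10
OCCLUSION_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80)

#: Kinematic channels tracked for every reaching act.  GA = grip aperture
#: (thumb-index distance), the earliest size-informative feature; IZ/IX/IY =
#: index-finger coordinates, TZ/TX/TY = thumb coordinates, WZ/WX/WY = wrist
#: coordinates, WV = wrist velocity, GV = grip-aperture velocity.
DEFAULT_FEATURES = (
    "GA", "IZ", "WZ", "WV", "IX", "IY", "TX", "TY", "TZ", "WX", "WY", "GV",
)


@dataclass
class KinematicStimulus:
    """One reaching act: a feature-by-epoch matrix plus its object-size label."""

    stimulus_id: str
    agent_id: int
    exemplar: int
    object_size: str  # "small" | "large"
    features: np.ndarray  # (F, N_EPOCHS)
    feature_names: tuple[str, ...]
    duration_ms: float = 1000.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_EPOCHS:
            raise ValueError(
                f"features must be (F, {N_EPOCHS}), got {self.features.shape}"
            )
        if self.features.shape[0] != len(self.feature_names):
            raise ValueError("feature_names length must match feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("all feature values must be finite")
        if self.object_size not in ("small", "large"):
            raise ValueError(f"object_size must be small/large, got {self.object_size}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    def visible(self, occlusion_level: int) -> np.ndarray:
        """Feature matrix restricted to epochs exposed at an occlusion level."""
        n = _n_visible_epochs(occlusion_level)
        return self.features[:, :n]


def _n_visible_epochs(occlusion_level: int) -> int:
    if occlusion_level not in OCCLUSION_LEVELS:
        raise ValueError(
            f"occlusion level {occlusion_level} not on the grid {OCCLUSION_LEVELS}"
        )
    return occlusion_level // 10


@dataclass
class StimulusSet:
    """A set of reaching acts plus the generative size-effect profile.

    ``size_effect[f, e]`` is the expected small-minus-large difference of
    feature ``f`` at epoch ``e``; synthetic ideal observers use its direction
    as their generative readout weights.
    """

    stimuli: list[KinematicStimulus]
    feature_names: tuple[str, ...]
    size_effect: np.ndarray  # (F, N_EPOCHS)

    def __post_init__(self) -> None:
        self.size_effect = np.asarray(self.size_effect, dtype=float)
        self._by_id = {s.stimulus_id: s for s in self.stimuli}

    def __len__(self) -> int:
        return len(self.stimuli)

    def __getitem__(self, stimulus_id: str) -> KinematicStimulus:
        try:
            return self._by_id[stimulus_id]
        except KeyError:
            raise KeyError(f"unknown stimulus id: {stimulus_id}") from None

    def __contains__(self, stimulus_id: str) -> bool:
        return stimulus_id in self._by_id

    def ids(self, object_size: str | None = None) -> list[str]:
        return [
            s.stimulus_id
            for s in self.stimuli
            if object_size is None or s.object_size == object_size
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: stimulus_id, agent_id, exemplar, object_size, feature, epoch, value."""
        rows = []
        for s in self.stimuli:
            for fi, f in enumerate(self.feature_names):
                for e in range(N_EPOCHS):
                    rows.append(
                        (s.stimulus_id, s.agent_id, s.exemplar, s.object_size,
                         f, e + 1, s.features[fi, e])
                    )
        return pd.DataFrame(
            rows,
            columns=["stimulus_id", "agent_id", "exemplar", "object_size",
                     "feature", "epoch", "value"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   size_effect: np.ndarray | None = None) -> "StimulusSet":
        feature_names = tuple(pd.unique(df["feature"]))
        stimuli = []
        for sid, grp in df.groupby("stimulus_id", sort=False):
            mat = (
                grp.pivot_table(index="feature", columns="epoch", values="value")
                .reindex(index=list(feature_names))
                .to_numpy()
            )
            first = grp.iloc[0]
            stimuli.append(
                KinematicStimulus(
                    stimulus_id=str(sid),
                    agent_id=int(first["agent_id"]),
                    exemplar=int(first["exemplar"]),
                    object_size=str(first["object_size"]),
                    features=mat,
                    feature_names=feature_names,
                )
            )
        if size_effect is None:
            size_effect = np.zeros((len(feature_names), N_EPOCHS))
        return cls(stimuli=stimuli, feature_names=feature_names,
                   size_effect=size_effect)


@dataclass
class DesignSpec:
    """Session design: trial counts, blocking, and occlusion balancing."""

    n_trials: int = 240
    n_blocks: int = 8
    occlusion_levels: tuple[int, ...] = OCCLUSION_LEVELS
    seed: int = 0
    instruction_order: str = "small_first_half"  # or "large_first_half"

    def __post_init__(self) -> None:
        if self.n_blocks <= 0 or self.n_trials <= 0:
            raise ValueError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks != 0:
            raise ValueError("n_trials must be divisible by n_blocks")
        if len(self.occlusion_levels) == 0:
            raise ValueError("occlusion_levels must be non-empty")
        for o in self.occlusion_levels:
            _n_visible_epochs(o)
        per_block = self.n_trials // self.n_blocks
        if per_block < len(self.occlusion_levels):
            raise ValueError(
                "each block must hold at least one trial per occlusion level"
            )
        if self.n_trials % len(self.occlusion_levels) != 0:
            raise ValueError(
                "n_trials must divide evenly across occlusion levels "
                "(exact session balance)"
            )


@dataclass
class ObserverProfile:
    """Generative model of one synthetic observer.

    The observer forms a decision variable ``d = dK . weights + bias + noise``
    from the visible-epoch kinematic difference ``dK`` of the two intervals,
    answers "small first" when ``d > 0`` (flipped with probability ``lapse``),
    and rates confidence by binning ``confidence_gain * |d|``.  Epochs at or
    below ``null_window_pct`` carry zero weight (a null-integration window);
    within ``confidence_miscalibrated_window_pct`` confidence is drawn
    independently of the evidence.
    """

    group: str  # "control" | "patient"
    weights: np.ndarray  # (F, N_EPOCHS)
    bias: float = 0.0
    noise_sd: float = 1.0
    lapse: float = 0.02
    null_window_pct: int = 0
    confidence_gain: float = 1.0
    confidence_miscalibrated_window_pct: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group: {self.group}")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.confidence_gain <= 0:
            raise ValueError("confidence_gain must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")


@dataclass
class ObserverSession:
    """Completed session: observer metadata plus one row per trial."""

    observer_id: str
    group: str
    trials: pd.DataFrame
    profile: ObserverProfile | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.trials.copy()
        df.insert(0, "observer_id", self.observer_id)
        df.insert(1, "group", self.group)
        return df


TRIAL_COLUMNS = [
    "trial_id", "block", "occlusion_level", "first_stimulus_id",
    "second_stimulus_id", "configuration", "instruction", "response_interval",
    "chose_small_first", "correct", "confidence",
]


def sessions_frame(sessions: list[ObserverSession]) -> pd.DataFrame:
    """Concatenate sessions into one tidy trial table."""
    if not sessions:
        raise ValueError("no sessions given")
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)
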