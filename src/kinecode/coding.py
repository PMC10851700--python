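"""Single-trial kinematic encoding and readout models.

At each occlusion level the predictor for a trial is the vector of
first-interval minus second-interval kinematic features restricted to the
visible epochs, flattened feature-major (all visible epochs of feature 1,
then feature 2, ...).  Two penalized logistic models share this predictor:

* the **encoding model** predicts the true configuration (small object in
  the first interval) and quantifies the size information available in the
  kinematics to an ideal observer;
* the **readout model**, fitted per observer, predicts the observer's own
  choice and quantifies the information that observer actually used.

Both report cross-validated (CV) accuracy; readout accuracy is referenced
to a permutation chance level (the mean of the CV-accuracy distribution
after shuffling the observer's responses).  The readout intercept measures
evidence-independent response bias, summarized as the fractional bias
contribution |b| / (|b| + mean |dK . beta|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import DEFAULT_LAMBDA_GRID, cv_logistic
from .types import StimulusSet, _n_visible_epochs


# ---------------------------------------------------------------------------
# predictors


def trial_delta_features(first_id: str, second_id: str, stimuli: StimulusSet,
                         occlusion: int) -> np.ndarray:
    """Flattened first-minus-second kinematic difference, visible epochs only.

    Ordering is feature-major: entry ``f * n_vis + e`` is feature ``f`` at
    visible epoch ``e`` (0-based), with ``n_vis = occlusion / 10``.
    """
    n_vis = _n_visible_epochs(occlusion)
    diff = (stimuli[first_id].visible(occlusion)
            - stimuli[second_id].visible(occlusion))
    return diff.reshape(-1)  # row-major == feature-major


def feature_epoch_index(feature_names: tuple[str, ...],
                        occlusion: int) -> pd.MultiIndex:
    """(feature, epoch) labels aligned with the flattened predictor."""
    n_vis = occlusion // 10
    return pd.MultiIndex.from_product(
        [list(feature_names), list(range(1, n_vis + 1))],
        names=["feature", "epoch"],
    )


def build_delta_matrix(trials: pd.DataFrame, stimuli: StimulusSet,
                       occlusion: int) -> np.ndarray:
    """Stack trial_delta_features for all rows of a trial table."""
    return np.stack([
        trial_delta_features(r.first_stimulus_id, r.second_stimulus_id,
                             stimuli, occlusion)
        for r in trials.itertuples(index=False)
    ])


# ---------------------------------------------------------------------------
# fits


@dataclass
class EncodingFit:
    """Encoding model at one occlusion level."""

    occlusion_level: int
    feature_names: tuple[str, ...]
    beta: np.ndarray  # (F * n_vis,), feature-major
    intercept: float
    penalty: float
    cv_accuracy: float
    cv_sem: float
    fold_assignments: np.ndarray

    def coef_matrix(self) -> np.ndarray:
        """(F, n_vis) view of the coefficient vector."""
        n_vis = self.occlusion_level // 10
        return self.beta.reshape(len(self.feature_names), n_vis)


@dataclass
class ReadoutFit:
    """Per-observer readout model at one occlusion level."""

    observer_id: str
    occlusion_level: int
    feature_names: tuple[str, ...]
    beta: np.ndarray
    intercept: float  # the evidence-independent bias term
    penalty: float
    cv_accuracy: float
    cv_sem: float
    heldout_proba: np.ndarray  # per-trial held-out P(chose small first)
    heldout_pred: np.ndarray
    trial_ids: np.ndarray
    degenerate: bool = False
    chance_level: float | None = None
    null_quantiles: dict[str, float] | None = None
    bias_fraction: float | None = None

    def coef_matrix(self) -> np.ndarray:
        n_vis = self.occlusion_level // 10
        return self.beta.reshape(len(self.feature_names), n_vis)

    @property
    def predicted_confidence(self) -> np.ndarray:
        """Per-trial model confidence: deviation of P-hat from chance."""
        return np.abs(self.heldout_proba - 0.5)


def fit_encoding(trials: pd.DataFrame, stimuli: StimulusSet, occlusion: int,
                 seed: int = 0, outer_k: int = 10, inner_k: int = 5,
                 lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                 min_trials: int = 20) -> EncodingFit:
    """Fit the encoding model on one occlusion level's trials.

    Labels are the true configuration (small object first).  Outer CV folds
    are grouped by the trial's (unordered) agent pair, so held-out trials
    come from actors unseen during training: with the within-agent pairing
    of the default design this removes stimulus-identity leakage entirely
    and drives the no-signal null to chance exactly.
    """
    sub = trials[trials["occlusion_level"] == occlusion]
    if len(sub) < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials at occlusion {occlusion}, got {len(sub)}"
        )
    y = (sub["configuration"] == "small_first").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both configurations must be present")
    X = build_delta_matrix(sub, stimuli, occlusion)
    pairs = np.array([
        "|".join(sorted((str(stimuli[a].agent_id), str(stimuli[b].agent_id))))
        for a, b in zip(sub["first_stimulus_id"], sub["second_stimulus_id"])
    ])
    res = cv_logistic(X, y, seed=seed, outer_k=outer_k, inner_k=inner_k,
                      lam_grid=lam_grid, groups=pairs)
    return EncodingFit(
        occlusion_level=occlusion,
        feature_names=stimuli.feature_names,
        beta=res.beta, intercept=res.intercept, penalty=res.penalty,
        cv_accuracy=res.cv_accuracy, cv_sem=res.cv_sem,
        fold_assignments=res.fold_assignments,
    )


def fit_readout(session_trials: pd.DataFrame, stimuli: StimulusSet,
                occlusion: int, observer_id: str = "obs", seed: int = 0,
                outer_k: int = 10, inner_k: int = 5,
                lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                min_trials: int = 15) -> ReadoutFit:
    """Fit one observer's readout model at one occlusion level.

    Labels are the observer's choices.  An observer who answered identically
    on every trial yields a degenerate fit: zero coefficients and
    CV accuracy equal to the base rate.
    """
    sub = session_trials[session_trials["occlusion_level"] == occlusion]
    if len(sub) < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials at occlusion {occlusion}, got {len(sub)}"
        )
    y = sub["chose_small_first"].to_numpy().astype(int)
    X = build_delta_matrix(sub, stimuli, occlusion)
    trial_ids = sub["trial_id"].to_numpy()
    if len(np.unique(y)) < 2:
        base = float(np.mean(y == int(round(np.mean(y)))))
        p = len(stimuli.feature_names) * (occlusion // 10)
        return ReadoutFit(
            observer_id=observer_id, occlusion_level=occlusion,
            feature_names=stimuli.feature_names,
            beta=np.zeros(p), intercept=0.0, penalty=np.nan,
            cv_accuracy=base, cv_sem=0.0,
            heldout_proba=np.full(len(y), float(np.mean(y))),
            heldout_pred=np.full(len(y), int(round(np.mean(y)))),
            trial_ids=trial_ids, degenerate=True,
        )
    res = cv_logistic(X, y, seed=seed, outer_k=outer_k, inner_k=inner_k,
                      lam_grid=lam_grid)
    fit = ReadoutFit(
        observer_id=observer_id, occlusion_level=occlusion,
        feature_names=stimuli.feature_names,
        beta=res.beta, intercept=res.intercept, penalty=res.penalty,
        cv_accuracy=res.cv_accuracy, cv_sem=res.cv_sem,
        heldout_proba=res.heldout_proba, heldout_pred=res.heldout_pred,
        trial_ids=trial_ids,
    )
    fit.bias_fraction = bias_fraction(fit, X)
    return fit


# ---------------------------------------------------------------------------
# permutation chance level


def readout_chance_null(trials: pd.DataFrame, stimuli: StimulusSet,
                        occlusion: int, n_perm: int, seed: int,
                        outer_k: int = 10, inner_k: int = 5,
                        lam_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                        labels: str = "chose_small_first") -> dict:
    """Null distribution of CV accuracy under label permutation.

    Responses are shuffled within the occlusion level and the full nested-CV
    pipeline re-run per permutation; the chance level is the mean of the
    resulting distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (null mean is unstable below)")
    sub = trials[trials["occlusion_level"] == occlusion]
    y = sub[labels].to_numpy().astype(int)
    X = build_delta_matrix(sub, stimuli, occlusion)
    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    cv_seeds = (np.random.SeedSequence(seed).generate_state(n_perm + 1)
                & 0x7FFFFFFF)
    accs = np.empty(n_perm)
    for i in range(n_perm):
        yp = perm_rng.permutation(y)
        if len(np.unique(yp)) < 2:  # cannot happen for mixed y, kept for safety
            accs[i] = float(np.mean(yp))
            continue
        res = cv_logistic(X, yp, seed=int(cv_seeds[i + 1]), outer_k=outer_k,
                          inner_k=inner_k, lam_grid=lam_grid)
        accs[i] = res.cv_accuracy
    return {
        "null_accuracies": accs,
        "chance_level": float(np.mean(accs)),
        "quantiles": {
            "q025": float(np.quantile(accs, 0.025)),
            "q500": float(np.quantile(accs, 0.5)),
            "q950": float(np.quantile(accs, 0.95)),
            "q975": float(np.quantile(accs, 0.975)),
        },
    }


def attach_chance_level(fit: ReadoutFit, trials: pd.DataFrame,
                        stimuli: StimulusSet, n_perm: int, seed: int,
                        **kwargs) -> ReadoutFit:
    null = readout_chance_null(trials, stimuli, fit.occlusion_level,
                               n_perm=n_perm, seed=seed, **kwargs)
    fit.chance_level = null["chance_level"]
    fit.null_quantiles = null["quantiles"]
    return fit


# ---------------------------------------------------------------------------
# bias decomposition


def bias_fraction(fit: ReadoutFit, X: np.ndarray) -> float:
    """Fractional contribution of the evidence-independent intercept.

    |b| / (|b| + mean_t |dK_t . beta|); 0 when the intercept is 0, undefined
    (NaN) for a degenerate fit with zero denominator.
    """
    evid = float(np.mean(np.abs(np.asarray(X) @ fit.beta)))
    denom = abs(fit.intercept) + evid
    if denom == 0.0:
        return float("nan")
    return abs(fit.intercept) / denom


def group_bias_test(fits: list[ReadoutFit], n_flip: int = 10000,
                    seed: int = 0) -> dict:
    """Sign-flip test of the readout intercepts across observers.

    Under no systematic bias, b_read is symmetric about 0 across observers;
    the two-sided p-value is the sign-flip permutation probability of a mean
    at least as extreme as observed.
    """
    b = np.array([f.intercept for f in fits if not f.degenerate])
    if len(b) == 0:
        return {"mean_intercept": float("nan"), "p_value": float("nan"), "n": 0}
    rng = np.random.default_rng(seed)
    obs = abs(np.mean(b))
    signs = rng.choice([-1.0, 1.0], size=(n_flip, len(b)))
    null = np.abs(np.mean(signs * b, axis=1))
    p = float((np.sum(null >= obs - 1e-15) + 1) / (n_flip + 1))
    return {"mean_intercept": float(np.mean(b)), "p_value": p, "n": len(b)}


# ---------------------------------------------------------------------------
# encoding profiles across occlusion levels


def encoding_profile(fits: list[EncodingFit]) -> dict:
    """Feature contributions and cross-occlusion coefficient stability.

    Contribution of feature f at a level is the summed |coefficient| over
    its visible epochs, normalized to 1 across features.  Stability between
    two levels is the Pearson correlation of the coefficient vectors on
    their shared feature x epoch support.  Features are ordered by their
    contribution at the highest fitted level (descending).
    """
    if len(fits) < 2:
        raise ValueError("need fits at >= 2 occlusion levels")
    fits = sorted(fits, key=lambda f: f.occlusion_level)
    feature_names = fits[0].feature_names
    levels = [f.occlusion_level for f in fits]

    contrib_rows, epoch_rows = [], []
    for f in fits:
        mat = np.abs(f.coef_matrix())
        total = mat.sum()
        contrib = mat.sum(axis=1) / total if total > 0 else np.zeros(len(mat))
        for fi, name in enumerate(feature_names):
            contrib_rows.append((f.occlusion_level, name, contrib[fi]))
            for e in range(mat.shape[1]):
                epoch_rows.append(
                    (f.occlusion_level, name, e + 1,
                     mat[fi, e] / total if total > 0 else 0.0)
                )
    contributions = pd.DataFrame(
        contrib_rows, columns=["occlusion_level", "feature", "contribution"]
    )
    per_epoch = pd.DataFrame(
        epoch_rows, columns=["occlusion_level", "feature", "epoch", "contribution"]
    )

    stability = pd.DataFrame(np.nan, index=levels, columns=levels, dtype=float)
    for i, fa in enumerate(fits):
        for j, fb in enumerate(fits):
            n_shared = min(fa.occlusion_level, fb.occlusion_level) // 10
            va = fa.coef_matrix()[:, :n_shared].reshape(-1)
            vb = fb.coef_matrix()[:, :n_shared].reshape(-1)
            if len(va) < 2 or np.std(va) == 0 or np.std(vb) == 0:
                continue
            stability.iloc[i, j] = float(np.corrcoef(va, vb)[0, 1])

    top = fits[-1]
    order_key = np.abs(top.coef_matrix()).sum(axis=1)
    order = [feature_names[i] for i in np.argsort(-order_key, kind="stable")]
    return {
        "contributions": contributions,
        "per_epoch": per_epoch,
        "stability": stability,
        "feature_order": order,
    }


# ---------------------------------------------------------------------------
# model predictions vs behaviour


def readout_predictions(fits: list[ReadoutFit],
                        sessions: pd.DataFrame) -> dict:
    """Predicted-vs-observed accuracy and confidence agreement.

    Predicted accuracy for an observer x level is the fraction of held-out
    trials on which the model's predicted choice matches the correct
    configuration; observed accuracy is the observer's own fraction correct.
    Confidence agreement correlates the per-trial model confidence
    |P-hat - 0.5| with the reported 1-4 rating (never used in fitting).
    """
    sess = sessions.set_index(["observer_id", "trial_id"])
    groups = sessions.drop_duplicates("observer_id").set_index("observer_id")["group"]

    acc_rows, conf_rows = [], []
    for fit in fits:
        sub = sess.loc[fit.observer_id].loc[fit.trial_ids]
        truth = (sub["configuration"] == "small_first").to_numpy().astype(int)
        predicted_acc = float(np.mean(fit.heldout_pred == truth))
        observed_acc = float(np.mean(sub["correct"].to_numpy().astype(bool)))
        acc_rows.append((fit.observer_id, groups[fit.observer_id],
                         fit.occlusion_level, predicted_acc, observed_acc))
        conf = sub["confidence"].to_numpy(dtype=float)
        for pc, c in zip(fit.predicted_confidence, conf):
            if np.isfinite(c):
                conf_rows.append((fit.observer_id, groups[fit.observer_id],
                                  fit.occlusion_level, pc, c))
    acc = pd.DataFrame(acc_rows, columns=["observer_id", "group",
                                          "occlusion_level",
                                          "predicted_accuracy",
                                          "observed_accuracy"])
    conf = pd.DataFrame(conf_rows, columns=["observer_id", "group",
                                            "occlusion_level",
                                            "predicted_confidence",
                                            "confidence"])

    def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    accuracy_corr, confidence_corr = {}, {}
    for g, sub in acc.groupby("group"):
        if sub["observer_id"].nunique() < 3:
            accuracy_corr[g] = {"r": float("nan"), "p": float("nan"),
                                "n": len(sub)}
            continue
        r, p = _corr(sub["predicted_accuracy"].to_numpy(),
                     sub["observed_accuracy"].to_numpy())
        accuracy_corr[g] = {"r": r, "p": p, "n": len(sub)}
    for g, sub in conf.groupby("group"):
        r, p = _corr(sub["predicted_confidence"].to_numpy(),
                     sub["confidence"].to_numpy())
        confidence_corr[g] = {"r": r, "p": p, "n": len(sub)}
    return {"accuracy_pairs": acc, "confidence_pairs": conf,
            "accuracy_corr": accuracy_corr, "confidence_corr": confidence_corr}


def information_read(enc: EncodingFit, observer_trials: pd.DataFrame) -> float:
    """Fraction of the encoded information the observer extracted.

    clip0( (acc_obs - 1/2) / (acc_enc - 1/2) ), clipped to [0, 1]; NaN when
    the encoding model itself is at or below chance.
    """
    sub = observer_trials[
        observer_trials["occlusion_level"] == enc.occlusion_level
    ]
    if len(sub) == 0:
        raise ValueError("no observer trials at this occlusion level")
    acc_obs = float(np.mean(sub["correct"].to_numpy().astype(bool)))
    if enc.cv_accuracy <= 0.5:
        return float("nan")
    return float(np.clip((acc_obs - 0.5) / (enc.cv_accuracy - 0.5), 0.0, 1.0))
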