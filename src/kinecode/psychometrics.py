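"""Psychometric curves, piecewise change-point fitting, and confidence
calibration for the occluded 2AFC size-discrimination task.

Signed occlusion codes the stimulus configuration: ``+o`` on trials where
the small object appeared in the first interval, ``-o`` where it appeared
second.  The psychometric function P(respond "small first") is modelled on
the logit scale as a two-segment piecewise-linear function of signed
occlusion, odd-symmetric about 0 and continuous at the change-point knots
``+/-c``:

    logit P = b0 + s1 * f1(x; c) + s2 * f2(x; c)
    f1 = sign(x) * min(|x|, c),   f2 = sign(x) * max(|x| - c, 0)

with a participant random intercept.  The change point is selected by AIC
over a candidate grid and its two slopes are tested against a single-slope
model by a likelihood-ratio test.  Confidence-accuracy calibration divides
the session at the change point into an early and a late integration
period and compares the normalized-confidence / accuracy ratio across
groups and periods with a linear mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .mixed import MixedLogitResult, fit_mixed_logit, likelihood_ratio_test


def signed_occlusion(trials: pd.DataFrame) -> np.ndarray:
    """+o on small-first trials, -o on large-first trials."""
    sign = np.where(trials["configuration"] == "small_first", 1.0, -1.0)
    return sign * trials["occlusion_level"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# empirical summaries


def empirical_curve(sessions: pd.DataFrame) -> pd.DataFrame:
    """P(small first) by signed occlusion x group: participant mean +/- SEM.

    All 16 signed levels are always present; a cell with no trials for any
    participant is reported as NaN (missing), never as 0.
    """
    if len(sessions) == 0:
        raise ValueError("no sessions given")
    df = sessions.copy()
    df["signed_occlusion"] = signed_occlusion(df)
    df["resp"] = df["chose_small_first"].astype(float)
    per = (df.groupby(["group", "observer_id", "signed_occlusion"])["resp"]
           .mean().rename("p_small_first").reset_index())
    levels = sorted(
        set([float(o) for o in df["occlusion_level"].unique()])
        | set([-float(o) for o in df["occlusion_level"].unique()])
    )
    rows = []
    for g, sub in per.groupby("group"):
        for lev in levels:
            vals = sub.loc[sub["signed_occlusion"] == lev, "p_small_first"]
            if len(vals) == 0:
                rows.append((g, lev, np.nan, np.nan, 0))
            else:
                sem = (vals.std(ddof=1) / np.sqrt(len(vals))
                       if len(vals) > 1 else np.nan)
                rows.append((g, lev, vals.mean(), sem, len(vals)))
    return pd.DataFrame(
        rows, columns=["group", "signed_occlusion", "p_small_first",
                       "sem", "n_participants"]
    )


def accuracy_by_occlusion(sessions: pd.DataFrame,
                          by_stimulus: bool = False) -> pd.DataFrame:
    """Fraction correct by occlusion x group (participant-mean, never pooled).

    With ``by_stimulus=True`` the table is additionally split by unordered
    stimulus pair (trial-pooled within pair), which exposes individual
    movements that are discriminable inside an at-chance period.
    """
    df = sessions.copy()
    df["correct"] = df["correct"].astype(float)
    if by_stimulus:
        df["pair"] = [
            "|".join(sorted((a, b)))
            for a, b in zip(df["first_stimulus_id"], df["second_stimulus_id"])
        ]
        out = (df.groupby(["group", "occlusion_level", "pair"])["correct"]
               .agg(accuracy="mean", n_trials="size").reset_index())
        return out
    per = (df.groupby(["group", "observer_id", "occlusion_level"])["correct"]
           .mean().rename("accuracy").reset_index())
    out = (per.groupby(["group", "occlusion_level"])["accuracy"]
           .agg(accuracy="mean",
                sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1
                else np.nan,
                n_participants="size")
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# piecewise psychometric fitting


def piecewise_basis(x: np.ndarray, c: float) -> np.ndarray:
    """Two-segment odd-symmetric basis continuous at +/-c: columns f1, f2."""
    ax, sx = np.abs(x), np.sign(x)
    return np.column_stack([sx * np.minimum(ax, c), sx * np.maximum(ax - c, 0.0)])


@dataclass
class PsychometricFit:
    change_point: float
    slopes: pd.DataFrame  # term, estimate, se, z, p
    group_terms: pd.DataFrame | None
    random_effect_sd: float
    loglik: float
    aic: float
    candidate_table: pd.DataFrame
    lrt_vs_single_slope: dict
    method: str
    result: MixedLogitResult


def _design(x: np.ndarray, c: float | None, group: np.ndarray | None):
    """Model matrix + names; c=None gives the single-slope reduced model."""
    if c is None:
        cols = [np.ones_like(x), x]
        names = ["intercept", "slope"]
    else:
        B = piecewise_basis(x, c)
        cols = [np.ones_like(x), B[:, 0], B[:, 1]]
        names = ["intercept", "slope_early", "slope_late"]
    if group is not None:
        g = group.astype(float)
        base = list(cols)
        for col, nm in zip(base[1:], names[1:]):
            cols.append(g * col)
            names.append(f"group_x_{nm}")
        cols.append(g)
        names.append("group")
    return np.column_stack(cols), names


def fit_piecewise_psychometric(
    sessions: pd.DataFrame,
    candidates: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0),
    method: str = "quadrature",
    include_group: bool | None = None,
) -> PsychometricFit:
    """AIC-selected change point for the piecewise psychometric GLMM.

    For each candidate knot ``c`` a binomial mixed model of the
    "small first" response on the two-segment basis (participant random
    intercept; group x segment-slope interactions when two groups are
    present) is fitted; the candidate minimizing AIC is selected and the
    two-segment model compared against the single-slope model by LRT.
    Non-converging candidates are dropped with a warning.
    """
    df = sessions
    if df["observer_id"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    bad = [c for c in candidates if not (10 <= c <= 70)]
    if bad:
        raise ValueError(f"candidates outside 10..70: {bad}")
    x = signed_occlusion(df) / 10.0  # slopes per 10% of movement duration
    y = df["chose_small_first"].to_numpy().astype(int)
    obs = df["observer_id"].to_numpy()
    groups_present = sorted(df["group"].unique())
    if include_group is None:
        include_group = len(groups_present) > 1
    gvec = None
    if include_group:
        if len(groups_present) < 2:
            raise ValueError("group terms requested but only one group present")
        gvec = (df["group"].to_numpy() == "patient").astype(float)

    cand_rows, fits = [], {}
    for c in candidates:
        X, names = _design(x, c / 10.0, gvec)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_mixed_logit(X, y, obs, names=names, method=method)
            if not np.isfinite(res.loglik):
                raise RuntimeError("non-finite log-likelihood")
        except Exception as err:  # noqa: BLE001 - candidate dropped, not fatal
            warnings.warn(f"candidate change point {c} dropped: {err}",
                          stacklevel=2)
            continue
        fits[c] = res
        cand_rows.append((c, res.aic, res.loglik, res.converged))
    if not fits:
        raise RuntimeError("no candidate change point converged")
    candidate_table = pd.DataFrame(
        cand_rows, columns=["change_point", "aic", "loglik", "converged"]
    )
    best = candidate_table.loc[candidate_table["aic"].idxmin(), "change_point"]
    res = fits[best]

    X1, names1 = _design(x, None, gvec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single = fit_mixed_logit(X1, y, obs, names=names1, method=method)
    lrt = likelihood_ratio_test(res.loglik, single.loglik,
                                df=res.n_params - single.n_params)

    slope_terms = [n for n in res.params.index if n.startswith("slope")]
    slopes = pd.DataFrame({
        "term": slope_terms,
        "estimate": res.params[slope_terms].to_numpy(),
        "se": res.bse[slope_terms].to_numpy(),
        "z": res.zvalues[slope_terms].to_numpy(),
        "p": res.pvalues[slope_terms].to_numpy(),
    })
    gterms = None
    if include_group:
        gnames = [n for n in res.params.index if n.startswith("group")]
        gterms = pd.DataFrame({
            "term": gnames,
            "estimate": res.params[gnames].to_numpy(),
            "se": res.bse[gnames].to_numpy(),
            "z": res.zvalues[gnames].to_numpy(),
            "p": res.pvalues[gnames].to_numpy(),
        })
    return PsychometricFit(
        change_point=float(best), slopes=slopes, group_terms=gterms,
        random_effect_sd=res.random_effect_sd, loglik=res.loglik,
        aic=res.aic, candidate_table=candidate_table,
        lrt_vs_single_slope=lrt, method=res.method, result=res,
    )


# ---------------------------------------------------------------------------
# group x occlusion interaction on accuracy


def group_interaction_test(sessions: pd.DataFrame,
                           method: str = "quadrature") -> pd.DataFrame:
    """Binomial mixed model of P(correct) on group x occlusion (linear).

    Occlusion enters as a centred linear trend in tens of percent
    ((occ - 45) / 10); group is coded patient = 1, so a patient integration
    deficit appears as a negative ``group_x_occlusion`` term.
    """
    if sessions["group"].nunique() < 2:
        raise ValueError("both observer groups must be present")
    occ = (sessions["occlusion_level"].to_numpy(dtype=float) - 45.0) / 10.0
    g = (sessions["group"].to_numpy() == "patient").astype(float)
    y = sessions["correct"].to_numpy().astype(int)
    X = np.column_stack([np.ones_like(occ), occ, g, g * occ])
    names = ["intercept", "occlusion", "group", "group_x_occlusion"]
    res = fit_mixed_logit(X, y, sessions["observer_id"].to_numpy(),
                          names=names, method=method)
    return pd.DataFrame({
        "term": names,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "z": res.zvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })


# ---------------------------------------------------------------------------
# confidence-accuracy calibration


def confidence_accuracy_ratio(sessions: pd.DataFrame,
                              change_point: float = 20.0) -> dict:
    """Confidence/accuracy calibration by integration period.

    Confidence is normalized to [0,1] as (c-1)/3.  The early period covers
    occlusions <= change_point, the late period the rest.  The ratio
    normalized-confidence / accuracy is computed per observer x period
    (undefined and excluded when accuracy is 0) and compared across groups
    and periods by a linear mixed model with a participant random intercept.
    """
    df = sessions.dropna(subset=["confidence"]).copy()
    if len(df) == 0:
        raise ValueError("confidence missing on all trials")
    df["conf_norm"] = (df["confidence"].astype(float) - 1.0) / 3.0
    df["period"] = np.where(df["occlusion_level"] <= change_point,
                            "early", "late")
    per = (df.groupby(["group", "observer_id", "period"])
           .agg(mean_accuracy=("correct", "mean"),
                mean_confidence_norm=("conf_norm", "mean"),
                n_trials=("correct", "size"))
           .reset_index())
    per["ratio"] = np.where(per["mean_accuracy"] > 0,
                            per["mean_confidence_norm"] / per["mean_accuracy"],
                            np.nan)
    n_undefined = int(per["ratio"].isna().sum())
    valid = per.dropna(subset=["ratio"]).copy()

    interaction = None
    if valid["group"].nunique() > 1 and valid["period"].nunique() > 1:
        valid["is_patient"] = (valid["group"] == "patient").astype(float)
        valid["is_late"] = (valid["period"] == "late").astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("ratio ~ is_patient * is_late", valid,
                             groups=valid["observer_id"])
            fit = md.fit(reml=False)
        interaction = {
            "estimate": float(fit.params["is_patient:is_late"]),
            "se": float(fit.bse["is_patient:is_late"]),
            "p_value": float(fit.pvalues["is_patient:is_late"]),
        }
    return {
        "table": per,
        "period_bounds": {"early": (min(df["occlusion_level"].min(), 10),
                                    change_point),
                          "late": (change_point, df["occlusion_level"].max())},
        "n_undefined": n_undefined,
        "group_period_interaction": interaction,
    }
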