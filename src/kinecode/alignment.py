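"""Alignment of per-observer readout weights with encoding weights.

For every observer, occlusion level, feature and epoch the readout weight
fraction is |beta_read| normalized to sum to 1 over the feature x epoch
support of that level; its alignment sign is the sign of
beta_read * beta_enc, or "null" when either weight falls below a magnitude
floor (a stated fraction of the level's total absolute weight).  Features
are ordered by the encoding weight at the highest fitted occlusion level,
descending, for stacked-profile reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .coding import EncodingFit, ReadoutFit

#: Default magnitude floor: 1% of the level's total absolute weight.
DEFAULT_MAGNITUDE_FLOOR = 0.01


def feature_order(enc_fits: list[EncodingFit]) -> list[str]:
    """Features sorted by encoding weight at the highest level, descending."""
    top = max(enc_fits, key=lambda f: f.occlusion_level)
    key = np.abs(top.coef_matrix()).sum(axis=1)
    return [top.feature_names[i] for i in np.argsort(-key, kind="stable")]


def alignment_profile(read_fits: list[ReadoutFit],
                      enc_fits: list[EncodingFit],
                      magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR) -> dict:
    """Per-observer and group-averaged readout-weight alignment profiles.

    Returns per-cell rows (observer, level, feature, epoch, fraction, sign)
    plus group-mean fractions; observers with an all-zero readout vector at
    a level are excluded there (their count is reported).
    """
    enc_by_level = {f.occlusion_level: f for f in enc_fits}
    rows = []
    n_excluded = 0
    for rf in read_fits:
        if rf.occlusion_level not in enc_by_level:
            raise ValueError(
                f"no encoding fit at occlusion {rf.occlusion_level}"
            )
        enc = enc_by_level[rf.occlusion_level]
        br = rf.coef_matrix()
        be = enc.coef_matrix()
        tot_r = np.abs(br).sum()
        tot_e = np.abs(be).sum()
        if tot_r == 0:
            n_excluded += 1
            continue
        floor_r = magnitude_floor * tot_r
        floor_e = magnitude_floor * tot_e
        for fi, feat in enumerate(rf.feature_names):
            for e in range(br.shape[1]):
                wr, we = br[fi, e], be[fi, e]
                if abs(wr) < floor_r or abs(we) < floor_e:
                    sign = "null"
                else:
                    sign = "positive" if wr * we > 0 else "negative"
                rows.append((rf.observer_id, rf.occlusion_level, feat, e + 1,
                             abs(wr) / tot_r, sign))
    per_cell = pd.DataFrame(
        rows, columns=["observer_id", "occlusion_level", "feature", "epoch",
                       "fraction", "alignment"]
    )
    group_mean = (per_cell
                  .groupby(["occlusion_level", "feature", "epoch"])["fraction"]
                  .mean().reset_index())
    per_feature = (per_cell
                   .groupby(["observer_id", "occlusion_level", "feature"])
                   ["fraction"].sum().reset_index())
    return {
        "per_cell": per_cell,
        "group_mean": group_mean,
        "per_feature": per_feature,
        "feature_order": feature_order(enc_fits),
        "n_excluded": n_excluded,
    }


def readout_strength(read_fits: list[ReadoutFit]) -> pd.Series:
    """Per-observer readout strength: mean CV accuracy minus chance level
    across fitted occlusion levels (chance taken as 0.5 where no permutation
    null was attached)."""
    rows: dict[str, list[float]] = {}
    for rf in read_fits:
        chance = rf.chance_level if rf.chance_level is not None else 0.5
        rows.setdefault(rf.observer_id, []).append(rf.cv_accuracy - chance)
    return pd.Series({k: float(np.mean(v)) for k, v in rows.items()},
                     name="readout_strength")


def covariate_correlations(metrics: pd.DataFrame,
                           covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman correlations of observer metrics vs covariates.

    ``metrics`` and ``covariates`` are observer-indexed tables; observers
    missing a covariate are dropped pairwise.  A constant covariate yields
    NaN correlations flagged ``undefined``.
    """
    joined = metrics.join(covariates, how="inner")
    if len(joined) < 4:
        raise ValueError("need >= 4 observers with non-missing covariates")
    rows = []
    for m in metrics.columns:
        for c in covariates.columns:
            sub = joined[[m, c]].dropna()
            x, y = sub[m].to_numpy(float), sub[c].to_numpy(float)
            if len(sub) < 4 or np.std(x) == 0 or np.std(y) == 0:
                rows.append((m, c, len(sub), np.nan, np.nan, np.nan, np.nan,
                             True))
                continue
            pr, pp = stats.pearsonr(x, y)
            sr, sp = stats.spearmanr(x, y)
            rows.append((m, c, len(sub), pr, pp, sr, sp, False))
    return pd.DataFrame(
        rows, columns=["metric", "covariate", "n", "pearson_r", "pearson_p",
                       "spearman_r", "spearman_p", "undefined"]
    )
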