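"""Psychometric-analysis tests: curves, change-point fit, calibration."""

import numpy as np
import pandas as pd
import pytest

from kinecode import (
    DesignSpec,
    ObserverProfile,
    make_design,
    make_stimulus_set,
    sessions_frame,
    simulate_observer,
)
from kinecode.psychometrics import (
    accuracy_by_occlusion,
    confidence_accuracy_ratio,
    empirical_curve,
    fit_piecewise_psychometric,
    group_interaction_test,
    piecewise_basis,
    signed_occlusion,
)


def _swap_small_large(df: pd.DataFrame) -> pd.DataFrame:
    """Relabel small<->large everywhere (configurations, choices, pairs)."""
    out = df.copy()
    out["configuration"] = np.where(df["configuration"] == "small_first",
                                    "large_first", "small_first")
    out["chose_small_first"] = ~df["chose_small_first"].astype(bool)
    out[["first_stimulus_id", "second_stimulus_id"]] = \
        df[["first_stimulus_id", "second_stimulus_id"]]
    return out


class TestEmpiricalCurve:
    def test_all_sixteen_signed_levels_present(self, cohort_frame):
        curve = empirical_curve(cohort_frame)
        for g in ("control", "patient"):
            sub = curve[curve.group == g]
            assert len(sub) == 16
            assert sub["p_small_first"].between(0, 1).all()

    def test_small_large_relabel_symmetry(self, cohort_frame):
        """P'(+o) after a global small<->large relabel equals 1 - P(-o)."""
        a = empirical_curve(cohort_frame).set_index(
            ["group", "signed_occlusion"])
        b = empirical_curve(_swap_small_large(cohort_frame)).set_index(
            ["group", "signed_occlusion"])
        for (g, lev), row in a.iterrows():
            assert b.loc[(g, -lev), "p_small_first"] == pytest.approx(
                1.0 - row["p_small_first"], abs=1e-12)

    def test_noiseless_perfect_observer_curve(self):
        from kinecode.generator import GeneratorParams, observer_preset
        params = GeneratorParams(trait_sd=0.0, noise_sd=0.0)
        clean = make_stimulus_set(params, seed=0)
        design = make_design(DesignSpec(seed=3), clean)
        p = observer_preset("control", clean, noise_sd=0.0, lapse=0.0)
        sess = simulate_observer(p, design, clean, seed=0)
        # a single observer still needs the frame schema
        curve = empirical_curve(sess.to_frame())
        for _, row in curve.iterrows():
            want = 1.0 if row["signed_occlusion"] > 0 else 0.0
            assert row["p_small_first"] == want

    def test_patient_chance_at_early_signed_levels(self, cohort_frame):
        curve = empirical_curve(cohort_frame)
        sub = curve[(curve.group == "patient")
                    & (np.abs(curve.signed_occlusion) <= 20)]
        n_per_cell = 15 * 16  # trials per signed level x participants
        se = 0.5 / np.sqrt(n_per_cell)
        for _, row in sub.iterrows():
            assert abs(row["p_small_first"] - 0.5) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            empirical_curve(pd.DataFrame())


class TestAccuracy:
    def test_participant_mean_not_pooled(self):
        # two observers with unbalanced trial counts: the participant mean
        # differs from the trial-pooled accuracy
        df = pd.DataFrame({
            "observer_id": ["a"] * 4 + ["b"] * 1,
            "group": "control",
            "occlusion_level": 10,
            "correct": [True, True, True, True, False],
            "first_stimulus_id": "s", "second_stimulus_id": "l",
        })
        out = accuracy_by_occlusion(df)
        assert out["accuracy"].iloc[0] == pytest.approx(0.5)  # (1.0 + 0.0)/2

    def test_all_correct_is_one(self, cohort_frame):
        df = cohort_frame.copy()
        df["correct"] = True
        out = accuracy_by_occlusion(df)
        assert (out["accuracy"] == 1.0).all()

    def test_by_stimulus_pair_resolution(self, cohort_frame):
        out = accuracy_by_occlusion(cohort_frame, by_stimulus=True)
        assert {"pair", "accuracy", "n_trials"} <= set(out.columns)
        assert out["accuracy"].between(0, 1).all()


class TestPiecewiseFit:
    def test_basis_continuity_and_odd_symmetry(self):
        x = np.linspace(-80, 80, 321)
        B = piecewise_basis(x, 20.0)
        # odd symmetry
        assert np.allclose(B, -B[::-1])
        # continuity at the knot
        i = np.searchsorted(x, 20.0)
        assert abs(B[i, 1] - B[i - 1, 1]) < 1.0

    def test_trial_and_participant_order_invariance(self, small_cohort_frame):
        fit1 = fit_piecewise_psychometric(small_cohort_frame,
                                          candidates=(20.0, 40.0))
        shuffled = small_cohort_frame.sample(frac=1.0, random_state=1)
        fit2 = fit_piecewise_psychometric(shuffled, candidates=(20.0, 40.0))
        assert fit1.change_point == fit2.change_point
        assert np.isclose(fit1.aic, fit2.aic, atol=1e-5)

    def test_zero_slope_responders(self, stim):
        # observers with all-zero weights respond at random
        profile = ObserverProfile(group="control",
                                  weights=np.zeros((12, 10)), noise_sd=1.0)
        sessions = []
        for i in range(6):
            d = make_design(DesignSpec(seed=400 + i), stim)
            s = simulate_observer(profile, d, stim, seed=300 + i,
                                  observer_id=f"r{i}")
            sessions.append(s.to_frame())
        df = pd.concat(sessions, ignore_index=True)
        fit = fit_piecewise_psychometric(df, candidates=(20.0,),
                                         include_group=False)
        for _, row in fit.slopes.iterrows():
            assert abs(row["estimate"]) < 2 * row["se"]

    def test_candidates_validated(self, small_cohort_frame):
        with pytest.raises(ValueError):
            fit_piecewise_psychometric(small_cohort_frame, candidates=(5.0,))

    def test_single_participant_rejected(self, cohort_frame):
        one = cohort_frame[cohort_frame.observer_id == "c01"]
        with pytest.raises(ValueError):
            fit_piecewise_psychometric(one)

    def test_single_slope_data_rarely_rejects(self):
        """Type-I control: on data generated with one psychometric slope
        and no plateau, the two-segment LRT at the AIC-selected knot stays
        non-significant in >= 90% of replicate cohorts."""
        rng = np.random.default_rng(0)
        n_sig = 0
        N = 40
        for _ in range(N):
            rows = []
            for p in range(16):
                occ = np.tile(np.repeat(np.arange(10, 90, 10), 15), 2)
                sgn = np.r_[np.ones(120), -np.ones(120)]
                eta = 0.35 * sgn * occ / 10
                y = rng.random(240) < 1 / (1 + np.exp(-eta))
                rows.append(pd.DataFrame({
                    "observer_id": f"p{p}", "group": "control",
                    "occlusion_level": occ,
                    "configuration": np.where(sgn > 0, "small_first",
                                              "large_first"),
                    "chose_small_first": y}))
            fit = fit_piecewise_psychometric(
                pd.concat(rows, ignore_index=True),
                candidates=(10, 20, 30, 40, 50), method="fixed",
                include_group=False)
            n_sig += fit.lrt_vs_single_slope["p_value"] < 0.05
        assert n_sig / N <= 0.10

    def test_fallback_method_agrees_on_change_point(self, small_cohort_frame):
        quad = fit_piecewise_psychometric(small_cohort_frame,
                                          candidates=(20.0, 40.0))
        fixed = fit_piecewise_psychometric(small_cohort_frame,
                                           candidates=(20.0, 40.0),
                                           method="fixed")
        assert quad.change_point == fixed.change_point
        q = quad.slopes.set_index("term")["estimate"]
        f = fixed.slopes.set_index("term")["estimate"]
        assert (np.sign(q) == np.sign(f)).all()


class TestGroupInteraction:
    def test_patient_deficit_is_negative_interaction(self, cohort_frame):
        tab = group_interaction_test(cohort_frame).set_index("term")
        assert tab.loc["occlusion", "estimate"] > 0
        assert tab.loc["group", "p"] < 0.05  # overall patient deficit

    def test_single_group_rejected(self, cohort_frame):
        with pytest.raises(ValueError, match="both observer groups"):
            group_interaction_test(
                cohort_frame[cohort_frame.group == "control"])


class TestCalibration:
    def test_all_confident_all_correct_ratio_one(self):
        df = pd.DataFrame({
            "observer_id": np.repeat(["a", "b"], 8),
            "group": "control",
            "occlusion_level": list(range(10, 90, 10)) * 2,
            "correct": True,
            "confidence": 4,
        })
        out = confidence_accuracy_ratio(df, change_point=20.0)
        assert np.allclose(out["table"]["ratio"], 1.0)

    def test_patient_overconfidence_early(self, cohort_frame):
        out = confidence_accuracy_ratio(cohort_frame, change_point=20.0)
        t = out["table"].groupby(["group", "period"])[
            ["ratio", "mean_accuracy"]].mean()
        # patients: higher confidence/accuracy ratio early despite lower
        # accuracy, mirroring decoupled confidence in the null window
        assert (t.loc[("patient", "early"), "ratio"]
                > t.loc[("control", "early"), "ratio"])
        assert (t.loc[("patient", "early"), "mean_accuracy"]
                < t.loc[("control", "early"), "mean_accuracy"])
        assert out["group_period_interaction"]["p_value"] < 0.05

    def test_control_ratio_increases_with_period(self, cohort_frame):
        out = confidence_accuracy_ratio(cohort_frame, change_point=20.0)
        t = out["table"]
        ctrl = t[t.group == "control"].pivot(index="observer_id",
                                             columns="period", values="ratio")
        diff = ctrl["late"] - ctrl["early"]
        assert diff.mean() > 0
        # paired difference reliably positive across observers
        assert diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff))) > 2

    def test_zero_accuracy_cell_excluded(self):
        df = pd.DataFrame({
            "observer_id": ["a"] * 8,
            "group": "control",
            "occlusion_level": list(range(10, 90, 10)),
            "correct": [False, False] + [True] * 6,
            "confidence": 3,
        })
        out = confidence_accuracy_ratio(df, change_point=20.0)
        assert out["n_undefined"] == 1
        assert out["table"]["ratio"].isna().sum() == 1
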