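"""Encoding/readout model tests: predictors, fits, nulls, predictions."""

import numpy as np
import pandas as pd
import pytest

from kinecode import (
    DesignSpec,
    GeneratorParams,
    make_design,
    make_stimulus_set,
    observer_preset,
    simulate_observer,
)
from kinecode.coding import (
    EncodingFit,
    ReadoutFit,
    bias_fraction,
    build_delta_matrix,
    encoding_profile,
    fit_encoding,
    fit_readout,
    information_read,
    readout_chance_null,
    readout_predictions,
    trial_delta_features,
)


class TestDeltaFeatures:
    def test_identical_stimuli_give_zero(self, stim):
        sid = stim.stimuli[0].stimulus_id
        dk = trial_delta_features(sid, sid, stim, 40)
        assert np.all(dk == 0.0)

    @pytest.mark.parametrize("occ,dim", [(10, 12), (40, 48), (80, 96)])
    def test_dimension_follows_epoch_rule(self, stim, occ, dim):
        a, b = stim.stimuli[0].stimulus_id, stim.stimuli[31].stimulus_id
        assert trial_delta_features(a, b, stim, occ).shape == (dim,)

    def test_interval_swap_negates(self, stim):
        a, b = stim.stimuli[2].stimulus_id, stim.stimuli[40].stimulus_id
        d1 = trial_delta_features(a, b, stim, 60)
        d2 = trial_delta_features(b, a, stim, 60)
        assert np.array_equal(d1, -d2)

    def test_feature_major_ordering(self, stim):
        a, b = stim.stimuli[0].stimulus_id, stim.stimuli[31].stimulus_id
        dk = trial_delta_features(a, b, stim, 20)
        full = stim[a].features - stim[b].features
        assert np.array_equal(dk, full[:, :2].reshape(-1))

    def test_errors(self, stim):
        a = stim.stimuli[0].stimulus_id
        with pytest.raises(KeyError):
            trial_delta_features("missing", a, stim, 20)
        with pytest.raises(ValueError):
            trial_delta_features(a, a, stim, 15)


class TestEncoding:
    def test_fit_and_accuracy_range(self, design, stim):
        fit = fit_encoding(design, stim, 60, seed=0)
        assert 0.0 <= fit.cv_accuracy <= 1.0
        assert fit.beta.shape == (72,)
        assert fit.cv_accuracy > 0.8  # calibrated signal at 60%

    def test_no_signal_at_chance(self):
        # zero size effects: CV accuracy within 3 SE of 1/2 across sets
        accs = []
        for seed in range(12):
            s = make_stimulus_set(GeneratorParams(effect_scale=0.0),
                                  seed=seed)
            d = make_design(DesignSpec(seed=seed), s)
            accs.append(fit_encoding(d, s, 40, seed=seed).cv_accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se

    def test_too_few_trials_rejected(self, design, stim):
        few = design[design.occlusion_level == 60].head(12)
        with pytest.raises(ValueError, match=">= 20"):
            fit_encoding(few, stim, 60)

    def test_interval_swap_invariance(self, design, stim):
        """Swapping the two intervals of every trial leaves the encoding
        CV accuracy unchanged (the 2AFC antisymmetry)."""
        fit = fit_encoding(design, stim, 30, seed=5)
        swapped = design.copy()
        swapped[["first_stimulus_id", "second_stimulus_id"]] = \
            design[["second_stimulus_id", "first_stimulus_id"]].to_numpy()
        swapped["configuration"] = np.where(
            design["configuration"] == "small_first", "large_first",
            "small_first")
        fit2 = fit_encoding(swapped, stim, 30, seed=5)
        assert fit.cv_accuracy == fit2.cv_accuracy
        assert np.allclose(fit.beta, fit2.beta, atol=1e-6)
        assert np.isclose(fit.intercept, -fit2.intercept, atol=1e-6)


class TestEncodingProfile:
    def _fits(self, stim, design, levels=(10, 20, 30, 40, 50, 60, 70, 80)):
        return [fit_encoding(design, stim, o, seed=o) for o in levels]

    def test_contributions_simplex_and_stability(self, stim, design):
        fits = self._fits(stim, design, levels=(20, 40, 80))
        prof = encoding_profile(fits)
        sums = prof["contributions"].groupby("occlusion_level")[
            "contribution"].sum()
        assert np.allclose(sums, 1.0)
        stab = prof["stability"]
        assert np.allclose(np.diag(stab), 1.0)
        assert ((stab.to_numpy() <= 1.0 + 1e-12).all()
                and (stab.to_numpy() >= -1.0 - 1e-12).all())

    def test_identical_fits_perfectly_stable(self, stim, design):
        f = fit_encoding(design, stim, 40, seed=1)
        f2 = EncodingFit(occlusion_level=80,
                         feature_names=f.feature_names,
                         beta=np.tile(f.coef_matrix(), (1, 2)).reshape(-1),
                         intercept=f.intercept, penalty=f.penalty,
                         cv_accuracy=f.cv_accuracy, cv_sem=f.cv_sem,
                         fold_assignments=f.fold_assignments)
        prof = encoding_profile([f, f2])
        assert prof["stability"].loc[40, 80] == pytest.approx(1.0)

    def test_grip_aperture_dominates_early(self, stim):
        """GA is the top feature at early occlusions and its contribution
        peaks at 20-30% of movement duration (averaged over stimulus sets)."""
        contribs = []
        for seed in (0, 1, 2):
            s = make_stimulus_set(seed=seed)
            d = make_design(DesignSpec(seed=seed), s)
            prof = encoding_profile(self._fits(s, d))
            c = prof["contributions"].pivot(index="feature",
                                            columns="occlusion_level",
                                            values="contribution")
            contribs.append(c)
        mean_c = sum(contribs) / len(contribs)
        for occ in (10, 20, 30):
            assert mean_c[occ].idxmax() == "GA"
        ga = mean_c.loc["GA"]
        assert ga.idxmax() in (20, 30)

    def test_needs_two_levels(self, stim, design):
        with pytest.raises(ValueError):
            encoding_profile([fit_encoding(design, stim, 40, seed=0)])


class TestReadout:
    def test_near_noiseless_observer_recovered(self, stim, design):
        p = observer_preset("control", stim, noise_sd=1e-3, lapse=0.0)
        sess = simulate_observer(p, design, stim, seed=3)
        fit = fit_readout(sess.trials, stim, 60, seed=0)
        assert fit.cv_accuracy >= 0.9

    def test_degenerate_constant_responder(self, stim, design):
        t = design.copy()
        t["chose_small_first"] = True
        t["correct"] = t["configuration"] == "small_first"
        t["confidence"] = 2
        fit = fit_readout(t, stim, 40, seed=0)
        assert fit.degenerate
        assert np.all(fit.beta == 0.0)
        assert fit.cv_accuracy == 1.0  # base rate of the constant response

    def test_bias_fraction_limits(self, stim):
        p = len(stim.feature_names) * 2
        base = dict(observer_id="x", occlusion_level=20,
                    feature_names=stim.feature_names, penalty=1.0,
                    cv_accuracy=0.7, cv_sem=0.0,
                    heldout_proba=np.zeros(4), heldout_pred=np.zeros(4),
                    trial_ids=np.arange(4))
        X = np.ones((4, p))
        no_bias = ReadoutFit(beta=np.ones(p), intercept=0.0, **base)
        assert bias_fraction(no_bias, X) == 0.0
        pure_bias = ReadoutFit(beta=np.zeros(p), intercept=0.4, **base)
        assert bias_fraction(pure_bias, X) == 1.0
        degenerate = ReadoutFit(beta=np.zeros(p), intercept=0.0, **base)
        assert np.isnan(bias_fraction(degenerate, X))

    def test_predicted_confidence_bounded(self, stim, design,
                                          control_session):
        fit = fit_readout(control_session.trials, stim, 40, seed=0)
        assert (fit.predicted_confidence >= 0).all()
        assert (fit.predicted_confidence <= 0.5).all()


class TestChanceNull:
    def test_determinism_and_mean(self, stim, design, patient_session):
        a = readout_chance_null(patient_session.trials, stim, 20,
                                n_perm=100, seed=9)
        b = readout_chance_null(patient_session.trials, stim, 20,
                                n_perm=100, seed=9)
        assert np.array_equal(a["null_accuracies"], b["null_accuracies"])
        assert 0.35 < a["chance_level"] < 0.65

    def test_small_n_perm_rejected(self, stim, design, patient_session):
        with pytest.raises(ValueError, match="n_perm"):
            readout_chance_null(patient_session.trials, stim, 20,
                                n_perm=50, seed=0)


class TestPredictionsAndInformation:
    def test_predicted_vs_observed_accuracy_correlates(self, stim,
                                                       small_cohort_frame):
        fits = []
        for obs, sess in small_cohort_frame.groupby("observer_id"):
            for occ in (20, 60):
                fits.append(fit_readout(sess, stim, occ, observer_id=obs,
                                        seed=hash(obs) % 1000))
        out = readout_predictions(fits, small_cohort_frame)
        for g in ("control", "patient"):
            assert out["accuracy_corr"][g]["r"] > 0.5
            assert out["accuracy_corr"][g]["p"] < 0.05
        # model confidence tracks reported confidence in controls
        assert out["confidence_corr"]["control"]["r"] > 0.2

    def test_too_few_observers_flagged(self, stim, small_cohort_frame):
        one = small_cohort_frame[small_cohort_frame.observer_id == "c01"]
        fits = [fit_readout(one, stim, 60, observer_id="c01", seed=0)]
        out = readout_predictions(fits, one)
        assert np.isnan(out["accuracy_corr"]["control"]["r"])

    def test_information_read_bounds(self, stim, design, control_session,
                                     patient_session):
        enc = fit_encoding(design, stim, 60, seed=0)
        frac_c = information_read(enc, control_session.trials)
        assert 0.0 <= frac_c <= 1.0
        # patient with zero early weights extracts ~nothing at 10%
        enc10 = fit_encoding(design, stim, 10, seed=0)
        if enc10.cv_accuracy > 0.5:
            frac_p = information_read(enc10, patient_session.trials)
            assert frac_p < 0.5

    def test_information_undefined_below_chance_encoder(self, stim,
                                                        control_session):
        enc = EncodingFit(occlusion_level=10,
                          feature_names=stim.feature_names,
                          beta=np.zeros(12), intercept=0.0, penalty=1.0,
                          cv_accuracy=0.45, cv_sem=0.0,
                          fold_assignments=np.zeros(30, dtype=int))
        assert np.isnan(information_read(enc, control_session.trials))
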