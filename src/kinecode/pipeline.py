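"""End-to-end orchestration: simulate -> psychometrics -> encoding ->
readout -> alignment -> summary report.

A :class:`RunConfig` fully determines all outputs.  Per-stage seeds are
derived from the master seed with :class:`numpy.random.SeedSequence` using
fixed stage indices as spawn keys (stimuli=0, design=1, observers=2, cv=3,
permutations=4), so adding a stage never perturbs earlier stages' streams.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import alignment as align_mod
from . import coding, psychometrics
from .generator import (
    DEFAULT_OBSERVER_NOISE_SD,
    GeneratorParams,
    make_stimulus_set,
    simulate_cohort,
)
from .io import (
    dump_json,
    encoding_fit_record,
    readout_fit_record,
    write_sessions,
    write_stimuli,
)
from .types import DesignSpec, OCCLUSION_LEVELS, sessions_frame

log = logging.getLogger("kinecode")

_STAGE_KEYS = {"stimuli": 0, "design": 1, "observers": 2, "cv": 3,
               "permutations": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage seed: SeedSequence(master, spawn_key=(stage index,)), < 2^31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Single-file configuration of a full pipeline run."""

    master_seed: int = 0
    n_control: int = 16
    n_patient: int = 16
    n_trials: int = 240
    n_blocks: int = 8
    occlusion_levels: tuple[int, ...] = OCCLUSION_LEVELS
    candidate_change_points: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    observer_noise_sd: float = DEFAULT_OBSERVER_NOISE_SD
    observer_lapse: float = 0.02
    effect_scale: float = 1.0
    cv_folds: int = 10
    inner_folds: int = 5
    n_perm: int = 200
    #: occlusion levels at which permutation chance levels are computed
    #: (None = every level; the nulls dominate runtime)
    null_levels: tuple[int, ...] | None = None
    mixed_method: str = "quadrature"
    out_dir: str = "kinecode_run"

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.n_control + self.n_patient < 1:
            raise ValueError("at least one observer required")
        if self.cv_folds < 2 or self.inner_folds < 2:
            raise ValueError("cv_folds and inner_folds must be >= 2")
        DesignSpec(n_trials=self.n_trials, n_blocks=self.n_blocks,
                   occlusion_levels=tuple(self.occlusion_levels))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for f in ("occlusion_levels", "candidate_change_points", "null_levels"):
            val = getattr(cfg, f)
            if val is not None:
                setattr(cfg, f, tuple(val))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["occlusion_levels"] = list(self.occlusion_levels)
        d["candidate_change_points"] = list(self.candidate_change_points)
        if self.null_levels is not None:
            d["null_levels"] = list(self.null_levels)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis; returns the in-memory report.

    Stages: stimulus generation, cohort simulation, psychometric analysis
    (curves, piecewise change point, group interaction, confidence
    calibration), encoding fits per occlusion level, per-observer readout
    fits with permutation chance levels and bias fractions, readout
    predictions, and weight-alignment profiles.  Identical configs give
    byte-identical summary JSON.
    """
    config.validate()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("stage: %s", name)

    try:
        _stage("stimuli")
        params = GeneratorParams(effect_scale=config.effect_scale)
        stimuli = make_stimulus_set(params,
                                    seed=stage_seed(config.master_seed,
                                                    "stimuli"))
    except Exception:
        log.error("stage 'stimuli' failed (config=%s)", config)
        raise

    try:
        _stage("simulate")
        spec = DesignSpec(n_trials=config.n_trials, n_blocks=config.n_blocks,
                          occlusion_levels=tuple(config.occlusion_levels),
                          seed=stage_seed(config.master_seed, "design"))
        cohort = simulate_cohort(stimuli, spec, config.n_control,
                                 config.n_patient,
                                 seed=stage_seed(config.master_seed,
                                                 "observers"),
                                 noise_sd=config.observer_noise_sd,
                                 lapse=config.observer_lapse)
        sessions = sessions_frame(cohort)
    except Exception:
        log.error("stage 'simulate' failed")
        raise

    try:
        _stage("psychometrics")
        curve = psychometrics.empirical_curve(sessions)
        acc = psychometrics.accuracy_by_occlusion(sessions)
        psy = psychometrics.fit_piecewise_psychometric(
            sessions, candidates=tuple(config.candidate_change_points),
            method=config.mixed_method)
        interaction = (psychometrics.group_interaction_test(
            sessions, method=config.mixed_method)
            if sessions["group"].nunique() > 1 else None)
        calib = psychometrics.confidence_accuracy_ratio(
            sessions, change_point=psy.change_point)
    except Exception:
        log.error("stage 'psychometrics' failed")
        raise

    cv_seed = stage_seed(config.master_seed, "cv")
    perm_seed = stage_seed(config.master_seed, "permutations")
    try:
        _stage("encoding")
        design = cohort[0].trials  # shared design structure: use first
        enc_fits = [
            coding.fit_encoding(design, stimuli, o, seed=cv_seed + oi,
                                outer_k=config.cv_folds,
                                inner_k=config.inner_folds)
            for oi, o in enumerate(config.occlusion_levels)
        ]
        enc_profile = coding.encoding_profile(enc_fits)
    except Exception:
        log.error("stage 'encoding' failed")
        raise

    try:
        _stage("readout")
        read_fits = []
        for si, sess in enumerate(cohort):
            for oi, o in enumerate(config.occlusion_levels):
                rf = coding.fit_readout(sess.trials, stimuli, o,
                                        observer_id=sess.observer_id,
                                        seed=cv_seed + 1000 + si * 100 + oi,
                                        outer_k=config.cv_folds,
                                        inner_k=config.inner_folds)
                want_null = (config.null_levels is None
                             or o in config.null_levels)
                if not rf.degenerate and want_null:
                    coding.attach_chance_level(
                        rf, sess.trials, stimuli, n_perm=config.n_perm,
                        seed=perm_seed + si * 100 + oi,
                        outer_k=config.cv_folds, inner_k=config.inner_folds)
                read_fits.append(rf)
        bias_tests = {
            g: coding.group_bias_test(
                [f for f, s in zip(read_fits, _expand(cohort, config)) if s == g],
                seed=perm_seed)
            for g in sessions["group"].unique()
        }
        preds = coding.readout_predictions(read_fits, sessions)
    except Exception:
        log.error("stage 'readout' failed")
        raise

    try:
        _stage("alignment")
        alignment = align_mod.alignment_profile(read_fits, enc_fits)
    except Exception:
        log.error("stage 'alignment' failed")
        raise

    _stage("report")
    summary = {
        "config": {**asdict(config),
                   "occlusion_levels": list(config.occlusion_levels),
                   "candidate_change_points":
                       list(config.candidate_change_points)},
        "change_point": psy.change_point,
        "change_point_lrt": psy.lrt_vs_single_slope,
        "slopes": psy.slopes.to_dict("records"),
        "group_interaction": (interaction.to_dict("records")
                              if interaction is not None else None),
        "calibration_interaction": calib["group_period_interaction"],
        "encoding": [encoding_fit_record(f) | {"beta": None} | {
            "n_coef": len(f.beta)} for f in enc_fits],
        "readout": [readout_fit_record(f) | {"beta": None} for f in read_fits],
        "bias_tests": bias_tests,
        "prediction_correlations": {
            "accuracy": preds["accuracy_corr"],
            "confidence": preds["confidence_corr"],
        },
        "alignment_feature_order": alignment["feature_order"],
        "n_alignment_excluded": alignment["n_excluded"],
    }

    report = {
        "summary": summary, "sessions": sessions, "stimuli": stimuli,
        "curve": curve, "accuracy": acc, "psychometric_fit": psy,
        "calibration": calib, "encoding_fits": enc_fits,
        "encoding_profile": enc_profile, "readout_fits": read_fits,
        "predictions": preds, "alignment": alignment,
    }
    if write:
        write_stimuli(stimuli, out / "stimuli.csv")
        write_sessions(sessions, out / "sessions.csv")
        curve.to_csv(out / "psychometric_curve.csv", index=False)
        acc.to_csv(out / "accuracy.csv", index=False)
        calib["table"].to_csv(out / "calibration.csv", index=False)
        enc_profile["contributions"].to_csv(
            out / "encoding_contributions.csv", index=False)
        alignment["per_cell"].to_csv(out / "alignment.csv", index=False)
        dump_json([encoding_fit_record(f) for f in enc_fits],
                  out / "encoding_fits.json")
        dump_json([readout_fit_record(f) for f in read_fits],
                  out / "readout_fits.json")
        dump_json(summary, out / "summary.json")
        config.to_yaml(out / "config.yaml")
    return report


def _expand(cohort, config) -> list[str]:
    """Group label per (observer x occlusion level) readout fit."""
    return [s.group for s in cohort for _ in config.occlusion_levels]
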