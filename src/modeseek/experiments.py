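"""Benchmark studies on fully synthetic data.

Each function runs one self-contained study against the package's own
generator — parameter recovery, model selection with the permutation
control, classification-image recovery, contrast calibration, and type-I
error calibration of the statistics — and returns a flat dictionary of
summary numbers. They are what `scripts/acceptance.py` and the heavier end
of the test suite execute; problem sizes are chosen so each study finishes
in minutes on one CPU (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import glmhmm, stats, stimpower, synth
from .exceptions import InsufficientDataError

__all__ = [
    "recovery_study",
    "model_selection_study",
    "template_study",
    "calibration_study",
    "type1_study",
    "alarm_rate_study",
]

TRUE_WEIGHTS = np.array([[4.0, 0.2], [1.0, 2.0]])
TRUE_SELF_TRANSITION = 0.98


def _two_state_dataset(
    n_observers: int, n_trials: int, seed: int,
    design: synth.ExperimentDesign | None = None,
) -> pd.DataFrame:
    """Trial tables for a cohort of default two-state observers."""
    design = design or synth.ExperimentDesign()
    observer = synth.GenerativeObserver()
    tabs = []
    for p in range(n_observers):
        seq = synth.generate_trial_sequence(design, seed=seed + 17 * p, n_trials=n_trials)
        tabs.append(
            synth.simulate_observer(seq, observer, seed=seed + 17 * p + 1, participant=p)
        )
    return pd.concat(tabs, ignore_index=True)


def recovery_study(
    seed: int, n_observers: int = 20, n_trials: int = 2000
) -> dict[str, float]:
    """Parameter recovery of the two-state GLM-HMM on its own generator.

    Simulates ``n_observers`` default observers (external beta = (4, 0.2),
    internal beta = (1, 2), self-transitions 0.98), fits the GLM-HMM and the
    one-state control per observer, and summarizes weight and transition
    errors, mode-decoding accuracy against the hidden modes, and delta-BIC.
    """
    trials = _two_state_dataset(n_observers, n_trials, seed)
    fits = glmhmm.fit_per_participant(trials)
    weight_errors, self_errors, accuracies, dbics = [], [], [], []
    occupancies, run_lengths = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, (fit, one) in fits.items():
            sub = trials[trials["participant"] == pid]
            weight_errors.extend(np.abs(fit.weights - TRUE_WEIGHTS).ravel())
            self_errors.extend(np.abs(np.diag(fit.A) - TRUE_SELF_TRANSITION))
            labels = glmhmm.label_modes(fit)
            accuracies.append(
                float(np.mean(labels.labels == sub["mode_true"].to_numpy()))
            )
            dbics.append(glmhmm.delta_bic(fit, one))
            occupancies.append(labels.occupancy_internal)
            run_lengths.append(labels.mean_run_length_trials)
    dbics = np.asarray(dbics)
    return {
        "median_abs_weight_error": float(np.median(weight_errors)),
        "median_self_transition_error": float(np.median(self_errors)),
        "median_decoding_accuracy": float(np.median(accuracies)),
        "mean_decoding_accuracy": float(np.mean(accuracies)),
        "delta_bic_sum": float(dbics.sum()),
        "frac_delta_bic_negative": float(np.mean(dbics < 0)),
        "mean_occupancy_internal_pct": float(100.0 * np.mean(occupancies)),
        "mean_run_length_trials": float(np.mean(run_lengths)),
        "mean_run_length_seconds": float(
            np.mean(run_lengths) * glmhmm.DEFAULT_TRIAL_DURATION_S
        ),
        "n_observers": n_observers,
        "n_trials_per_observer": n_trials,
    }


def model_selection_study(
    seed: int,
    n_observers: int = 20,
    n_trials: int = 2000,
    n_perm: int = 20,
) -> dict[str, float]:
    """delta-BIC on two-state data and its loss under trial-order permutation."""
    trials = _two_state_dataset(n_observers, n_trials, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glmhmm.permutation_control(trials, n_perm=n_perm, seed=seed + 1)
        fits = glmhmm.fit_per_participant(trials)
    dbics = np.array([glmhmm.delta_bic(f, o) for f, o in fits.values()])
    return {
        "frac_delta_bic_negative": float(np.mean(dbics < 0)),
        "observed_delta_bic_sum": float(res["observed"]),
        "median_permuted_delta_bic_sum": float(np.median(res["permuted"])),
        "n_perm": n_perm,
        "n_observers": n_observers,
    }


def template_study(
    seed: int,
    n_noise_trials: int = 10_000,
    n_observers: int = 20,
    n_trials: int = 16_000,
    shift_pixels: int = 64,
) -> dict[str, float]:
    """Classification-image recovery from a template-coupled observer.

    Part 1: a template observer (positive coupling to close-to-vertical noise
    power) over noise-only trials at the full 128-pixel grid; the
    classification image should peak at vertical (its average-vector angle
    is the peak-location estimate; the raw arg-max bin is also reported and
    should fall inside the coupling band). Part 2: with the inducer-following
    template enabled, the average-vector displacement toward the preceding
    inducer should be positive during the internal mode and near zero during
    the external mode (assessed against the ground-truth mode labels). The
    shift cohort uses a 64-pixel grid and a size chosen for ~95% power at the
    mechanism's ~4-degree displacement (see docs/methods.md).
    """
    design = synth.ExperimentDesign()
    observer = synth.GenerativeObserver(template_gain=2.0, bias=-2.0)

    profiles = stimpower.simulate_noise_profiles(design, n_noise_trials, seed=seed)
    seq = pd.DataFrame(
        {
            "session": np.zeros(n_noise_trials, dtype=int),
            "trial": np.arange(n_noise_trials),
            "stim_class": "noise",
            "contrast": 0.0,
            "orientation_deg": np.nan,
        }
    )
    tab = synth.simulate_observer(
        seq, observer, seed=seed + 1, profiles=profiles,
        bin_centers=stimpower.bin_centers(),
    )
    ci = stimpower.classification_image(
        profiles, tab["response"].to_numpy(dtype=bool)
    )
    peak_deg = float(stimpower.bin_centers()[int(np.argmax(ci.delta_power))])
    vector_deg = stimpower.average_vector(ci).angle

    follower = dataclasses.replace(observer, inducer_following_template=True)
    shift_design = dataclasses.replace(design, n_pixels=shift_pixels)
    tabs, profs = [], []
    for p in range(n_observers):
        seq_p = synth.generate_trial_sequence(
            shift_design, seed=seed + 31 * p + 2, n_trials=n_trials
        )
        pr = stimpower.simulate_noise_profiles(
            shift_design, n_trials, seed=seed + 31 * p + 3
        )
        tabs.append(
            synth.simulate_observer(
                seq_p, follower, seed=seed + 31 * p + 4, profiles=pr,
                bin_centers=stimpower.bin_centers(), participant=p,
            )
        )
        profs.append(pr)
    trials = pd.concat(tabs, ignore_index=True)
    angles = stats.classification_vector_angles(
        trials, np.concatenate(profs), mode_column="mode_true"
    )
    internal = stats.vector_shift_test(angles, "internal")
    external = stats.vector_shift_test(angles, "external")
    return {
        "ci_peak_deg": peak_deg,
        "ci_vector_angle_deg": float(vector_deg),
        "shift_internal_deg": float(internal.coefficient),
        "shift_internal_p": float(internal.p),
        "shift_external_deg": float(external.coefficient),
        "shift_external_p": float(external.p),
        "n_noise_trials": n_noise_trials,
        "n_shift_trials": n_observers * n_trials,
    }


def calibration_study(seed: int, target_dprime: float = 1.5) -> dict[str, float]:
    """Contrast calibration of the standard calibration observer."""
    design = synth.ExperimentDesign()
    observer = synth.calibration_observer()
    contrast = synth.calibrate_contrast(
        observer, design, target_dprime=target_dprime, seed=seed
    )
    achieved = synth.simulated_dprime(
        observer, design, contrast, seed=seed + 1000, n_trials=8000
    )
    return {
        "calibrated_contrast": float(contrast),
        "achieved_dprime": float(achieved),
        "target_dprime": target_dprime,
    }


def alarm_rate_study(
    seed: int,
    n_participants: int = 8,
    n_trials: int = 2000,
    n_pixels: int = 64,
) -> dict[str, float]:
    """Alarm-rate predictors on a template-coupled serial-dependence cohort.

    Simulates default two-state observers with a positive template coupling
    (so false alarms track the noise's close-to-vertical power) and a
    conservative response criterion, then fits the mixed alarm-rate model.
    All three predictors — current contrast, preceding contrast, relative
    vertical noise power — should come out positive, plus the mode-conditional
    serial-dependence contrast and the FA-rate-by-mode contrast computed
    against the ground-truth mode labels.
    """
    design = dataclasses.replace(synth.ExperimentDesign(), n_pixels=n_pixels)
    observer = synth.GenerativeObserver(template_gain=2.0, bias=-2.0)
    tabs, profs = [], []
    for p in range(n_participants):
        seq = synth.generate_trial_sequence(design, seed=seed + 11 * p, n_trials=n_trials)
        pr = stimpower.simulate_noise_profiles(design, n_trials, seed=seed + 11 * p + 5)
        tabs.append(
            synth.simulate_observer(
                seq, observer, seed=seed + 11 * p + 7, profiles=pr,
                bin_centers=stimpower.bin_centers(), participant=p,
            )
        )
        profs.append(pr)
    trials = pd.concat(tabs, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = {r.term: r for r in stats.alarm_rate_model(trials)}
        by_mode = trials.rename(columns={"mode_true": "mode"})
        sd = stats.mode_conditional_serial_dependence(by_mode)
        fa = stats.fa_rate_by_mode(by_mode)
    return {
        "coef_contrast": model["contrast"].coefficient,
        "z_contrast": model["contrast"].statistic,
        "coef_prev_contrast": model["prev_contrast"].coefficient,
        "z_prev_contrast": model["prev_contrast"].statistic,
        "coef_relpower": model["relpower"].coefficient,
        "z_relpower": model["relpower"].statistic,
        "serial_dependence_internal": sd["internal"].coefficient,
        "serial_dependence_external": sd["external"].coefficient,
        "fa_rate_internal_minus_external": fa.coefficient,
        "fa_rate_t": fa.statistic,
        "n_trials_total": n_participants * n_trials,
    }


def type1_study(
    seed: int,
    n_datasets: int = 500,
    n_participants: int = 6,
    n_trials: int = 600,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Empirical type-I error of every test on null data.

    Null datasets come from :func:`modeseek.synth.simulate_null_observer`:
    responses depend on the current contrast only, mode labels follow an
    independent Markov chain, and noise profiles are decoupled from the
    responses. Noise images use a reduced 32-pixel grid (the profile
    statistics are grid-independent; see docs/methods.md). Reported rates are
    the fraction of datasets on which each test's p-value falls below
    ``alpha``.
    """
    design = dataclasses.replace(synth.ExperimentDesign(), n_pixels=32)
    tests = [
        "alarm_prev_contrast", "alarm_relpower",
        "serial_dependence_internal", "serial_dependence_external",
        "fa_rate_by_mode", "shift_internal", "shift_external",
    ]
    rejections = {t: 0 for t in tests}
    counts = {t: 0 for t in tests}
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_datasets):
            tabs, profs = [], []
            for p in range(n_participants):
                s = int(rng.integers(2**31 - 10))
                seq = synth.generate_trial_sequence(design, seed=s, n_trials=n_trials)
                pr = stimpower.simulate_noise_profiles(design, n_trials, seed=s + 1)
                tabs.append(
                    synth.simulate_null_observer(seq, seed=s + 2, profiles=pr, participant=p)
                )
                profs.append(pr)
            trials = pd.concat(tabs, ignore_index=True)
            trials = trials.rename(columns={"mode_true": "mode"})
            profiles = np.concatenate(profs)

            pvals: dict[str, float] = {}
            model = {r.term: r for r in stats.alarm_rate_model(trials)}
            pvals["alarm_prev_contrast"] = model["prev_contrast"].p
            pvals["alarm_relpower"] = model["relpower"].p
            try:
                sd = stats.mode_conditional_serial_dependence(trials)
                pvals["serial_dependence_internal"] = sd["internal"].p
                pvals["serial_dependence_external"] = sd["external"].p
            except InsufficientDataError:
                pass
            try:
                pvals["fa_rate_by_mode"] = stats.fa_rate_by_mode(trials).p
            except InsufficientDataError:
                pass
            angles = stats.classification_vector_angles(trials, profiles)
            for mode in ("internal", "external"):
                try:
                    pvals[f"shift_{mode}"] = stats.vector_shift_test(angles, mode).p
                except InsufficientDataError:
                    pass
            for t, p in pvals.items():
                counts[t] += 1
                rejections[t] += p < alpha
    out: dict[str, float] = {"n_datasets": n_datasets, "nominal_alpha": alpha}
    for t in tests:
        out[f"type1_{t}"] = rejections[t] / counts[t] if counts[t] else float("nan")
        out[f"n_valid_{t}"] = counts[t]
    return out
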