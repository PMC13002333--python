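"""Tests of the regression and test statistics."""

import numpy as np
import pandas as pd
import pytest

import modeseek as mk
from modeseek import stats
from modeseek.exceptions import InsufficientDataError, SchemaError

from conftest import make_trials


def null_cohort(n_participants=4, n_trials=800, seed=60, with_profiles=False):
    import dataclasses

    design = dataclasses.replace(mk.ExperimentDesign(), n_pixels=32)
    tabs, profs = [], []
    for p in range(n_participants):
        seq = mk.generate_trial_sequence(design, seed=seed + p, n_trials=n_trials)
        pr = (
            mk.simulate_noise_profiles(design, n_trials, seed=seed + 100 + p)
            if with_profiles
            else None
        )
        tabs.append(
            mk.simulate_null_observer(seq, seed=seed + 200 + p, profiles=pr, participant=p)
        )
        if with_profiles:
            profs.append(pr)
    trials = pd.concat(tabs, ignore_index=True)
    profiles = np.concatenate(profs) if with_profiles else None
    return trials, profiles


class TestAlarmRateModel:
    def test_missing_covariate_raises_schema_error(self):
        trials = make_trials([0, 1, 0, 1])
        with pytest.raises(SchemaError, match="relpower"):
            stats.alarm_rate_model(trials)

    def test_null_predictors_are_null(self):
        trials, _ = null_cohort(with_profiles=True)
        results = {r.term: r for r in stats.alarm_rate_model(trials)}
        assert abs(results["prev_contrast"].statistic) < 3.5
        assert abs(results["relpower"].statistic) < 3.5
        assert results["contrast"].statistic > 5  # the real effect stays

    def test_wald_statistic_consistency(self):
        trials, _ = null_cohort(with_profiles=True)
        for r in stats.alarm_rate_model(trials):
            assert abs(r.statistic) == pytest.approx(
                abs(r.coefficient) / r.se, rel=1e-6
            )

    def test_standardization_changes_scale_not_sign(self):
        trials, _ = null_cohort(with_profiles=True)
        raw = {r.term: r for r in stats.alarm_rate_model(trials, method="fixed")}
        std = {r.term: r for r in stats.alarm_rate_model(
            trials, method="fixed", standardize=True)}
        for term in raw:
            assert np.sign(raw[term].statistic) == np.sign(std[term].statistic)
        assert raw["contrast"].coefficient != pytest.approx(std["contrast"].coefficient)

    def test_add_prev_contrast_lags_within_session(self):
        trials = make_trials(
            [0, 1, 0, 1], sessions=[0, 0, 1, 1], contrasts=[0.5, 0.0, 0.3, 0.2]
        )
        out = stats.add_prev_contrast(trials)
        np.testing.assert_allclose(out["prev_contrast"], [0.0, 0.5, 0.0, 0.3])


class TestModeConditionalSerialDependence:
    def test_mode_partition_is_exhaustive(self):
        trials, _ = null_cohort()
        trials = trials.rename(columns={"mode_true": "mode"})
        n_int = (trials["mode"] == "internal").sum()
        n_ext = (trials["mode"] == "external").sum()
        assert n_int + n_ext == len(trials)
        res = stats.mode_conditional_serial_dependence(trials)
        assert set(res) == {"external", "internal"}

    def test_randomized_labels_equal_coefficients(self):
        trials, _ = null_cohort(n_trials=1500)
        rng = np.random.default_rng(61)
        trials["mode"] = rng.choice(["external", "internal"], size=len(trials))
        res = stats.mode_conditional_serial_dependence(trials)
        gap = abs(res["internal"].coefficient - res["external"].coefficient)
        pooled_se = np.hypot(res["internal"].se, res["external"].se)
        assert gap < 3 * pooled_se

    def test_history_driven_observer_shows_internal_dependence(self, design):
        obs = mk.GenerativeObserver()
        seq = mk.generate_trial_sequence(design, seed=62, n_trials=6000)
        tab = mk.simulate_observer(seq, obs, seed=63)
        tab = tab.rename(columns={"mode_true": "mode"})
        res = stats.mode_conditional_serial_dependence(tab)
        assert res["internal"].coefficient > res["external"].coefficient
        assert res["internal"].coefficient > 0


class TestFaRateByMode:
    def test_toy_table_difference_and_bounds(self):
        rows = []
        for part in range(3):
            rates = {"external": 0.2 - 0.05 * part, "internal": 0.5 + 0.05 * part}
            for sess in range(2):
                for mode, rate in rates.items():
                    for i in range(20):
                        rows.append(
                            {"participant": part, "session": sess, "trial": i,
                             "stim_class": "noise", "contrast": 0.0,
                             "response": int(i < round(rate * 20)), "mode": mode}
                        )
        trials = pd.DataFrame(rows)
        res = stats.fa_rate_by_mode(trials)
        # per-participant differences 0.3, 0.4, 0.5 -> mean 0.4 over 6 blocks
        assert res.coefficient == pytest.approx(0.4)
        assert -1.0 <= res.coefficient <= 1.0
        assert res.df == 5  # 6 blocks
        assert res.p < 0.01

    def test_identical_rates_give_zero_difference(self):
        rows = []
        for part in range(3):
            for i in range(20):
                rows.append(
                    {"participant": part, "session": 0, "trial": i,
                     "stim_class": "noise", "contrast": 0.0,
                     "response": i % 2,
                     "mode": "internal" if i % 4 >= 2 else "external"}
                )
        res = stats.fa_rate_by_mode(pd.DataFrame(rows))
        assert res.coefficient == pytest.approx(0.0)
        assert res.statistic == 0.0

    def test_internal_dominant_observer_positive_difference(self, design):
        obs = mk.GenerativeObserver()
        seq = mk.generate_trial_sequence(design, seed=64, n_trials=8000)
        tab = mk.simulate_observer(seq, obs, seed=65)
        tab = tab.rename(columns={"mode_true": "mode"})
        res = stats.fa_rate_by_mode(tab)
        assert res.coefficient > 0

    def test_no_noise_trials_raises(self):
        trials = make_trials([0, 1], contrasts=[0.5, 0.5])
        trials["mode"] = "external"
        with pytest.raises(InsufficientDataError):
            stats.fa_rate_by_mode(trials)


class TestVectorShift:
    def _angles(self, cw, ccw, mode="internal"):
        return pd.DataFrame(
            {"participant": range(len(cw)), "mode": mode,
             "angle_cw": cw, "angle_ccw": ccw}
        )

    def test_all_vertical_gives_zero_with_warning(self):
        angles = self._angles([90.0] * 4, [90.0] * 4)
        with pytest.warns(UserWarning, match="variance"):
            res = stats.vector_shift_test(angles, "internal")
        assert res.coefficient == 0.0 and res.statistic == 0.0

    def test_mirror_displacement_equals_half_gap(self):
        angles = self._angles([100.0, 101.0, 99.0], [80.0, 81.0, 79.0])
        res = stats.vector_shift_test(angles, "internal")
        assert res.coefficient == pytest.approx(10.0)
        assert res.statistic > 0

    def test_too_few_participants_raises(self):
        angles = self._angles([100.0, 95.0], [85.0, 88.0])
        with pytest.raises(InsufficientDataError):
            stats.vector_shift_test(angles, "internal")

    def test_welch_df_is_fractional_capable(self):
        angles = self._angles([100.0, 104.0, 91.0, 97.0], [86.0, 83.0, 89.0, 80.0])
        res = stats.vector_shift_test(angles, "internal")
        assert 2.0 < res.df < 7.0


class TestVerticalDisplacement:
    def test_all_vertical_is_zero(self):
        mean, sem = stats.vertical_displacement([90.0, 90.0, 90.0])
        assert mean == 0.0 and sem == 0.0

    def test_symmetric_pair_averages_displacement(self):
        mean, sem = stats.vertical_displacement([80.0, 100.0])
        assert mean == pytest.approx(10.0)
        assert sem == pytest.approx(0.0)

    def test_sem_matches_direct_formula(self):
        angles = np.array([85.0, 95.0, 102.0, 78.0])
        disp = np.abs(angles - 90.0)
        mean, sem = stats.vertical_displacement(angles)
        assert mean == pytest.approx(disp.mean())
        assert sem == pytest.approx(disp.std(ddof=1) / 2.0)


class TestClassificationVectorAngles:
    def test_shift_appears_only_for_inducer_following_template(self, small_design):
        rng_seed = 70
        follower = mk.GenerativeObserver(
            template_gain=2.0, bias=-2.0, inducer_following_template=True
        )
        plain = mk.GenerativeObserver(template_gain=2.0, bias=-2.0)
        shifts = {}
        for name, obs in (("follower", follower), ("plain", plain)):
            tabs, profs = [], []
            for p in range(6):
                seq = mk.generate_trial_sequence(
                    small_design, seed=rng_seed + p, n_trials=3000
                )
                pr = mk.simulate_noise_profiles(small_design, 3000, seed=rng_seed + 50 + p)
                tabs.append(
                    mk.simulate_observer(
                        seq, obs, seed=rng_seed + 90 + p, profiles=pr,
                        bin_centers=mk.bin_centers(), participant=p,
                    )
                )
                profs.append(pr)
            trials = pd.concat(tabs, ignore_index=True)
            angles = stats.classification_vector_angles(
                trials, np.concatenate(profs), mode_column="mode_true"
            )
            shifts[name] = stats.vector_shift_test(angles, "internal").coefficient
        assert shifts["follower"] > shifts["plain"]
        assert shifts["follower"] > 0
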