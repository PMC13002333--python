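"""Regression and test statistics for the mode-segmentation analysis.

Four analyses are covered:

* a mixed logistic regression of the alarm on the current signal contrast,
  the preceding signal contrast, and the relative close-to-vertical power of
  the current noise image (the "template" covariate);
* mode-conditional serial dependence: the preceding-contrast effect fit
  separately on internal- and external-labeled trials;
* the paired contrast of false-alarm rates between modes, blocked by
  participant x session;
* Welch tests on the classification-image average-vector angles after
  clockwise versus counter-clockwise inducers (the template-shift test), plus
  the descriptive displacement of the vectors from vertical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, SchemaError, UndefinedValueError
from .stimpower import average_vector, classification_image, conditional_shift

__all__ = [
    "RegressionResult",
    "add_prev_contrast",
    "alarm_rate_model",
    "mode_conditional_serial_dependence",
    "fa_rate_by_mode",
    "classification_vector_angles",
    "vector_shift_test",
    "vertical_displacement",
]


@dataclass
class RegressionResult:
    """One estimated effect with its Wald-type uncertainty."""

    term: str
    coefficient: float
    se: float
    statistic: float  # z or t
    df: float  # NaN for z-type results, Welch-fractional allowed
    p: float
    model: str

    def as_dict(self) -> dict[str, float | str]:
        return {
            "term": self.term,
            "estimate": self.coefficient,
            "se": self.se,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "model": self.model,
        }


def _wald(term: str, coef: float, se: float, model: str) -> RegressionResult:
    z = coef / se if se > 0 else np.nan
    p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return RegressionResult(term, float(coef), float(se), float(z), np.nan, float(p), model)


def add_prev_contrast(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the preceding trial's signal contrast (0 at session starts)."""
    out = trials.copy()
    keys = [k for k in ("participant", "session") if k in out.columns]
    prev = out.groupby(keys, sort=False)["contrast"].shift(1) if keys else out["contrast"].shift(1)
    out["prev_contrast"] = prev.fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# Alarm-rate predictors
# ---------------------------------------------------------------------------

def _mixed_logit(y: np.ndarray, X: np.ndarray, names: list[str],
                 groups: np.ndarray, model_name: str) -> list[RegressionResult]:
    """Logistic regression with participant random intercepts (variational Bayes)."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    codes, _ = pd.factorize(groups)
    n_groups = codes.max() + 1
    exog_vc = np.zeros((len(y), n_groups))
    exog_vc[np.arange(len(y)), codes] = 1.0
    ident = np.zeros(n_groups, dtype=int)
    # Laplace (MAP) posterior: its standard deviations are well calibrated for
    # Wald tests here, where the variational approximation's are not. The
    # optimizer's start values are drawn from numpy's global RNG, so pin it
    # (and restore the caller's state) to keep fits bit-reproducible.
    state = np.random.get_state()
    try:
        np.random.seed(0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM(y, X, exog_vc, ident)
            fit = model.fit_map()
    finally:
        np.random.set_state(state)
    return [
        _wald(name, fit.fe_mean[i], fit.fe_sd[i], model_name)
        for i, name in enumerate(names)
    ]


def _plain_logit(y: np.ndarray, X: np.ndarray, names: list[str],
                 model_name: str) -> list[RegressionResult]:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return [
        _wald(name, fit.params[i], fit.bse[i], model_name)
        for i, name in enumerate(names)
    ]


def alarm_rate_model(
    trials: pd.DataFrame, method: str = "mixed", standardize: bool = False
) -> list[RegressionResult]:
    """Alarm probability as a function of contrast, history and noise content.

    Fits ``alarm ~ contrast + prev_contrast + relpower`` with a fixed
    intercept and participant random intercepts (``method="mixed"``, the
    default whenever several participants are present) or a pooled logistic
    regression (``method="fixed"``). ``standardize`` rescales each predictor
    to unit variance (coefficient scale changes, z statistics do not change
    sign). Returns one :class:`RegressionResult` per substantive predictor
    (the intercept is estimated but not reported).
    """
    for col in ("response", "contrast", "relpower"):
        if col not in trials.columns:
            raise SchemaError(f"trials table is missing required column {col!r}")
    if "prev_contrast" not in trials.columns:
        trials = add_prev_contrast(trials)
    y = trials["response"].to_numpy(dtype=float)
    predictors = [
        trials["contrast"].to_numpy(dtype=float),
        trials["prev_contrast"].to_numpy(dtype=float),
        trials["relpower"].to_numpy(dtype=float) - 1.0,  # centred at the flat-noise value
    ]
    if standardize:
        predictors = [p / s if (s := p.std()) > 0 else p for p in predictors]
    X = np.column_stack([np.ones(len(trials))] + predictors)
    names = ["intercept", "contrast", "prev_contrast", "relpower"]
    multi = "participant" in trials.columns and trials["participant"].nunique() > 1
    if method == "mixed" and multi:
        res = _mixed_logit(y, X, names, trials["participant"].to_numpy(),
                           "alarm ~ contrast + prev_contrast + relpower + (1|participant)")
    else:
        res = _plain_logit(y, X, names, "alarm ~ contrast + prev_contrast + relpower")
    return [r for r in res if r.term != "intercept"]


# ---------------------------------------------------------------------------
# Mode-conditional serial dependence
# ---------------------------------------------------------------------------

def mode_conditional_serial_dependence(
    trials: pd.DataFrame, mode_column: str = "mode"
) -> dict[str, RegressionResult]:
    """Preceding-contrast effect on the alarm, fit separately per mode.

    Fits ``alarm ~ contrast + prev_contrast`` (with intercept) on the
    internal-labeled and external-labeled trials and reports the
    ``prev_contrast`` coefficient for each mode.
    """
    if mode_column not in trials.columns:
        raise SchemaError(f"trials table is missing the mode column {mode_column!r}")
    if "prev_contrast" not in trials.columns:
        trials = add_prev_contrast(trials)
    out: dict[str, RegressionResult] = {}
    for mode in ("external", "internal"):
        sub = trials[trials[mode_column] == mode]
        if len(sub) < 50:
            warnings.warn(f"only {len(sub)} trials labeled {mode}; estimate unstable")
        if len(sub) < 10 or sub["response"].nunique() < 2:
            raise InsufficientDataError(f"too few usable trials in {mode} mode")
        y = sub["response"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(sub)), sub["contrast"].to_numpy(dtype=float),
             sub["prev_contrast"].to_numpy(dtype=float)]
        )
        res = _plain_logit(y, X, ["intercept", "contrast", "prev_contrast"],
                           f"alarm ~ contrast + prev_contrast | {mode}")
        out[mode] = next(r for r in res if r.term == "prev_contrast")
    return out


# ---------------------------------------------------------------------------
# FA rate by mode
# ---------------------------------------------------------------------------

def fa_rate_by_mode(
    trials: pd.DataFrame, mode_column: str = "mode", blocking: str = "session"
) -> RegressionResult:
    """Paired contrast of false-alarm rates, internal minus external.

    False-alarm rates are computed on noise-only trials within each
    participant x session block (``blocking="participant"`` aggregates per
    participant instead); blocks missing either mode are dropped with a
    warning. The paired differences are tested with a one-sample t statistic
    (df = number of blocks - 1).
    """
    noise = trials[trials["stim_class"] == "noise"]
    if noise.empty:
        raise InsufficientDataError("no noise-only trials available")
    keys = ["participant", "session"] if blocking == "session" else ["participant"]
    keys = [k for k in keys if k in noise.columns]
    rates = (
        noise.groupby(keys + [mode_column], observed=True)["response"]
        .mean()
        .unstack(mode_column)
    )
    complete = rates.dropna(subset=["external", "internal"]) if {
        "external", "internal"
    }.issubset(rates.columns) else rates.iloc[0:0]
    n_dropped = len(rates) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} block(s) missing one mode")
    if len(complete) < 2:
        raise InsufficientDataError("need at least 2 blocks with both modes")
    diffs = (complete["internal"] - complete["external"]).to_numpy()
    mean = float(diffs.mean())
    se = float(diffs.std(ddof=1) / np.sqrt(len(diffs)))
    df = float(len(diffs) - 1)
    if se == 0.0:
        warnings.warn("zero variance in FA-rate differences; t reported as 0")
        t, p = 0.0, 1.0
    else:
        t = mean / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RegressionResult(
        term="fa_rate_internal_minus_external",
        coefficient=mean, se=se, statistic=float(t), df=df, p=p,
        model=f"paired t over {len(diffs)} {'x'.join(keys)} blocks",
    )


# ---------------------------------------------------------------------------
# Classification-vector shift tests
# ---------------------------------------------------------------------------

def classification_vector_angles(
    trials: pd.DataFrame,
    profiles: np.ndarray,
    mode_column: str = "mode",
) -> pd.DataFrame:
    """Average-vector angles after CW and CCW inducers, per participant x mode.

    For each participant and mode, the classification image is computed over
    noise-only trials whose immediately preceding trial (same session) was an
    inducer, split by the inducer's tilt direction (CW: orientation > 90).
    Cells where either response class is absent yield NaN angles.

    Returns a tidy frame with columns ``participant, mode, angle_cw,
    angle_ccw``.
    """
    t = trials.reset_index(drop=True)
    profiles = np.asarray(profiles, dtype=float)
    if len(t) != len(profiles):
        raise SchemaError("profiles must align row-wise with the trial table")
    same_sess = t["session"].to_numpy()[1:] == t["session"].to_numpy()[:-1]
    same_part = (
        t["participant"].to_numpy()[1:] == t["participant"].to_numpy()[:-1]
        if "participant" in t.columns
        else np.ones(len(t) - 1, dtype=bool)
    )
    prev_ind = np.r_[False, (t["stim_class"].to_numpy()[:-1] == "inducer") & same_sess & same_part]
    prev_orient = np.r_[np.nan, t["orientation_deg"].to_numpy()[:-1]]
    base = prev_ind & (t["stim_class"].to_numpy() == "noise")

    rows = []
    participants = t["participant"].unique() if "participant" in t.columns else [0]
    for pid in participants:
        in_part = t["participant"].to_numpy() == pid if "participant" in t.columns else np.ones(len(t), bool)
        for mode in ("external", "internal"):
            in_mode = t[mode_column].to_numpy() == mode
            angles = {}
            for label, sel_dir in (("cw", prev_orient > 90.0), ("ccw", prev_orient < 90.0)):
                mask = base & in_part & in_mode & sel_dir
                try:
                    ci = classification_image(
                        profiles, t["response"].to_numpy(dtype=bool), mask,
                        condition=f"after_{label.upper()},{mode}",
                    )
                    angles[label] = average_vector(ci).angle
                except (InsufficientDataError, UndefinedValueError):
                    angles[label] = np.nan
            rows.append(
                {"participant": pid, "mode": mode,
                 "angle_cw": angles["cw"], "angle_ccw": angles["ccw"]}
            )
    return pd.DataFrame(rows)


def vector_shift_test(angles: pd.DataFrame, mode: str) -> RegressionResult:
    """Welch test of CW- vs CCW-conditioned average-vector angles in one mode.

    ``angles`` is the output of :func:`classification_vector_angles`. The
    reported coefficient is the mean per-participant displacement toward the
    preceding inducer (:func:`modeseek.stimpower.conditional_shift`); the test
    statistic is a Welch two-sample t comparing the participants'
    ``angle_cw`` and ``angle_ccw`` distributions, with Welch fractional df.
    """
    sub = angles[angles["mode"] == mode].dropna(subset=["angle_cw", "angle_ccw"])
    if len(sub) < 3:
        raise InsufficientDataError(
            f"need at least 3 participants with both conditions in {mode} mode"
        )
    cw = sub["angle_cw"].to_numpy(dtype=float)
    ccw = sub["angle_ccw"].to_numpy(dtype=float)
    disp = np.array([conditional_shift(a, b) for a, b in zip(cw, ccw)])
    mean_disp = float(disp.mean())
    se = float(disp.std(ddof=1) / np.sqrt(len(disp)))
    if np.allclose(cw, cw[0]) and np.allclose(ccw, ccw[0]):
        warnings.warn("no variance in either condition; t reported as 0")
        t, df, p = 0.0, float(2 * len(sub) - 2), 1.0
    else:
        welch = sps.ttest_ind(cw, ccw, equal_var=False)
        t = float(welch.statistic)
        df = float(welch.df)
        p = float(welch.pvalue)
    return RegressionResult(
        term=f"shift_toward_inducer_{mode}",
        coefficient=mean_disp, se=se, statistic=t, df=df, p=p,
        model=f"Welch t, angle_CW vs angle_CCW | {mode} (n={len(sub)})",
    )


def vertical_displacement(angles_deg: np.ndarray) -> tuple[float, float]:
    """Mean +- SEM of the absolute displacement of vector angles from 90 deg."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 2:
        raise InsufficientDataError("need at least 2 participants")
    disp = np.abs(a - 90.0)
    return float(disp.mean()), float(disp.std(ddof=1) / np.sqrt(len(disp)))
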