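"""Synthetic Gabor-in-noise detection experiments.

This module generates the three ingredients of a detection-in-noise study:

* trial sequences mixing low-contrast near-vertical Gabor signals, noise-only
  trials, and high-contrast oriented "inducer" gratings inserted at randomized
  intervals to boost serial dependence;
* stimulus images (Gabor carrier under a Gaussian contrast envelope, embedded
  in bounded white noise);
* simulated observers whose responses arise from a two-state Markov chain with
  logistic emissions — an *external* state dominated by the current stimulus
  and an *internal* state dominated by the previous response — optionally
  coupled to the orientation content of the noise through a predictive
  template.

All randomness is driven by explicit integer seeds; identical seeds reproduce
identical experiments bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import CalibrationError, ConfigurationError, ShapeError

__all__ = [
    "ExperimentDesign",
    "GenerativeObserver",
    "StimulusImage",
    "generate_trial_sequence",
    "render_gabor",
    "render_noise",
    "compose_stimulus",
    "simulate_observer",
    "calibrate_contrast",
]

#: Orientation of a vertical grating on the absolute scale used throughout.
VERTICAL_DEG = 90.0


@dataclass
class ExperimentDesign:
    """Parameters of the detection experiment.

    Orientations are in degrees on an absolute scale where vertical = 90 and
    values > 90 denote clockwise tilt. Contrasts are Michelson contrasts in
    [0, 1]; spatial quantities are in degrees of visual angle (d.v.a.).
    """

    p_low_contrast: float = 0.44
    p_noise_only: float = 0.44
    p_inducer: float = 0.12
    inducer_contrast: float = 0.40
    inducer_orientations: tuple[float, float] = (-10.0, 10.0)  # deg from vertical
    low_orientation_range: tuple[float, float] = (-3.0, 3.0)  # deg from vertical
    inducer_gap_range: tuple[int, int] = (4, 10)  # non-inducer trials between inducers
    trials_per_session: int = 100
    n_sessions: int = 20
    low_contrast: float = 0.72  # value calibrated to d' ~ 1.5 for the standard
    # calibration observer (see calibration_observer)
    noise_max_contrast: float = 0.60
    field_size: float = 14.0  # d.v.a. (square field)
    envelope_sd: float = 3.0  # d.v.a.
    spatial_freq: float = 0.5  # cycles / degree
    n_pixels: int = 128
    noise_distribution: str = "uniform"  # or "gaussian" (clipped at the bound)
    stim_duration: float = 0.5  # s
    iti_range: tuple[float, float] = (0.8, 1.2)  # s

    def __post_init__(self) -> None:
        props = (self.p_low_contrast, self.p_noise_only, self.p_inducer)
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"trial-type proportions must be nonnegative and sum to 1, got {props}"
            )
        lo, hi = self.inducer_gap_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(f"invalid inducer gap range {self.inducer_gap_range}")
        if self.n_pixels <= 0 or self.field_size <= 0:
            raise ConfigurationError("pixel grid and field size must be positive")
        if self.noise_distribution not in ("uniform", "gaussian"):
            raise ConfigurationError(
                f"noise_distribution must be 'uniform' or 'gaussian', got {self.noise_distribution!r}"
            )

    @property
    def pixels_per_degree(self) -> float:
        return self.n_pixels / self.field_size

    @property
    def trial_duration(self) -> float:
        """Nominal seconds per trial: stimulus + mask + mean inter-trial interval."""
        return 2 * self.stim_duration + 0.5 * (self.iti_range[0] + self.iti_range[1])


@dataclass
class GenerativeObserver:
    """Ground-truth two-state observer.

    ``weights_external`` and ``weights_internal`` are (beta_S, beta_H) pairs in
    log-odds units: the pull of the current signal contrast and of the previous
    response on the alarm probability. The external state must weight the
    stimulus more than history (beta_S > beta_H) and vice versa for the
    internal state. ``template_gain`` couples the alarm probability to the
    relative orientation power of the current noise in a 60-degree band around
    the observer's template orientation; 0 disables the coupling so responses
    follow the two-regressor logistic emissions exactly.

    With ``inducer_following_template`` set, the template band is re-centred on
    the orientation of a preceding high-contrast inducer for the following
    trial, but only while the observer is in the internal state — the
    mechanism that yields mode-specific classification-image shifts.
    """

    weights_external: tuple[float, float] = (4.0, 0.2)
    weights_internal: tuple[float, float] = (1.0, 2.0)
    transition_matrix_true: np.ndarray = field(
        default_factory=lambda: np.array([[0.98, 0.02], [0.02, 0.98]])
    )
    template_gain: float = 0.0  # log-odds per unit relative band power
    bias: float = 0.0  # response criterion (log-odds intercept); 0 matches the
    # bias-free emission model exactly
    lapse_rate: float = 0.0
    inducer_following_template: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.transition_matrix_true, dtype=float)
        if A.shape != (2, 2) or np.any(A < 0) or not np.allclose(A.sum(axis=1), 1.0):
            raise ConfigurationError("transition_matrix_true must be 2x2 row-stochastic")
        self.transition_matrix_true = A
        bs_e, bh_e = self.weights_external
        bs_i, bh_i = self.weights_internal
        if not bs_e > bh_e:
            raise ConfigurationError("external state requires beta_S > beta_H")
        if not bh_i > bs_i:
            raise ConfigurationError("internal state requires beta_H > beta_S")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ConfigurationError("lapse_rate must be in [0, 1)")


@dataclass
class StimulusImage:
    """A luminance-contrast image with its rendering metadata.

    ``pixels`` holds contrast values in [-1, 1]; ``gabor_orientation`` uses the
    absolute scale (vertical = 90 deg).
    """

    pixels: np.ndarray
    pixels_per_degree: float
    gabor_orientation: float = np.nan
    gabor_contrast: float = 0.0
    gabor_phase: float = 0.0
    rng_seed: int | None = None


# ---------------------------------------------------------------------------
# Trial sequences
# ---------------------------------------------------------------------------

def generate_trial_sequence(
    design: ExperimentDesign, seed: int, n_trials: int | None = None
) -> pd.DataFrame:
    """Draw an ordered trial sequence for one participant.

    Inducers are placed first: consecutive inducers are separated by a number
    of non-inducer trials drawn uniformly from ``design.inducer_gap_range``
    (an inducer every gap+1 trials, so the long-run inducer fraction is
    1/(mean gap + 1) = 1/8 = 0.125 at the defaults). Remaining trials are
    split between low-contrast signal and noise-only trials in proportion
    ``p_low_contrast : p_noise_only``. Low-contrast orientations are uniform
    within the near-vertical range; inducer orientations are drawn from the
    two fixed tilts.

    Returns a DataFrame with columns ``session, trial, stim_class, contrast,
    orientation_deg`` where ``stim_class`` is one of ``noise | low | inducer``.
    """
    if n_trials is None:
        n_trials = design.trials_per_session * design.n_sessions
    rng = np.random.default_rng(seed)

    is_inducer = np.zeros(n_trials, dtype=bool)
    if design.p_inducer > 0:
        lo, hi = design.inducer_gap_range
        pos = int(rng.integers(lo, hi + 1))
        while pos < n_trials:
            is_inducer[pos] = True
            pos += int(rng.integers(lo, hi + 1)) + 1

    stim_class = np.empty(n_trials, dtype=object)
    contrast = np.zeros(n_trials)
    orientation = np.full(n_trials, np.nan)

    stim_class[is_inducer] = "inducer"
    contrast[is_inducer] = design.inducer_contrast
    n_ind = int(is_inducer.sum())
    orientation[is_inducer] = VERTICAL_DEG + rng.choice(
        design.inducer_orientations, size=n_ind
    )

    rest = ~is_inducer
    n_rest = int(rest.sum())
    denom = design.p_low_contrast + design.p_noise_only
    p_low = design.p_low_contrast / denom if denom > 0 else 0.0
    is_low = rng.random(n_rest) < p_low
    stim_class[rest] = np.where(is_low, "low", "noise")
    contrast[rest] = np.where(is_low, design.low_contrast, 0.0)
    lo_o, hi_o = design.low_orientation_range
    low_orients = VERTICAL_DEG + rng.uniform(lo_o, hi_o, size=n_rest)
    orientation[rest] = np.where(is_low, low_orients, np.nan)

    session = np.arange(n_trials) // design.trials_per_session
    trial = np.arange(n_trials) % design.trials_per_session
    return pd.DataFrame(
        {
            "session": session,
            "trial": trial,
            "stim_class": stim_class,
            "contrast": contrast,
            "orientation_deg": orientation,
        }
    )


# ---------------------------------------------------------------------------
# Stimulus rendering
# ---------------------------------------------------------------------------

def _grid(design: ExperimentDesign) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in d.v.a., origin at the field centre."""
    n = design.n_pixels
    coords = (np.arange(n) - (n - 1) / 2) / design.pixels_per_degree
    return np.meshgrid(coords, coords)  # x varies along columns, y along rows


def gaussian_envelope(design: ExperimentDesign) -> np.ndarray:
    """Centered Gaussian contrast envelope (1 at the centre, sd = envelope_sd)."""
    if design.envelope_sd <= 0:
        raise ConfigurationError("envelope_sd must be positive")
    x, y = _grid(design)
    return np.exp(-(x**2 + y**2) / (2.0 * design.envelope_sd**2))


def render_gabor(
    orientation: float, contrast: float, phase: float, design: ExperimentDesign
) -> StimulusImage:
    """Render a Gabor patch: sinusoidal carrier under the Gaussian envelope.

    ``orientation`` is the grating orientation in degrees (90 = vertical
    stripes, >90 = clockwise tilt); ``contrast`` the Michelson contrast of the
    carrier; ``phase`` in radians.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ConfigurationError(f"contrast must be in [0, 1], got {contrast}")
    if design.pixels_per_degree <= 0:
        raise ConfigurationError("pixels_per_degree must be positive")
    x, y = _grid(design)
    a = np.deg2rad(orientation)
    # u advances perpendicular to the stripes: u = x for a vertical grating.
    u = x * np.sin(a) - y * np.cos(a)
    carrier = np.cos(2.0 * np.pi * design.spatial_freq * u + phase)
    pixels = contrast * carrier * gaussian_envelope(design)
    return StimulusImage(
        pixels=pixels,
        pixels_per_degree=design.pixels_per_degree,
        gabor_orientation=float(orientation),
        gabor_contrast=float(contrast),
        gabor_phase=float(phase),
    )


def render_noise(design: ExperimentDesign, seed: int | np.random.Generator) -> StimulusImage:
    """Render one static white-noise image bounded by ``noise_max_contrast``.

    The per-pixel distribution is uniform on [-bound, +bound] by default; the
    Gaussian alternative uses sd = bound/3, hard-clipped at the bound.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, b = design.n_pixels, design.noise_max_contrast
    if design.noise_distribution == "uniform":
        pixels = rng.uniform(-b, b, size=(n, n))
    else:
        pixels = np.clip(rng.normal(0.0, b / 3.0, size=(n, n)), -b, b)
    return StimulusImage(
        pixels=pixels,
        pixels_per_degree=design.pixels_per_degree,
        rng_seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def compose_stimulus(gabor: StimulusImage, noise: StimulusImage) -> StimulusImage:
    """Additive composition of signal and noise, clipped to the [-1, 1] range."""
    if gabor.pixels.shape != noise.pixels.shape:
        raise ShapeError(
            f"grid mismatch: {gabor.pixels.shape} vs {noise.pixels.shape}"
        )
    return StimulusImage(
        pixels=np.clip(gabor.pixels + noise.pixels, -1.0, 1.0),
        pixels_per_degree=gabor.pixels_per_degree,
        gabor_orientation=gabor.gabor_orientation,
        gabor_contrast=gabor.gabor_contrast,
        gabor_phase=gabor.gabor_phase,
        rng_seed=noise.rng_seed,
    )


# ---------------------------------------------------------------------------
# Simulated observers
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _band_relative_power(profile: np.ndarray, bin_centers: np.ndarray, center: float,
                         half_width: float = 30.0) -> float:
    """Mean power in the band [center-hw, center+hw] over the mean of all bins."""
    total = profile.mean()
    if total <= 0:
        return 1.0
    in_band = np.abs(bin_centers - center) <= half_width
    return float(profile[in_band].mean() / total)


def simulate_observer(
    stimuli: pd.DataFrame,
    observer: GenerativeObserver,
    seed: int,
    profiles: np.ndarray | None = None,
    bin_centers: np.ndarray | None = None,
    participant: int = 0,
    initial_state: int | None = None,
) -> pd.DataFrame:
    """Simulate trial-wise responses with hidden mode dynamics.

    ``stimuli`` is a trial sequence (``generate_trial_sequence`` output),
    optionally carrying a ``relpower`` column with the relative vertical noise
    power of each trial's noise image. Alternatively, ``profiles`` supplies
    the full per-trial orientation-power profiles (n_trials x n_bins, with
    ``bin_centers`` in degrees), which is required for the inducer-following
    template because the coupling band is then re-centred trial by trial.

    The hidden mode follows ``observer.transition_matrix_true`` (state 0 =
    external, state 1 = internal; the chain starts from its stationary
    distribution unless ``initial_state`` pins it). The response is Bernoulli with
    ``p = sigmoid(bias + contrast * beta_S + prev_response * beta_H + relpower * beta_N)``
    using the active state's weights, mixed with a 50/50 lapse at
    ``lapse_rate``. The previous response resets to 0 at session starts.

    Returns a trial table with columns ``participant, session, trial,
    stim_class, contrast, orientation_deg, response, prev_response, mode_true,
    relpower``.
    """
    A = observer.transition_matrix_true
    rng = np.random.default_rng(seed)
    n = len(stimuli)
    sessions = stimuli["session"].to_numpy()
    contrast = stimuli["contrast"].to_numpy(dtype=float)
    stim_class = stimuli["stim_class"].to_numpy()
    orientation = stimuli["orientation_deg"].to_numpy(dtype=float)

    if profiles is not None:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape[0] != n:
            raise ShapeError("profiles must have one row per trial")
        if bin_centers is None:
            bin_centers = np.arange(profiles.shape[1]) * (180.0 / profiles.shape[1])
        totals = profiles.mean(axis=1)
        in_band = np.abs(bin_centers - VERTICAL_DEG) <= 30.0
        relpower_vertical = np.where(
            totals > 0, profiles[:, in_band].mean(axis=1) / np.where(totals > 0, totals, 1.0), 1.0
        )
    elif "relpower" in stimuli.columns:
        relpower_vertical = stimuli["relpower"].to_numpy(dtype=float)
    else:
        relpower_vertical = np.ones(n)
    if observer.inducer_following_template and profiles is None:
        raise ConfigurationError(
            "inducer_following_template requires full per-trial profiles"
        )

    if initial_state is None:
        # stationary distribution of the mode chain for the initial state
        evals, evecs = np.linalg.eig(A.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat = np.abs(stat) / np.abs(stat).sum()
    else:
        stat = np.eye(2)[int(initial_state)]

    betas = np.array([observer.weights_external, observer.weights_internal])
    mode = np.empty(n, dtype=int)
    response = np.empty(n, dtype=int)
    prev_resp = np.empty(n, dtype=int)
    relpower_used = np.empty(n)

    z = int(rng.choice(2, p=stat))
    y_prev = 0
    for t in range(n):
        if t > 0:
            z = int(rng.choice(2, p=A[z]))
            if sessions[t] != sessions[t - 1]:
                y_prev = 0
        mode[t] = z
        prev_resp[t] = y_prev
        rp = relpower_vertical[t]
        if (
            observer.inducer_following_template
            and z == 1
            and t > 0
            and stim_class[t - 1] == "inducer"
        ):
            rp = _band_relative_power(profiles[t], bin_centers, orientation[t - 1])
        relpower_used[t] = rp
        drive = (observer.bias + contrast[t] * betas[z, 0]
                 + y_prev * betas[z, 1] + rp * observer.template_gain)
        p = _sigmoid(drive)
        if observer.lapse_rate > 0 and rng.random() < observer.lapse_rate:
            y = int(rng.random() < 0.5)
        else:
            y = int(rng.random() < p)
        response[t] = y
        y_prev = y

    out = stimuli.copy()
    out.insert(0, "participant", participant)
    out["response"] = response
    out["prev_response"] = prev_resp
    out["mode_true"] = np.where(mode == 0, "external", "internal")
    out["relpower"] = relpower_vertical
    return out


# ---------------------------------------------------------------------------
# Contrast calibration
# ---------------------------------------------------------------------------

def calibration_observer() -> GenerativeObserver:
    """The standard observer used to calibrate the low-signal contrast.

    Contrast calibration emulates preliminary sessions in which behavior is
    stimulus-driven, so this observer spends ~91% of trials in the external
    state and carries a conservative response criterion (bias = -3, i.e. a
    false-alarm rate near 5% when nothing pulls toward an alarm). A bias-free
    observer cannot reach d' = 1.5 at any legal contrast: without a response
    criterion the logistic emissions pin the false-alarm rate at or above
    50%, which caps the attainable sensitivity near d' = 1.35.
    """
    return GenerativeObserver(
        bias=-3.0,
        transition_matrix_true=np.array([[0.995, 0.005], [0.05, 0.95]]),
    )


def simulate_null_observer(
    stimuli: pd.DataFrame,
    seed: int,
    beta_S: float = 2.0,
    bias: float = -1.0,
    transition_matrix: np.ndarray | None = None,
    profiles: np.ndarray | None = None,
    participant: int = 0,
) -> pd.DataFrame:
    """Simulate a null observer: no serial dependence, no template coupling.

    Responses are Bernoulli(sigmoid(bias + contrast * beta_S)), independent
    across trials, so every history-, mode- and noise-content-related effect
    is null by construction. A ``mode_true`` column is still produced from an
    independent two-state Markov chain (default self-transitions 0.98) so the
    mode-conditional statistics can be exercised under their null. If
    ``profiles`` is given, the ``relpower`` column holds each trial's relative
    vertical noise power (which, being decoupled from the response, is also a
    null covariate); otherwise it is filled with 1.
    """
    rng = np.random.default_rng(seed)
    n = len(stimuli)
    A = (
        np.array([[0.98, 0.02], [0.02, 0.98]])
        if transition_matrix is None
        else np.asarray(transition_matrix, dtype=float)
    )
    mode = np.empty(n, dtype=int)
    z = int(rng.integers(2))
    for t in range(n):
        if t > 0:
            z = int(rng.choice(2, p=A[z]))
        mode[t] = z
    contrast = stimuli["contrast"].to_numpy(dtype=float)
    p = _sigmoid(bias + beta_S * contrast)
    response = (rng.random(n) < p).astype(int)
    if profiles is not None:
        profiles = np.asarray(profiles, dtype=float)
        centers = np.arange(profiles.shape[1]) * (180.0 / profiles.shape[1])
        in_band = np.abs(centers - VERTICAL_DEG) <= 30.0
        totals = profiles.mean(axis=1)
        relpower = profiles[:, in_band].mean(axis=1) / np.where(totals > 0, totals, 1.0)
    else:
        relpower = np.ones(n)
    out = stimuli.copy()
    out.insert(0, "participant", participant)
    out["response"] = response
    out["mode_true"] = np.where(mode == 0, "external", "internal")
    out["relpower"] = relpower
    out = out.sort_values(["participant", "session", "trial"]).reset_index(drop=True)
    from .glmhmm import rebuild_prev_response  # local import avoids a cycle

    return rebuild_prev_response(out)


def dprime(hit_rate: float, fa_rate: float, n_clip: int = 10_000) -> float:
    """Signal-detection sensitivity from hit and false-alarm rates.

    Rates are clipped away from 0 and 1 (half-count correction at ``n_clip``)
    before taking Gaussian quantiles.
    """
    eps = 1.0 / (2.0 * n_clip)
    h = min(max(hit_rate, eps), 1.0 - eps)
    f = min(max(fa_rate, eps), 1.0 - eps)
    return float(norm.ppf(h) - norm.ppf(f))


def simulated_dprime(
    observer: GenerativeObserver,
    design: ExperimentDesign,
    contrast: float,
    seed: int,
    n_trials: int = 6000,
) -> float:
    """d' of the simulated observer at a given low-signal contrast.

    Hits are alarms on low-contrast trials, false alarms are alarms on
    noise-only trials; both rates are pooled over the simulated sequence.
    """
    design_c = replace(design, low_contrast=float(contrast))
    seq = generate_trial_sequence(design_c, seed=seed, n_trials=n_trials)
    table = simulate_observer(seq, observer, seed=seed + 1)
    low = table["stim_class"] == "low"
    noise = table["stim_class"] == "noise"
    hit = table.loc[low, "response"].mean()
    fa = table.loc[noise, "response"].mean()
    return dprime(float(hit), float(fa), n_clip=int(low.sum()))


def calibrate_contrast(
    observer: GenerativeObserver,
    design: ExperimentDesign,
    target_dprime: float = 1.5,
    seed: int = 0,
    tol: float = 0.05,
    n_trials: int = 6000,
    max_iter: int = 40,
) -> float:
    """Find the low-signal contrast at which the observer's d' hits a target.

    Bisection over Michelson contrast in [0, 1] against the simulated d'
    (common random numbers across evaluations, so the simulated psychometric
    function is deterministic and monotone in contrast). Raises
    :class:`CalibrationError` when the target exceeds the d' attainable at
    full contrast.
    """
    if target_dprime < 0:
        raise ConfigurationError("target_dprime must be nonnegative")
    if target_dprime == 0:
        return 0.0
    lo, hi = 0.0, 1.0
    d_hi = simulated_dprime(observer, design, hi, seed, n_trials)
    if d_hi < target_dprime - 0.1:
        raise CalibrationError(
            f"target d'={target_dprime} unreachable: d' at full contrast is {d_hi:.3f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = simulated_dprime(observer, design, mid, seed, n_trials)
        if abs(d_mid - target_dprime) < tol:
            return mid
        if d_mid < target_dprime:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)
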