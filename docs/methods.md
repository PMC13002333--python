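# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `modeseek` pipeline. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic experiments (`modeseek.synth`)

The generator emulates a Gabor-in-noise detection study:

* **Trial mix.** 44% low-contrast near-vertical signals (orientation uniform
  within ±3° of vertical), 44% noise-only trials, 12% high-contrast
  "inducer" gratings (40% Michelson contrast, ±10° from vertical) inserted
  with 4–10 non-inducer trials between consecutive inducers. With gaps
  uniform on {4,…,10} an inducer occurs every 5–11 trials, so the long-run
  inducer fraction is 1/8 = 12.5%, consistent with the nominal 12% split.
  Sessions hold 100 trials; a default participant completes 20 sessions.
* **Stimuli.** A 14×14 d.v.a. field at 128×128 px by default
  (≈ 9.14 px/degree — 0.5 cpd is 7 cycles/image, far from Nyquist; the grid
  is configurable and profile statistics are grid-independent, which some
  studies exploit by dropping to 64 or 32 px). Gabors are cosine carriers at
  0.5 cpd under a Gaussian contrast envelope (sd 3 d.v.a.), with randomized
  phase. Noise is i.i.d. per pixel, uniform on ±0.6 by default (the bound is
  the 60% maximum noise contrast); a clipped-Gaussian alternative
  (sd = bound/3) sits behind `noise_distribution="gaussian"`. The nominal
  distribution is a design decision — only the bound is physically
  constrained — and the two options bracket plausible hardware. Composition
  is additive with clipping to ±1. The post-stimulus mask carries no
  analyzed signal and is not rendered.
* **Orientation convention.** Absolute scale with vertical = 90°; angles
  above 90° are clockwise. Inducers therefore sit at 80° (CCW) and 100° (CW).
* **Observers.** A hidden two-state Markov chain (default self-transitions
  0.98 in both states, i.e. geometric runs with mean 50 trials) selects
  between an external emission model (β_S, β_H) = (4, 0.2) and an internal
  one (1, 2), in log-odds per unit Michelson contrast and per previous
  response. Three optional extensions make the generator a superset of the
  fitted model, each defaulting to "off" so the default observer matches the
  bias-free two-regressor emissions exactly:
  * `bias` — a response criterion (intercept) in log-odds;
  * `template_gain` — additive coupling of the alarm log-odds to the
    relative vertical power of the current noise (mean power in the 60–120°
    band over the mean across all bins), which makes false alarms content-
    selective;
  * `inducer_following_template` — during the *internal* state only, the
    coupling band is re-centred on the orientation of an immediately
    preceding inducer (60° band around 80° or 100°), producing the
    mode-specific shift of classification images toward the inducer.
  A lapse parameter (uniform guessing) exists and defaults to 0.
* **Contrast calibration.** `calibrate_contrast` bisects the low-signal
  contrast until the simulated d′ (Gaussian quantile of the hit rate on
  low-contrast trials minus that of the FA rate on noise-only trials,
  half-count clipped) reaches a target, using common random numbers so the
  simulated psychometric function is monotone and deterministic. The
  standard calibration observer (`calibration_observer`) carries a
  conservative criterion (bias −3) and an external-dominant transition
  matrix (≈ 9% internal occupancy), emulating stimulus-driven preliminary
  calibration sessions. This is a substantive design point: a *bias-free*
  emission model pins the false-alarm rate at ≥ 50%, which caps attainable
  sensitivity near d′ ≈ 1.35, and the internal state (β_S = 1) contributes
  trials of near-zero sensitivity; without the criterion and the
  external-dominant chain no legal contrast reaches d′ = 1.5. The default
  design's low contrast (0.72) is the calibrated value for this observer.

## Orientation-power analysis (`modeseek.stimpower`)

Noise images are multiplied by the Gaussian stimulus envelope, 2-D
Fourier-transformed, and |F|² is sampled on the circle of radius
7 cycles/image (0.5 cpd × 14°) at 60 axial orientations (bin centres 0°,
3°, …, 177°; a bin's orientation is its centre, and band membership is by
centre). Antipodal spectral points are averaged, folding the spectrum to
[0°, 180°). The mapping from spectral angle to grating orientation absorbs
the 90° stripe/energy-axis rotation and is fixed by a calibration test: a
rendered vertical grating must peak in the 90° bin (a sweep over 0–150°
pins the whole convention).

Sampling uses bilinear interpolation of |F|² at the exact polar coordinates
(deterministic and resolution-robust); a one-pixel annulus-pooling variant
sits behind `method="annulus"`. Which variant original analyses of this
kind use is typically unstated; the two agree on peak locations.

`relative_band_power` is a ratio of means (band mean over total mean), so a
flat profile scores exactly 1; a ratio-of-sums variant is available
(`mode="sum"`). Classification images are bin-wise differences of
condition means (alarm minus rejection) and are exactly linear in the
per-trial profiles. The `average_vector` maps bins to polar endpoints
(radius = bin value, angle = bin centre) and takes the centroid; its angle
is folded to [0°, 180°). Negative bins have no defined polar radius, so
radii are shifted by the minimum bin value when any bin is negative
(default) or clipped at zero (`negative="clip"`); both are implemented
because the choice moves the angle slightly, and no axial angle-doubling is
applied before the centroid. Degenerate inputs (all-zero profiles, empty
response classes, zero total power) raise typed errors rather than
returning silent NaNs.

## GLM-HMM (`modeseek.glmhmm`)

* **Design.** Regressors are the current signal contrast (raw Michelson by
  default; an ordinal {0,1,2} "levels" coding is available — it rescales
  coefficients without changing the segmentation) and the previous response,
  lagged within session with y₀ = 0 at session starts. There is no
  intercept, matching the emission model exactly; the one-state control is
  the same regression without states.
* **Granularity.** One fit per participant; sessions are concatenated into a
  single HMM sequence (modes outlast single sessions) while the lagged
  response still resets at session boundaries. A pooled variant fits several
  participants as independent sequences sharing parameters.
* **E-step.** Scaled forward–backward (numba-compiled kernel), exact
  posteriors, per-trial emission log-likelihoods computed via
  `-log(1+exp(±x·w))` for numerical safety, with a per-trial row-max shift
  before exponentiation. Verified against exhaustive path enumeration on
  chains of length ≤ 10 to 1e-8.
* **M-steps.** Per state, a γ-weighted logistic regression penalized by
  ‖w‖²/(2σ²), solved by damped Newton iterations to gradient norm < 1e-8
  (backtracking guarantees ascent). Transitions are expected counts plus
  (α − 1), row-normalized; with α = 1 this is pure count normalization.
* **Initialization and identifiability.** Both states start at the
  one-state weights; a deterministic ±10% perturbation of β_H breaks the
  symmetric fixed point (±0.05 absolute when β_H starts at 0), and the
  initial state distribution is fixed uniform and not learned. After
  convergence states are relabeled so state 0 has the larger β_S − β_H
  (external). Multi-restart EM was considered and not made the default: on
  this model family the deterministic fit already attains log-likelihoods
  at or above those of the generating parameters, and determinism is worth
  more than the occasional tie-break.
* **Convergence.** Absolute change of the penalized log-posterior < 1e-4,
  max 200 iterations; the trace is monotone (asserted in tests) and
  non-convergence returns a flagged fit with a warning.
* **Model comparison.** BIC = k·ln(n) − 2·ln L with k = 2 (one state) or
  k = 6 (4 emission weights + 2 free transition entries; the fixed initial
  distribution is not counted), n = trials, and L the unpenalized likelihood
  at the MAP parameters. ΔBIC = BIC₂ − BIC₁, summed over participants when a
  cohort is reported. The permutation control shuffles trial *content*
  within participant (positions and session structure stay), rebuilds the
  lagged regressor from the shuffled order, and refits both models.
* **Mode labels.** External iff P(z_t = external) > 0.5; run lengths are
  maximal constant-label stretches, converted to seconds at 2.0 s/trial
  (0.5 s stimulus + 0.5 s mask + 1.0 s mean inter-trial interval). If both
  states land on the same side of β_S = β_H the labeling degenerates to
  "larger β_S − β_H" with a warning.

## Statistics (`modeseek.stats`)

* **Alarm-rate model.** Mixed logistic regression of the alarm on current
  contrast, preceding contrast (lagged within session), and relative
  vertical power (centred at its flat-noise value 1), with a fixed intercept
  and participant random intercepts. The statsmodels Bayesian mixed GLM is
  fit by its Laplace/MAP route: on null simulations its Wald tests hold the
  nominal level, whereas the variational route's posterior scales are
  anticonservative (measured 22% type-I at nominal 5%) — hence Laplace is
  the default, with the optimizer's RNG pinned for bit-reproducibility.
  Random slopes are out of scope; a pooled fixed-effects logit is available
  (`method="fixed"`), and `standardize` rescales predictors without changing
  the signs of the z statistics.
* **Mode-conditional serial dependence.** `alarm ~ contrast + prev_contrast`
  (with intercept) fit separately on internal- and external-labeled trials;
  the preceding-contrast coefficient is the serial-dependence measure.
* **FA rate by mode.** FA rates on noise-only trials per
  participant × session block and mode; blocks missing a mode are dropped
  with a warning; the internal-minus-external differences get a paired t
  (df = blocks − 1). Per-participant blocking is available; the natural
  blocking unit is genuinely ambiguous, which mostly moves the df, not the
  sign.
* **Template-shift test.** Per participant and mode, classification images
  over noise-only trials immediately following an inducer, split by inducer
  direction; the average-vector angles after CW vs CCW inducers are compared
  by a Welch two-sample t (fractional df), and the reported effect is the
  mean displacement toward the inducer,
  ((angle_CW − 90°) + (90° − angle_CCW))/2. Degenerate zero-variance inputs
  return t = 0 with a warning. `vertical_displacement` reports
  mean ± SEM of |angle − 90°| across participants.
* No multiple-testing correction is applied anywhere.

## Benchmark studies and problem sizes (`modeseek.experiments`)

All sizes are chosen to finish in minutes on one CPU while keeping the
relevant Monte-Carlo error small; each study takes a single seed that
drives all of its randomness.

* **Recovery** — 20 default observers × 2000 trials; reports median
  absolute emission-weight error, median self-transition error, median
  decoding accuracy against the hidden modes, and ΔBIC summaries. For
  context, decoding the modes with the *true* parameters and exact
  forward–backward (the Bayes ceiling) achieves a median accuracy of about
  0.85 at these settings, and the true model's likelihood advantage over the
  one-state MLE straddles the BIC penalty 2·ln(2000) ≈ 15.2 — so even the
  oracle's ΔBIC is not negative for every observer. These conditions bound
  what any fitted model can achieve.
* **Model selection** — the same cohort plus 20 within-participant
  permutations; the observed summed ΔBIC is strongly negative and the
  permuted median strongly positive (advantage lost).
* **Template recovery** — part 1: 10,000 noise-only trials at 128 px with
  `template_gain` = 2 and bias −2 (FA rates are then informative at both
  response classes). Because the coupling is to *band-mean* power, the
  expected classification image is a plateau over 60–120°; the
  average-vector angle is the peak-location estimate (stable near 90°),
  while the raw arg-max bin is only localized to the band. Part 2: 20
  inducer-following observers × 16,000 trials at 64 px; this size gives
  ≈ 95% power for the mechanism's ~4° internal-mode displacement (10 × 4000
  gives only ~50%), with the external-mode displacement serving as the
  built-in null.
* **Calibration** — the standard calibration observer; achieved d′ is
  re-simulated at an independent seed.
* **Type-I calibration** — 500 null datasets (6 participants × 600 trials,
  32-px noise) from `simulate_null_observer`: responses depend on current
  contrast only and an independent Markov chain supplies mode labels, so
  every history-, mode- and template-related test is null by construction
  while its machinery is fully exercised. Rejection rates at nominal 5% are
  reported per test.

## What the generator does and does not emulate

The synthetic world reproduces the design parameters (trial mix, inducer
scheduling, stimulus geometry and spectra, session structure), the
two-state emission/transition structure, and — through the template
extensions — content-selective false alarms and mode-specific serial
templates. It does not emulate: perceptual learning or drift across
sessions, contrast adaptation, lapses correlated in time, orientation
anisotropies of real observers (oblique effect), display nonlinearities, or
reaction times. Passing tests therefore demonstrate that the *analysis
recovers the structure it assumes*, at realistic sizes and noise levels —
not that real observers obey that structure. The emission scale is also a
synthetic convention: with weights of order 4 per contrast unit and no
intercept by default, calibrated "low" contrasts come out high in Michelson
terms (≈ 0.7); real observers reach d′ ≈ 1.5 at far lower contrasts because
their effective stimulus weights are much larger and their criteria
negative.

## Known limitations

* Two states only; no input-driven transitions, no hierarchical sharing
  across participants, no variational or sampling-based inference.
* The mixed model supports participant random intercepts only.
* The external-dataset adapter maps column aliases onto the trial-table
  schema but cannot validate semantics (orientation conventions, contrast
  units) of arbitrary deposits.
* BIC at the MAP (rather than ML) point slightly penalizes the two-state
  model when the prior binds; with σ² = 10 the effect is negligible at
  n = 2000.
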