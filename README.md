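# modeseek

Classification-image and GLM-HMM analysis of false alarms in
Gabor-in-noise detection experiments.

## The problem

In a yes/no detection task, observers judge whether a faint near-vertical
grating (a Gabor patch) is present in a patch of white noise. On some
noise-only trials they report seeing a signal anyway — a *false alarm* (FA).
Two questions about such FAs motivate this package:

1. **Do FAs carry perceptual content?** If an FA reflects a genuine
   percept rather than a response lapse, it should occur preferentially on
   noise images whose orientation content happens to match the expected
   signal. This is tested with *classification images*: the mean
   orientation-power profile of the noise on alarm trials minus that on
   rejection trials. A peak near vertical (90°) means the observer's internal
   template selected signal-like noise.
2. **Do FAs cluster in time?** Behavior in long sessions alternates between
   an *external mode*, in which responses track the current stimulus, and an
   *internal mode*, in which responses track recent experience (serial
   dependence). A two-state hidden Markov model with logistic emissions
   (a GLM-HMM) segments the trial series into these modes; FAs and
   template effects should concentrate in the internal mode.

The package provides every stage — synthetic experiment generation with
ground-truth mode dynamics, spectral analysis of noise stimuli, the GLM-HMM
fit, and the statistics — so the whole pipeline is testable end to end
without any external data.

## The model

Responses are $y_t \in \{0,1\}$ (rejection/alarm). Each latent state
$z_t \in \{\mathrm{external}, \mathrm{internal}\}$ has its own logistic
emission model on the current signal contrast $s_t$ and the previous
response:

$$P(y_t = 1 \mid x_t, z_t) = \sigma\left(s_t\,\beta_{S,z_t} + y_{t-1}\,\beta_{H,z_t}\right),$$

with state transitions governed by a 2×2 row-stochastic matrix $A$.
Fitting is MAP-EM: a Gaussian prior with variance $\sigma^2 = 10$ over
the emission weights, a Dirichlet($\alpha = 1$) prior over the rows of
$A$, an exact scaled forward–backward E-step, and penalized weighted
logistic M-steps. The external state is the one with $\beta_S > \beta_H$;
a trial is labeled external when $P(z_t = \mathrm{external}) > 0.5$. The
two-state model is compared with the one-state control GLM by
$\Delta\mathrm{BIC} = \mathrm{BIC}_2 - \mathrm{BIC}_1$
(negative favors two states), with a within-participant trial-order
permutation control under which the two-state advantage must disappear.

Noise images are reduced to orientation-power profiles: Gaussian-envelope
filtering, 2-D FFT, and power sampled on the circle at the Gabor's spatial
frequency (0.5 cpd) in 60 axial bins of 3° over [0°, 180°), with vertical
gratings mapping to the 90° bin. *Relative vertical power* is the mean power
in the 60–120° band divided by the mean over all orientations.
Classification images are summarized by their *average vector* — the
centroid of the bin endpoints in polar coordinates; angles above 90° denote
clockwise displacement.

## Worked example

Simulate one synthetic observer (external state β = (4, 0.2), internal
β = (1, 2), self-transitions 0.98) for 2000 trials and fit the GLM-HMM:

```python
import numpy as np
import modeseek as mk
from modeseek import glmhmm

design = mk.ExperimentDesign()
observer = mk.GenerativeObserver()
seq = mk.generate_trial_sequence(design, seed=11, n_trials=2000)
trials = mk.simulate_observer(seq, observer, seed=12, participant=0)

fit = mk.fit_glm_hmm(trials)
X, y, _ = glmhmm.build_design(trials)
one = glmhmm.fit_one_state_glm(X, y)
labels = glmhmm.label_modes(fit)

print("external state (beta_S, beta_H):", np.round(fit.weights[0], 2))
print("internal state (beta_S, beta_H):", np.round(fit.weights[1], 2))
print("delta BIC (two-state minus one-state):", round(glmhmm.delta_bic(fit, one), 1))
print("internal-mode occupancy:", round(labels.occupancy_internal, 3))
print("mean mode run length:", round(labels.mean_run_length_trials, 1), "trials")
```

prints

```
external state (beta_S, beta_H): [4.02 0.17]
internal state (beta_S, beta_H): [0.77 2.05]
delta BIC (two-state minus one-state): -8.3
internal-mode occupancy: 0.494
mean mode run length: 47.6 trials
```

The fit recovers the generating weights (stimulus-driven external state,
history-driven internal state), the negative ΔBIC favors the two-state
description, and the decoded modes alternate on the order of ~50 trials
(~95 s at 2 s/trial), matching the generator's 0.98 self-transitions. On
this single observer the decoded labels match the hidden modes on 84.8% of
trials.

The same pipeline runs from the shell:

```sh
modeseek run --seed 3 --participants 6 --out run/
modeseek permute --trials run/trials.csv --n 20 --seed 7
```

which writes trial tables, orientation-power profiles, per-participant fits,
mode posteriors, classification vectors, a statistics report, and a manifest
of SHA-256 hashes that makes re-runs bit-checkable.

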