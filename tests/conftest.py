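import dataclasses

import numpy as np
import pandas as pd
import pytest

from modeseek import ExperimentDesign, GenerativeObserver, generate_trial_sequence, simulate_observer


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_design():
    """Coarse pixel grid for tests that only need profile statistics."""
    return dataclasses.replace(ExperimentDesign(), n_pixels=32)


@pytest.fixture(scope="session")
def two_state_trials(design):
    """One default two-state observer, 2000 trials."""
    seq = generate_trial_sequence(design, seed=1, n_trials=2000)
    return simulate_observer(seq, GenerativeObserver(), seed=2, participant=0)


def make_trials(responses, sessions=None, contrasts=None, participant=0):
    """Hand-built minimal trial table for unit tests."""
    n = len(responses)
    sessions = np.zeros(n, dtype=int) if sessions is None else np.asarray(sessions)
    contrasts = np.zeros(n) if contrasts is None else np.asarray(contrasts, dtype=float)
    trial = np.concatenate(
        [np.arange(np.sum(sessions == s)) for s in np.unique(sessions)]
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "session": sessions,
            "trial": trial,
            "stim_class": np.where(contrasts == 0, "noise", "low"),
            "contrast": contrasts,
            "orientation_deg": np.nan,
            "response": np.asarray(responses, dtype=int),
        }
    )
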