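import numpy as np
import pandas as pd
import pytest

from esm_affect.synthetic_data import GeneratorParams, simulate_dataset


@pytest.fixture(scope="session")
def small_study():
    """Deterministic mid-sized synthetic study shared across model tests."""
    params = GeneratorParams(n_participants=30, n_pleasant=8, n_neutral=8, n_unpleasant=8)
    participants, stimuli, trials = simulate_dataset(params, seed=42)
    return params, participants, stimuli, trials


@pytest.fixture(scope="session")
def tiny_trials():
    """Hand-built four-trial table with known ratings."""
    return pd.DataFrame(
        {
            "participant_id": ["a", "a", "b", "b"],
            "stimulus_id": ["s1", "s2", "s1", "s2"],
            "category": ["pleasant", "neutral", "pleasant", "neutral"],
            "social": [True, False, True, False],
            "positivity": [8, 5, 6, 0],
            "negativity": [2, 5, 0, 0],
            "arousal": [4, 2, 3, 1],
        }
    )
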