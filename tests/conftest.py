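import numpy as np
import pytest

from sylseq.landmarks import F1Range
from sylseq.stimuli import build_schedule, build_stimulus_table
from sylseq.synth_audio import DEFAULT_PROFILE, synth_sequence


@pytest.fixture(scope="session")
def stimulus_table():
    return build_stimulus_table()


@pytest.fixture(scope="session")
def schedule():
    return build_schedule(7)


@pytest.fixture(scope="session")
def f1_default():
    """F1 band for the default profile (vowel F1 700 Hz, ±10% guard)."""
    return F1Range(630.0, 770.0, 10)


@pytest.fixture(scope="session")
def clean_trials(stimulus_table):
    """One clean synthetic trial per stimulus, default speaker profile."""
    return [(stim, synth_sequence(stim, DEFAULT_PROFILE, seed=100 + i))
            for i, stim in enumerate(stimulus_table)]
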