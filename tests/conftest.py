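"""Shared fixtures for the test suite."""

import numpy as np
import pytest

from nremscope import synthsleep
from nremscope.synthsleep import SimConfig


@pytest.fixture(scope="session")
def small_subject():
    """One deterministic synthetic subject with a short night."""
    cfg = SimConfig(seed=7, n_epochs=120)
    rng = np.random.default_rng(np.random.SeedSequence(7))
    return synthsleep.gen_subject(cfg, rng, subject_id="s_small"), cfg


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two groups x two subjects at reduced night length (fast cohort runs)."""
    cfg = SimConfig(seed=11, n_subjects=2, n_epochs=80)
    effects = {"control": synthsleep.GroupEffects(),
               "patient": synthsleep.GroupEffects(sw_amplitude_mult=0.8)}
    return synthsleep.gen_cohort(cfg, effects), cfg
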