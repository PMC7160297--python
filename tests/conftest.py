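import numpy as np
import pytest

from spectronet import (CohortSpec, EffectSpec, baseline_correct, bandpass,
                        dataset_ersp, simulate_cohort)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3v3 subjects, 10 frames each; shared across tests that only need a
    plausible labelled dataset."""
    spec = CohortSpec(n_per_group=3, frames_per_subject=10, seed=101)
    effects = EffectSpec(seed=102)
    subjects, epochs = simulate_cohort(spec, effects)
    return spec, effects, subjects, epochs


@pytest.fixture(scope="session")
def tiny_frames(tiny_cohort):
    _, _, subjects, epochs = tiny_cohort
    clean = {sid: baseline_correct(bandpass(es)) for sid, es in epochs.items()}
    return subjects, dataset_ersp(clean, subjects)


@pytest.fixture(scope="session")
def separated_frames():
    """Strongly separated two-class frames for learnability checks.

    Class-dependent mean shift in a block of cells plus noise; linearly
    separable in expectation."""
    rng = np.random.default_rng(42)
    n = 96
    y = np.arange(n) % 2
    x = rng.normal(0.0, 1.0, size=(n, 22, 20, 7))
    x[y == 1, 4:9, 2:8, :] += 3.0
    return x.astype(np.float32), y
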