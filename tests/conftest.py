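import numpy as np
import pytest

from perturbstance.constants import PLATFORM_CHANNEL
from perturbstance.segmentation import detect_onsets, segment
from perturbstance.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_subjects=2, trials_per_phase=3, n_anterior=1, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def segmented_trials(small_cohort):
    trials = []
    for rec in small_cohort.iter_trial_recordings():
        onsets = detect_onsets(rec.channels[PLATFORM_CHANNEL], 0.05)
        trials.extend(segment(rec, onsets, metadata=[rec.meta] * len(onsets)))
    return trials


@pytest.fixture(scope="session")
def mvc_refs(small_cohort):
    from perturbstance.emg_features import extract_mvc_reference

    refs = {}
    for sid in small_cohort.reflex_latencies:
        refs[sid] = {m: extract_mvc_reference(arrs, m)
                     for m, arrs in small_cohort.mvc_trials(sid).items()}
    return refs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
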