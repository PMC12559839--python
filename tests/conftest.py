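import numpy as np
import pytest

from speechlfp import (
    SynthConfig,
    TASKS,
    epoch_time_grid,
    generate_cohort,
    preprocess_session,
)
from speechlfp.timefreq import build_wavelet_bank, db_normalize, wavelet_power

#: problem sizes for cohort-level tests: small enough to keep the suite fast,
#: large enough for the group statistics to behave
N_PARTICIPANTS = 5
TRIALS_PER_TASK = 30
RAW_RATE_HZ = 500.0
N_FREQS = 16


def cohort_config(seed: int, null: bool = False, **overrides) -> SynthConfig:
    kw = dict(n_participants=N_PARTICIPANTS, trials_per_task=TRIALS_PER_TASK,
              sampling_rate_hz=RAW_RATE_HZ, seed=seed)
    if null:
        kw["theta_effect_db"] = {t: 0.0 for t in TASKS}
        kw["beta_effect_db"] = {t: 0.0 for t in TASKS}
    kw.update(overrides)
    return SynthConfig(**kw)


def cohort_tensors(config: SynthConfig, n_freqs: int = N_FREQS):
    """Generate -> preprocess -> wavelet dB tensors for every session."""
    bank = build_wavelet_bank(n_freqs=n_freqs)
    tensors = []
    for session, ann, _truth in generate_cohort(config):
        epochs, _report = preprocess_session(session, ann, line_hz=None)
        tensors.append(db_normalize(wavelet_power(epochs, bank)))
    return tensors


@pytest.fixture(scope="session")
def times_ms():
    return epoch_time_grid()


@pytest.fixture(scope="session")
def small_session():
    """One 4-contact session with default graded effects, 500 Hz raw."""
    from speechlfp import generate_session

    cfg = cohort_config(seed=10, trials_per_task=10)
    return generate_session(cfg, "P01", "left", seed=11)


@pytest.fixture(scope="session")
def effect_tensors():
    """Cohort with the default graded effects, processed to dB tensors."""
    return cohort_tensors(cohort_config(seed=21))
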