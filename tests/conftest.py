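import numpy as np
import pytest

from vptlab.bias import bias_table
from vptlab.cohort import CohortConfig, simulate_cohort
from vptlab.preprocess import exclude_participants, filter_trials, orientation_profiles

# Fixed master seed for all seeded fixtures (the study's publication date).
MASTER_SEED = 20220225


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-default synthetic cohort: (config, trials, questionnaires,
    true participant parameters)."""
    cfg = CohortConfig(seed=MASTER_SEED)
    trials, quest, params = simulate_cohort(cfg)
    return cfg, trials, quest, params


@pytest.fixture(scope="session")
def retained_profiles(default_cohort):
    """RT/error orientation profiles of the retained participants, plus the
    retained true parameters."""
    _, trials, _, params = default_cohort
    retained, _ = exclude_participants(trials)
    kept = trials[trials.participant_id.isin(retained)]
    filt = filter_trials(kept)
    return {
        "retained": retained,
        "rt": orientation_profiles(filt.rt_stream, "rt_ms"),
        "error": orientation_profiles(filt.error_stream, "error_rate"),
        "params": params[params.participant_id.isin(retained)].set_index("participant_id"),
    }


@pytest.fixture(scope="session")
def rt_biases(retained_profiles):
    return bias_table(retained_profiles["rt"])


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with zero noise and no errors: regression recovery is
    exact (up to RT rounding)."""
    cfg = CohortConfig(seed=MASTER_SEED + 1, n_recruited=6, n_lapse=0,
                      sigma=0.0, tau=0.0, p_error=0.0,
                      n_missing_questionnaire=0)
    trials, quest, params = simulate_cohort(cfg)
    return cfg, trials, quest, params


@pytest.fixture(scope="session")
def analyzed(default_cohort):
    from vptlab.pipeline import analyze

    _, trials, quest, _ = default_cohort
    return analyze(trials, quest)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
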