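import numpy as np
import pytest

import ovitrack as ot
from ovitrack.features import window_features
from ovitrack.io import BehaviourLabel

#: daily time shares close to the published baseline behaviour budget
DEFAULT_QUOTAS = {
    BehaviourLabel.RUMINATION: 0.34,
    BehaviourLabel.RESTING_IDLING: 0.44,
    BehaviourLabel.EATING: 0.19,
    BehaviourLabel.OTHER: 0.03,
}


def make_synth_session(minutes, schedule_seed, signal_seed, quotas=None):
    """A synthetic observation session: (trace, annotations, minute truth)."""
    schedule = ot.simulate_schedule(
        minutes, quotas or DEFAULT_QUOTAS, seed=schedule_seed
    )
    trace, annotations = ot.synth_trace(schedule, ot.SimConfig(seed=signal_seed))
    return trace, annotations, ot.annotations_to_minutes(annotations)


@pytest.fixture(scope="session")
def train_session():
    """4 h synthetic session used for calibration across tests."""
    return make_synth_session(240, schedule_seed=11, signal_seed=12)


@pytest.fixture(scope="session")
def holdout_session():
    """Independent 4 h synthetic session for held-out scoring."""
    return make_synth_session(240, schedule_seed=21, signal_seed=22)


@pytest.fixture(scope="session")
def fitted_results(train_session):
    trace, _, truth = train_session
    model = ot.ThresholdBehaviourModel(window_features(trace), truth)
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
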