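import numpy as np
import pytest

import gaitprog as gp


@pytest.fixture(scope="session")
def small_planted_cohort():
    """14-subject cohort with the default large planted effects (session-cached)."""
    spec = gp.CohortSpec(n_good=8, n_poor=6, cycles_per_subject=8, seed=5,
                         effects=gp.default_effects())
    subjects, manifest = gp.generate_cohort(spec)
    return spec, subjects, manifest


@pytest.fixture(scope="session")
def small_features(small_planted_cohort):
    """Feature table + labels for the small planted cohort."""
    _, subjects, _ = small_planted_cohort
    model = gp.OutcomePrognosisModel.from_cohort(subjects)
    return model.features, model.labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
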