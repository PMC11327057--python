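import numpy as np
import pytest

import qppdyn as q


@pytest.fixture(scope="session")
def pattern_library():
    """Three planted patterns on 90 locations (global + two anti-phase block pairs)."""
    return q.make_pattern_library(90, 3, seed=5)


@pytest.fixture(scope="session")
def small_subject(pattern_library):
    """One noisy subject with a ramping global pattern (SNR 1)."""
    specs = [
        q.EnvelopeSpec("linear_ramp", 0.5, 1.5),
        q.EnvelopeSpec("constant", 1.0),
        q.EnvelopeSpec("constant", 0.8),
    ]
    return q.simulate_subject(
        pattern_library, specs, 400, 0.72, snr=1.0, seed=11, subject_id="sub-000"
    )


@pytest.fixture(scope="session")
def cohort_recovery():
    """Full-size two-group cohort pushed through the whole pipeline (shared)."""
    from qppdyn import experiments

    return experiments.run_cohort_recovery(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
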