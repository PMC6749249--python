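import pytest

import mosdetect as m


@pytest.fixture(scope="session")
def canonical_session():
    """One default session (10 canonical events, seed 1) plus its 1 Hz table."""
    spec = m.SessionSpec(seed=1)
    gsr, st, geo, truth = m.generate_session(spec)
    table = m.preprocess_session(gsr, st, geo)
    return spec, gsr, st, geo, truth, table


@pytest.fixture(scope="session")
def quiet_session():
    """Zero-noise, zero-drift session with three canonical events."""
    spec = m.SessionSpec(
        duration=400.0, n_events=3, noise_sd_gsr=0.0, noise_sd_st=0.0,
        baseline_drift=0.0, rest_phase=60.0, seed=5,
    )
    gsr, st, geo, truth = m.generate_session(spec)
    table = m.preprocess_session(gsr, st, geo)
    return spec, gsr, st, geo, truth, table
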