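import numpy as np
import pytest

from sicisim import (
    CohortParams,
    ExcitabilityModel,
    ProtocolConfig,
    StudyDesign,
    run_study,
    summarize_group_curves,
    summarize_reliability,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_model():
    """Deterministic subject: no trial noise, drift or contamination."""
    return ExcitabilityModel(
        theta_true=55.0,
        slope_b=0.05,
        sigma_log=0.0,
        session_drift_sd=0.0,
        inhibition_sd_within=0.0,
        contamination_rate=0.0,
    )


@pytest.fixture
def noisy_model():
    return ExcitabilityModel(
        theta_true=55.0,
        slope_b=0.065,
        sigma_log=0.2,
        session_drift_sd=0.0,
        inhibition_sd_within=0.0,
        contamination_rate=0.0,
    )


@pytest.fixture
def protocol_cfg():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def default_study():
    """One complete default study plus its summaries and wall time.

    Shared across tests; the elapsed time covers simulation and the full
    reliability/group-curve analysis.
    """
    import time

    t0 = time.perf_counter()
    ds = run_study(
        CohortParams(n_subjects=18, seed=7), StudyDesign(), ProtocolConfig(), seed=1
    )
    rel = summarize_reliability(ds)
    curves = summarize_group_curves(ds)
    elapsed = time.perf_counter() - t0
    return ds, rel, curves, elapsed
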