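import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (10 planted types x 30 calls, 20 dB SNR),
    shared by the end-to-end checks."""
    from pilotcalls.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    report = run_pipeline(RunConfig(seed=0), str(out))
    return out, report


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A light synthetic bundle (10 types x 3 calls) for I/O round-trips."""
    from pilotcalls import synthcalls as sc

    out = tmp_path_factory.mktemp("small_bundle")
    spec = sc.default_synth_spec(seed=42, calls_per_type=3)
    bundles = sc.render_dataset(spec, str(out))
    return spec, bundles
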