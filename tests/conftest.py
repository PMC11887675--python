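import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One noise-free synthetic bundle shared across pipeline-level tests."""
    from glycopull.synthetic import make_fixture

    outdir = tmp_path_factory.mktemp("bundle")
    paths, truth = make_fixture(outdir, seed=7)
    return paths, truth
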