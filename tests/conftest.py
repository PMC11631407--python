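import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def gd_fixture(tmp_path_factory):
    """Default GenomeDiff fixture set: (directory, manifest)."""
    from refugia.synth import make_gd_fixtures

    d = tmp_path_factory.mktemp("gd_default")
    manifest = make_gd_fixtures(d, seed=0)
    return d, manifest


@pytest.fixture(scope="session")
def gd_pipeline(gd_fixture):
    """Pipeline results on the default fixture, computed once."""
    from refugia.genomediff import run_pipeline

    d, _ = gd_fixture
    return run_pipeline(d / "sample_sheet.csv", d)
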