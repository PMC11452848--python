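import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def peach_dataset(tmp_path_factory):
    """Small rendered peach dataset (8 per grade) shared across tests."""
    from fruitgrade import synthetic

    out = tmp_path_factory.mktemp("peach_ds")
    grades, template = synthetic.load_preset("peach")
    manifest = synthetic.make_benchmark_dataset(grades, template, 8, 42, out, species_tag="peach")
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
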