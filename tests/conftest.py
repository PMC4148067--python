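import numpy as np
import pytest
from hypothesis import settings

from clonability.synthetic import SyntheticConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticConfig(seed=0, write_fasta=False), outdir)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
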