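import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_mixture():
    """A fast mixed config exercising tolerant, IR and cache-hash paths."""
    from nrcomp import MixtureConfig, ModelSpec

    return MixtureConfig(
        models=(
            ModelSpec(12, 0.02, tolerance=2),
            ModelSpec(12, 0.01),
            ModelSpec(4, 0.5, inverted_repeats=True),
            ModelSpec(2, 1.0),
        ),
        gamma=0.9,
        cache_hash=4,
    )


@pytest.fixture(scope="session")
def tiny_fasta(tmp_path_factory):
    """A 3 kb random sequence written to FASTA, for CLI tests."""
    import nrcomp as nr

    path = tmp_path_factory.mktemp("fasta") / "r.fa"
    nr.write_fasta([nr.generate_random(3000, 5, id="r")], path)
    return str(path)
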