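import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Two-record FASTA with lowercase soft-masking and an N gap."""
    path = tmp_path / "tiny.fasta"
    path.write_text(">ctg1 first contig\nACGTNNNNNNacgt\n>ctg2\nGGCCggcc\n")
    return path
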