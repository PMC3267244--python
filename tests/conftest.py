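import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome(tmp_path):
    """A two-contig genome FASTA for BED-extraction and genome-null tests."""
    rng = np.random.default_rng(5)
    chr1 = "".join(rng.choice(list("ACGT"), size=300))
    chr2 = "".join(rng.choice(list("ACGT"), size=150))
    path = tmp_path / "genome.fa"
    path.write_text(f">chr1\n{chr1}\n>chr2\n{chr2}\n")
    return path, {"chr1": chr1, "chr2": chr2}
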