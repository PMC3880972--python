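import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from asmqc import fixtures


@pytest.fixture
def small_truth():
    """10 genes, moderate lengths; enough structure for end-to-end checks."""
    return fixtures.make_reference(10, min_aa=40, max_aa=150, seed=11)


@pytest.fixture
def fragmented(small_truth):
    contigs, hits, truth = fixtures.fragment_assembly(
        small_truth, fragments_per_gene=3, seed=11
    )
    return contigs, hits, truth
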