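import pytest
from hypothesis import settings

from fabpkit.motif_scan import WeightMatrix
from fabpkit.synthetic_data import consensus_to_counts

# property tests must be reproducible run-to-run (no example database)
settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_genome():
    """Tiny chromosome for hand-checkable promoter slicing."""
    return {"chrA": "AAAACGTT"}


@pytest.fixture
def consensus_matrix():
    """High-information width-10 matrix whose consensus is ACGTACGTAC."""
    return WeightMatrix("MX0001", "toy_consensus", consensus_to_counts("ACGTACGTAC"))
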