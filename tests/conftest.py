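import pytest
from hypothesis import settings

from ms4anchors.sitespace import SequenceSet

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def twin_acgt() -> SequenceSet:
    """Two identical 4-mers: every position pairs with its twin."""
    return SequenceSet.from_strings(["ACGT", "ACGT"])


@pytest.fixture
def distinct_pair() -> SequenceSet:
    """No repeated residue anywhere: everything stays a singleton."""
    return SequenceSet.from_strings(["AB", "CD"])
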