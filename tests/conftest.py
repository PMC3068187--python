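import pytest

from poolseq import PoolDesign


@pytest.fixture
def design():
    """The study layout: 5 pools of 20 diploid individuals."""
    return PoolDesign(5, 20)


@pytest.fixture
def single_pool():
    return PoolDesign(1, 20)
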