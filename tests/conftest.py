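import pytest

from purfrag.enumerate import (
    default_alcohols,
    default_isocyanates,
    enumerate_library,
)


@pytest.fixture(scope="session")
def default_blocks():
    return default_isocyanates(), default_alcohols()


@pytest.fixture(scope="session")
def default_library(default_blocks):
    """The full amine-capped 2/3/4-unit library from the packaged blocks."""
    isos, ols = default_blocks
    return enumerate_library(isos, ols, (2, 3, 4), cap="amine")
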