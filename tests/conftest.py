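import pytest

from pbnfit import casestudies as cs


@pytest.fixture(scope="session")
def example_pbn():
    """Three-node example: N3 driven by N1 (c=0.6) or N1 & ~N2 (c=0.4)."""
    return cs.example_pbn()


@pytest.fixture(scope="session")
def bundle1():
    return cs.case1()


@pytest.fixture(scope="session")
def bundle2():
    return cs.case2()


@pytest.fixture(scope="session")
def bundle3():
    return cs.case3()
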