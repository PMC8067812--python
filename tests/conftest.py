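import pytest

from exactsim.synthetic import fixtures


@pytest.fixture(scope="session")
def f1364():
    return fixtures("F1364")


@pytest.fixture(scope="session")
def f1344():
    return fixtures("F1344")


@pytest.fixture(scope="session")
def f1228():
    return fixtures("F1228")


@pytest.fixture(scope="session")
def f_dimer():
    return fixtures("F_DIMER")


@pytest.fixture(scope="session")
def f_noti():
    return fixtures("F_NOTI")
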