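import pytest

import abdimer as ab


@pytest.fixture(scope="session")
def general():
    return ab.default_parameters("general")


@pytest.fixture(scope="session")
def down():
    return ab.default_parameters("down")


@pytest.fixture(scope="session")
def dynamic_general(general):
    return ab.dynamic_hazard(general)


@pytest.fixture(scope="session")
def static_general(general):
    return ab.static_hazard(general)
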