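import pytest

from neurosweep.synthetic import toy_cerebellum_spec, minimal_two_type_spec


@pytest.fixture(scope="session")
def toy_spec():
    return toy_cerebellum_spec()


@pytest.fixture(scope="session")
def minimal_spec():
    return minimal_two_type_spec()
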