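import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def defaults():
    from pancreg import default_parameters

    return default_parameters()
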