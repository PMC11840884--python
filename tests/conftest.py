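import pytest

from dispersalenergy import DEFAULT_PARAMETERS, AnimalProfile


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMETERS


@pytest.fixture(
    params=["bird", "mammal", "fish"],
    ids=["flying-bird", "running-mammal", "swimming-fish"],
)
def each_group(request):
    """One representative 1 kg animal per parameterized pairing."""
    return AnimalProfile(1.0, group=request.param)
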