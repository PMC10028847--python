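import pytest

from mams import generate_use_case


@pytest.fixture
def simple_doc():
    """The simple scRNA-seq workflow document (strictly conformant)."""
    return generate_use_case("simple_rnaseq")


@pytest.fixture
def all_use_case_docs():
    from mams import USE_CASES
    return {name: generate_use_case(name) for name in USE_CASES}
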