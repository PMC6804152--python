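import pytest

from herbannot import AnnotationConfig, builtin_fixture_library


@pytest.fixture(scope="session")
def lib():
    return builtin_fixture_library()


@pytest.fixture(scope="session")
def config():
    return AnnotationConfig()
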