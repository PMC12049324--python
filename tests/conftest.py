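import pytest

from uacr_cea import load_config


@pytest.fixture(scope="session")
def cfg():
    """Packaged base-case configuration (synthetic life table)."""
    return load_config()
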