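from pathlib import Path

import pytest

from gramloc import RunConfig, load_default_catalog

DIALECT_DIR = Path(__file__).parent / "data" / "dialects"


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def dialect_dir():
    return DIALECT_DIR
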