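import sys
from pathlib import Path

import pytest

# make the sibling oracle helpers importable as `_oracles`
sys.path.insert(0, str(Path(__file__).parent))

from trialbf import example_config_path, read_config


@pytest.fixture(scope="session")
def remdesivir_records():
    return read_config(example_config_path())
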