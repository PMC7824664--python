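from pathlib import Path

import pytest

from rnascale.scenarios import CostParams, Demand, ProcessParams, table1_presets
from rnascale.throughput import process_recovery

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture(scope="session")
def presets():
    return table1_presets()


@pytest.fixture()
def process():
    return ProcessParams()


@pytest.fixture()
def costs():
    return CostParams()


@pytest.fixture()
def demand():
    return Demand()


@pytest.fixture(scope="session")
def effective_recovery_default():
    return process_recovery(ProcessParams())


@pytest.fixture(scope="session")
def examples_dir():
    return EXAMPLES
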