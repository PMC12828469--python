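import numpy as np
import pytest

from photorank.chem_io import CatalystRegistry
from photorank.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return CatalystRegistry.default()


@pytest.fixture(scope="session")
def small_corpus(registry):
    """400 synthetic records at the default study conditions, with truth."""
    records, truth = generate_dataset(
        GeneratorConfig(n_records=400, label_noise=0.1, seed=11, registry=registry)
    )
    return records, truth


@pytest.fixture(scope="session")
def labels_of(registry):
    def _labels(records):
        return np.array([registry.encode(r.catalyst_label) for r in records])

    return _labels
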