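import numpy as np
import pytest

from reefbiome.tables import OtuTable
from reefbiome.synthetic import GeneratorParams, generate_dataset

# Reduced-scale generator settings used where only structure (not planted
# recovery power) is being exercised; keeps unit tests fast.
SMALL_PARAMS = dict(n_otus=300, depth=8_000)


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with taxonomy; hand-checkable."""
    counts = np.array([
        [5, 0, 3, 1],
        [2, 2, 0, 4],
        [0, 7, 1, 1],
    ])
    tax = {
        "otuA": "k__Bacteria;p__Proteobacteria;c__;o__;f__;g__",
        "otuB": "k__Bacteria;p__Firmicutes;c__;o__;f__;g__",
    }
    return OtuTable(["s1", "s2", "s3"], ["otuA", "otuB", "otuC", "otuD"],
                    counts, tax)


@pytest.fixture(scope="session")
def small_dataset():
    params = GeneratorParams(**SMALL_PARAMS)
    return generate_dataset(params, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size dataset at the study conditions (96 samples)."""
    return generate_dataset(seed=7)
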