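import numpy as np
import pytest

from srnapipe.io_formats import SequenceRecord, TagCountTable
from srnapipe import synthdata


@pytest.fixture(scope="session")
def reference():
    return synthdata.make_reference(seed=7)


@pytest.fixture(scope="session")
def truth(reference):
    return synthdata.make_truth(reference, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def small_table():
    import pandas as pd

    df = pd.DataFrame(
        {"CK": [5, 0, 3], "A": [0, 2, 3], "M": [1, 1, 0]},
        index=["AAAACCCCGGGGTTTTAA", "ACGTACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAATT"],
    )
    return TagCountTable(df, {"CK": 100, "A": 100, "M": 100})
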