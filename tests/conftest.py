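import logging

import numpy as np
import pandas as pd
import pytest

from binsim.peak_table import PeakTable
from binsim.synthetic_data import table1_like

logging.getLogger("binsim").setLevel(logging.ERROR)


@pytest.fixture
def tiny_table():
    """3 samples x 4 features with two missing entries."""
    df = pd.DataFrame(
        [[12.3, np.nan, 5.0, 7.0],
         [np.nan, 5.1, 6.0, 8.0],
         [4.0, 6.2, 7.0, 9.0]],
        index=["s1", "s2", "s3"],
        columns=[100.1, 200.2, 300.3, 400.4],
    )
    return PeakTable(df, labels={"s1": "A", "s2": "A", "s3": "B"})


@pytest.fixture(scope="session")
def yd_dataset():
    """One YD-regime synthetic dataset shared by the end-to-end tests."""
    return table1_like("YD-like", seed=1)
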