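import numpy as np
import pandas as pd
import pytest

from mirna_synergy.datatypes import MIRNA, MRNA, ExpressionMatrix


@pytest.fixture
def small_expr():
    """3 miRNAs x 4 samples, fully observed."""
    return ExpressionMatrix.from_array(
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [2.0, 2.5, 3.5, 4.5],
                  [9.0, 1.0, 5.0, 2.0]]),
        ["miR-a", "miR-b", "miR-c"], ["S1", "S2", "S3", "S4"],
        [MIRNA, MIRNA, MIRNA])


def make_expr(arr, ids=None, classes=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"g{i}" for i in range(arr.shape[0])]
    classes = classes or [MRNA] * arr.shape[0]
    samples = [f"S{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=ids, columns=samples)
    return ExpressionMatrix(df, pd.Series(classes, index=ids))
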