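import numpy as np
import pandas as pd
import pytest

from circsplice.expression import ExpressionMatrix


@pytest.fixture
def grid16():
    """The default sampling grid: every 3 h over 45 h starting at 9 h."""
    return 9.0 + 3.0 * np.arange(16)


def make_matrix(values, times, unit="CPM", condition="WT", feature_ids=None):
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[1]
    sample_ids = [f"{condition}_s{i:02d}" for i in range(n)]
    samples = pd.DataFrame(
        {"condition": condition, "time_h": np.asarray(times, float), "replicate": 1},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                        columns=sample_ids)
    return ExpressionMatrix(data, samples, unit)


@pytest.fixture
def matrix_factory():
    return make_matrix
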