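import numpy as np
import pandas as pd
import pytest

from gmconcord.datamodel import AnalysisConfig, OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return AnalysisConfig()


def make_matrix(values, features=None, samples=None, dataset_id="DS01",
                omics_kind="metabolite", scale_state="linear"):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    df.index.name = "feature_id"
    return OmicsMatrix(dataset_id, omics_kind, df, scale_state)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]])
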