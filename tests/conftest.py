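import numpy as np
import pandas as pd
import pytest

from mvcotrain import FeatureTable, SyntheticConfig, generate


def make_table(X: np.ndarray, y01: np.ndarray, names=None, prefix="s") -> FeatureTable:
    """Build a FeatureTable from a numeric matrix and 0/1 labels (2 = unknown)."""
    names = names or [f"f{j}" for j in range(X.shape[1])]
    index = pd.Index([f"{prefix}{i:04d}" for i in range(len(X))])
    outcome = pd.Series(
        np.select([y01 == 1, y01 == 0], ["positive", "negative"], "unknown"), index=index
    )
    return FeatureTable(pd.DataFrame(X, columns=names, index=index), outcome)


@pytest.fixture(scope="session")
def accord_like():
    """Default-preset synthetic cohort: 151/1025 labeled + 9068 unlabeled."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture()
def separable_table():
    """Two well-separated Gaussian clusters, balanced, 2 features."""
    rng = np.random.default_rng(7)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 2)) * 0.3 + 4.0 * y[:, None]
    return make_table(X, y)
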