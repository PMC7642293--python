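import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """Deterministic 6-gene x 4-sample count matrix."""
    rng = np.random.default_rng(11)
    data = rng.integers(0, 500, size=(6, 4))
    return pd.DataFrame(
        data,
        index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
        columns=["s1", "s2", "s3", "s4"],
        dtype=np.int64,
    )


@pytest.fixture
def heteroscedastic_matrix() -> pd.DataFrame:
    """60 features x 6 samples with per-feature variances and a shifted block.

    Matches the fixture on which the frozen empirical-Bayes oracle values
    were computed with an independent reference implementation.
    """
    rng = np.random.default_rng(42)
    sds = np.exp(rng.normal(0, 0.6, size=60))
    y = rng.normal(0, 1, size=(60, 6)) * sds[:, None]
    y[:10, 3:] += 1.5
    y = np.round(y, 6)
    return pd.DataFrame(
        y, index=[f"f{i:03d}" for i in range(60)], columns=list("abcdef")
    )
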