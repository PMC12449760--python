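import numpy as np
import pandas as pd
import pytest

from paleonet import CountMatrix, SynthConfig


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        [[5, 0, 3], [1, 4, 0], [2, 2, 2], [0, 7, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["ta", "tb", "tc"],
    )
    return CountMatrix(counts)


@pytest.fixture
def core_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    n = 12
    counts = pd.DataFrame(
        rng.integers(0, 40, size=(n, 6)),
        index=[f"i{k}" for k in range(n)],
        columns=list("abcdef"),
    )
    counts.iloc[:, 0] += 5  # keep rows non-empty
    meta = pd.DataFrame(
        {
            "depth_cm": np.arange(n, dtype=float)[::-1] + 0.5,
            "age_ce": np.linspace(1760.0, 2015.0, n),
        },
        index=counts.index,
    )
    return CountMatrix(counts, meta)


@pytest.fixture
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture
def core_cfg() -> SynthConfig:
    return SynthConfig(n_taxa=20, n_samples=20, seed=0)
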