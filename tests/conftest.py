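import numpy as np
import pandas as pd
import pytest

from gbmscreen.io_formats import GeneExpressionMatrix, SurvivalTable


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(12)]
    return GeneExpressionMatrix(genes, samples, rng.poisson(50, (20, 12)).astype(float), "toy")


@pytest.fixture
def simple_survival():
    rng = np.random.default_rng(7)
    n = 12
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "time": rng.exponential(20, n) + 0.1,
                "event": rng.integers(0, 2, n),
            }
        ),
        endpoint="OS",
    )


def make_survival(ids, times, events, endpoint="OS"):
    return SurvivalTable(
        pd.DataFrame({"sample_id": list(ids), "time": times, "event": events}),
        endpoint=endpoint,
    )
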