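import numpy as np
import pandas as pd
import pytest

import scfa_micromap as sm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """3 samples x 2 features of counts, rows summing to 10."""
    frame = pd.DataFrame(
        [[7, 3], [5, 5], [1, 9]],
        index=["s1", "s2", "s3"],
        columns=["taxA", "taxB"],
        dtype=float,
    )
    return sm.AbundanceTable(frame, kind="counts")


def random_relative_table(rng, n, p, prefix="t"):
    raw = rng.lognormal(0.0, 1.0, size=(n, p))
    frame = pd.DataFrame(
        raw,
        index=[f"s{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(p)],
    )
    return sm.AbundanceTable(frame, kind="counts").to_relative()


@pytest.fixture
def default_cohort():
    return sm.generate_cohort(sm.GeneratorConfig(seed=11))


@pytest.fixture
def toy_gmm():
    return [
        sm.GMMDefinition("MF0001", "lactose degradation", frozenset({"K00001", "K00002", "K00003"})),
        sm.GMMDefinition("MF0002", "propionate production", frozenset({"K01026", "K01895", "K00925"})),
    ]
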