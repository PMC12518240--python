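import numpy as np
import pytest

from epheclass import AbundanceTable


@pytest.fixture(scope="session")
def recovery_results():
    """Consensus RFE at NSF=10 on 300x200 tables with 10 planted features,
    run once per session and shared between the unit and acceptance suites.

    Maps seed -> (n planted features recovered, consensus attainable?).
    """
    from epheclass import clr_transform, consensus_select, to_relative
    from epheclass.errors import ConsensusUnattainableError
    from epheclass.synthetic_fixtures import SyntheticConfig, generate

    out = {}
    for seed in range(5):
        cfg = SyntheticConfig(n_samples=300, n_features=200, n_informative=10,
                              effect=2.0, seed=seed)
        table, truth = generate(cfg)
        X = clr_transform(to_relative(table, 1)).values
        try:
            sel = consensus_select(X, table.labels, nsf=10, seed=seed)
        except ConsensusUnattainableError:
            out[seed] = (0, False)
            continue
        ids = [table.feature_ids[j] for j in sel.consensus]
        out[seed] = (len(set(ids) & set(truth)), True)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_table():
    """12 labelled samples x 6 features with both classes and two strata."""
    gen = np.random.default_rng(1)
    counts = gen.integers(0, 500, size=(12, 6))
    return AbundanceTable(
        sample_ids=[f"S{i}" for i in range(12)],
        feature_ids=[f"F{j}" for j in range(6)],
        counts=counts,
        labels=np.array(["D"] * 5 + ["NotD"] * 7, dtype=object),
        stratum=np.array(["a", "b"] * 6, dtype=object),
    )
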