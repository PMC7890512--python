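import numpy as np
import pandas as pd
import pytest

from polyethnet import BipartiteNetwork, SyntheticColonyConfig, generate_colony


def make_records(rows) -> pd.DataFrame:
    """Observation table from (ant_id, day, slot, behaviour) tuples."""
    return pd.DataFrame(
        [("col1", *r) for r in rows],
        columns=["colony_id", "ant_id", "day", "slot", "behaviour"],
    )


@pytest.fixture
def block_net() -> BipartiteNetwork:
    """Perfectly block-diagonal 4x4 network with two planted modules."""
    A = np.array([[3, 3, 0, 0], [3, 3, 0, 0], [0, 0, 3, 3], [0, 0, 3, 3]])
    return BipartiteNetwork(
        A=A, row_labels=["a", "b", "c", "d"], col_labels=["w", "x", "y", "z"]
    )


@pytest.fixture
def diag_net() -> BipartiteNetwork:
    return BipartiteNetwork(
        A=np.array([[2, 0], [0, 2]]), row_labels=["a", "b"], col_labels=["x", "y"]
    )


def random_net(rng, shape=(5, 6), high=6) -> BipartiteNetwork:
    """Random pruned integer network (rejects empty rows/columns)."""
    while True:
        A = rng.integers(0, high, shape)
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return BipartiteNetwork(
                A=A,
                row_labels=[f"r{i}" for i in range(shape[0])],
                col_labels=[f"c{j}" for j in range(shape[1])],
            )


#: Near-degenerate 3-role configuration: each role puts >=0.92 of its mass on
#: its signature behaviour, so the planted partition is recoverable.
THREE_ROLE_CONFIG = dict(
    n_ants=40,
    role_mix={"nurse": 1 / 3, "forager": 1 / 3, "inactive_specialist": 1 / 3},
    propensity_matrix={
        "nurse": {
            "larva_care": 0.92, "egg_care": 0.02, "pupa_care": 0.02,
            "walking": 0.02, "inactive": 0.01, "foraging": 0.01,
        },
        "forager": {
            "foraging": 0.92, "walking": 0.03, "inactive": 0.03,
            "egg_care": 0.0, "larva_care": 0.01, "pupa_care": 0.01,
        },
        "inactive_specialist": {
            "inactive": 0.92, "walking": 0.04, "foraging": 0.02,
            "egg_care": 0.0, "larva_care": 0.01, "pupa_care": 0.01,
        },
    },
    age_coupling=0.0,
)


@pytest.fixture
def small_colony():
    return generate_colony(SyntheticColonyConfig(n_ants=30, seed=42))
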