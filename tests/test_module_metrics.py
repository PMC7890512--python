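import numpy as np
import pandas as pd
import pytest

from polyethnet import (
    BipartiteNetwork,
    Partition,
    c_scores,
    d_prime,
    module_network,
    score_correlation,
    specialization_scores,
)

from conftest import random_net
from oracles import exhaustive_d_extremes
from polyethnet.module_metrics import _dmin_allocation


class TestModuleNetwork:
    def test_block_diagonal_has_zero_cross_module_weight(self, block_net):
        part = Partition(row_modules=[1, 1, 2, 2], col_modules=[1, 1, 2, 2])
        q = module_network(block_net, part).q
        assert q[0, 1] == 0 and q[1, 0] == 0
        assert q[0, 0] == pytest.approx(6.0)  # each ant sends 6 into its block

    def test_single_individual_module_mean_is_its_total(self):
        A = np.array([[5, 0], [0, 4]])
        net = BipartiteNetwork(A=A, row_labels=["a", "b"], col_labels=["x", "y"])
        part = Partition(row_modules=[1, 2], col_modules=[2, 2])
        q = module_network(net, part).q
        assert q[0, 1] == pytest.approx(5.0)  # sole ant of module 1 into module 2

    def test_mean_over_two_individuals(self):
        # ants a,b in module 1 send totals 4 and 2 into module 2's behaviours
        A = np.array([[1, 3, 1], [0, 1, 1]])
        net = BipartiteNetwork(A=A, row_labels=["a", "b"], col_labels=["x", "y", "z"])
        part = Partition(row_modules=[1, 1], col_modules=[1, 2, 2])
        q = module_network(net, part).q
        assert q[0, 1] == pytest.approx(3.0)

    def test_weight_accounting_identity(self):
        rng = np.random.default_rng(2)
        net = random_net(rng, shape=(6, 7))
        # every module label 1..3 appears among the rows by construction
        row_mods = rng.permutation([1, 2, 3] + list(rng.integers(1, 4, net.r - 3)))
        part = Partition(row_modules=row_mods, col_modules=rng.integers(1, 4, net.s))
        mn = module_network(net, part)
        for i in range(part.n_modules):
            rows = part.row_modules == i + 1
            emitted = net.A[rows].sum()
            assert mn.q[i].sum() * rows.sum() == pytest.approx(emitted)

    def test_module_without_individuals_gets_nan_row(self, block_net):
        part = Partition(row_modules=[1, 1, 1, 1], col_modules=[1, 1, 2, 2])
        q = module_network(block_net, part).q
        assert np.isnan(q[1]).all()  # behaviour-only module: no emitting ants
        assert np.isfinite(q[0]).all()
        with pytest.raises(ValueError, match="no individuals"):
            module_network(block_net, part, require_individuals=True)


class TestCScores:
    def test_own_module_specialist_scores_zero(self, block_net):
        part = Partition(row_modules=[1, 1, 2, 2], col_modules=[1, 1, 2, 2])
        assert (c_scores(block_net, part)["c_score"] == 0.0).all()

    def test_even_spread_over_three_modules_is_two_thirds(self):
        A = np.array([[2, 2, 2]])
        net = BipartiteNetwork(A=A, row_labels=["a"], col_labels=["x", "y", "z"])
        part = Partition(row_modules=[1], col_modules=[1, 2, 3])
        c = c_scores(net, part)["c_score"].iloc[0]
        assert c == pytest.approx(2 / 3)

    def test_single_module_gives_zero_for_everyone(self, block_net):
        part = Partition(row_modules=[1] * 4, col_modules=[1] * 4)
        assert (c_scores(block_net, part)["c_score"] == 0.0).all()

    def test_bound_attained_only_by_exactly_even_spread(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net = random_net(rng, shape=(5, 6))
            part = Partition(
                row_modules=rng.integers(1, 4, 5), col_modules=np.array([1, 1, 2, 2, 3, 3])
            )
            df = c_scores(net, part)
            n_m = part.n_modules
            bound = 1 - 1 / n_m
            assert ((df["c_score"] >= -1e-12) & (df["c_score"] <= bound + 1e-12)).all()
            d_cols = [f"d_to_module_{m}" for m in range(1, n_m + 1)]
            for _, row in df.iterrows():
                even = np.allclose(row[d_cols].astype(float), row["d_i"] / n_m)
                at_bound = np.isclose(row["c_score"], bound)
                assert even == at_bound


class TestDPrime:
    def test_usage_matching_availability_is_zero(self):
        # each row's proportions equal the overall column availability
        A = np.array([[2, 4, 2], [1, 2, 1]])
        net = BipartiteNetwork(A=A, row_labels=["a", "b"], col_labels=["x", "y", "z"])
        df = d_prime(net)
        assert df["d_raw"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert (df["d_prime"] == 0.0).all()

    def test_sole_user_of_exclusive_behaviour_is_perfect_specialist(self):
        A = np.array([[5, 0, 0], [0, 3, 2], [0, 2, 3]])
        net = BipartiteNetwork(A=A, row_labels=["a", "b", "c"], col_labels=["x", "y", "z"])
        assert d_prime(net).loc["a", "d_prime"] == pytest.approx(1.0)

    def test_values_always_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_net(rng, shape=(5, 5))
            dp = d_prime(net)["d_prime"]
            assert ((dp >= 0) & (dp <= 1)).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_extremes_match_exhaustive_allocation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, shape=(3, 3), high=4)
        z = net.z.astype(float)
        M = float(net.M)
        for i in range(net.r):
            y = int(net.A[i].sum())
            z_others = z - net.A[i]
            dmin_ex, dmax_ex = exhaustive_d_extremes(y, z_others, M)
            assert _dmin_allocation(y, z_others, M) == pytest.approx(dmin_ex, abs=1e-9)
            assert np.log(M / (z_others.min() + y)) == pytest.approx(dmax_ex, abs=1e-9)

    def test_single_column_network_defined_as_zero(self):
        net = BipartiteNetwork(A=np.array([[3], [2]]), row_labels=["a", "b"], col_labels=["x"])
        assert (d_prime(net)["d_prime"] == 0.0).all()


def test_module_specialist_need_not_be_information_specialist():
    """c = 0 (works only inside its module) does not imply d' = 1: two ants
    sharing a two-behaviour module are module-specialists but not exclusive."""
    A = np.array([[3, 3, 0, 0], [3, 3, 0, 0], [0, 0, 3, 3], [0, 0, 3, 3]])
    net = BipartiteNetwork(
        A=A, row_labels=["a", "b", "c", "d"], col_labels=["w", "x", "y", "z"]
    )
    part = Partition(row_modules=[1, 1, 2, 2], col_modules=[1, 1, 2, 2])
    scores = specialization_scores(net, part)
    assert scores.loc["a", "c_score"] == 0.0
    assert scores.loc["a", "d_prime"] < 1.0


class TestScoreCorrelation:
    def test_exact_anticorrelation(self):
        c = np.linspace(0, 0.6, 20)
        df = pd.DataFrame({"c_score": c, "d_prime": 1 - c})
        r, p = score_correlation(df)
        assert r == pytest.approx(-1.0)

    def test_independent_scores_are_uncorrelated(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"c_score": rng.random(1000), "d_prime": rng.random(1000)}
        )
        r, _ = score_correlation(df)
        assert abs(r) < 0.1

    def test_pooling_multiple_colonies(self):
        rng = np.random.default_rng(9)
        frames = [
            pd.DataFrame({"c_score": rng.random(10), "d_prime": rng.random(10)})
            for _ in range(3)
        ]
        r, p = score_correlation(frames)
        assert -1 <= r <= 1 and 0 <= p <= 1

    def test_constant_vector_rejected(self):
        df = pd.DataFrame({"c_score": [0.1] * 5, "d_prime": np.linspace(0, 1, 5)})
        with pytest.raises(ValueError, match="constant"):
            score_correlation(df)
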