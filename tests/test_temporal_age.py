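import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyethnet import (
    DEFAULT_PERIOD_MAP,
    Partition,
    age_module_comparison,
    age_regression,
    behaviour_proportions,
    build_network,
    compact_letter_display,
    maximize_modularity,
    period_mixing,
    split_by_period,
    steel_dwass,
)
from polyethnet.temporal_age import DAYTIME_SLOTS, NIGHTTIME_SLOTS

from conftest import make_records


ALL_SLOTS = (0, 3, 6, 9, 12, 15, 18, 21)


class TestSplitByPeriod:
    def test_interval_assignment(self):
        records = make_records([("w1", 1, 12, "walking"), ("w1", 1, 3, "inactive")])
        out = split_by_period(records)
        assert list(out["period"]) == ["daytime", "nighttime"]

    def test_record_count_conserved_and_four_scans_per_period(self):
        records = make_records([("w1", 1, s, "walking") for s in ALL_SLOTS])
        out = split_by_period(records)
        assert len(out) == len(records)
        assert out["period"].value_counts().to_dict() == {"daytime": 4, "nighttime": 4}

    def test_period_map_must_cover_all_slots(self):
        with pytest.raises(ValueError, match="missing"):
            split_by_period(make_records([("w1", 1, 0, "walking")]), {0: "daytime"})

    def test_default_map_matches_published_intervals(self):
        assert {s for s, p in DEFAULT_PERIOD_MAP.items() if p == "daytime"} == set(DAYTIME_SLOTS)
        assert {s for s, p in DEFAULT_PERIOD_MAP.items() if p == "nighttime"} == set(NIGHTTIME_SLOTS)


class TestPeriodMixing:
    def test_single_module_partition_trivially_mixed(self):
        records = make_records(
            [("w1", 1, s, "walking") for s in ALL_SLOTS]
            + [("w2", 1, s, "foraging") for s in ALL_SLOTS]
        )
        net = build_network(records, column_scheme="behaviour_by_period",
                            period_map=DEFAULT_PERIOD_MAP)
        part = Partition(row_modules=[1, 1], col_modules=[1] * net.s)
        res = period_mixing(net, part)
        assert res.mixed_module_fraction == 1.0

    def test_disjoint_day_and_night_populations_do_not_mix(self):
        # day-ants forage only in daytime; night-ants nurse only at night
        rows = []
        for k in range(6):
            rows += [(f"day{k}", d, s, "foraging") for d in (1, 2, 3) for s in DAYTIME_SLOTS]
            rows += [(f"night{k}", d, s, "larva_care") for d in (1, 2, 3) for s in NIGHTTIME_SLOTS]
        net = build_network(make_records(rows), column_scheme="behaviour_by_period",
                            period_map=DEFAULT_PERIOD_MAP)
        res_mod = maximize_modularity(net, n_restarts=10, seed=0)
        res = period_mixing(net, res_mod.partition)
        assert res.mixed_module_fraction == 0.0
        # both behaviours occur in a single period, so the indicator excludes them
        assert set(res.excluded) == {"foraging", "larva_care"}

    def test_wrong_scheme_rejected(self):
        records = make_records([("w1", 1, 0, "walking"), ("w2", 1, 0, "foraging")])
        net = build_network(records)
        part = Partition(row_modules=[1, 2], col_modules=[1, 2])
        with pytest.raises(ValueError, match="behaviour_by_period"):
            period_mixing(net, part)


class TestBehaviourProportions:
    def test_basic_arithmetic(self):
        rows = [("w1", d, s, "inactive") for d, s in
                [(1, 0), (1, 3), (1, 6), (2, 0), (2, 3), (3, 0)]]
        rows += [("w1", d, s, "walking") for d in (1, 2, 3) for s in (9, 12, 15, 18, 21)]
        rows += [("w1", 2, 6, "walking"), ("w1", 3, 3, "walking"), ("w1", 3, 6, "walking")]
        records = make_records(rows)  # 24 scans, 6 inactive
        props = behaviour_proportions(records)
        assert props.loc["w1", "n_scans"] == 24
        assert props.loc["w1", "inactive"] == pytest.approx(0.25)

    def test_denominator_is_observed_scans(self):
        rows = [("w1", 1, s, "foraging") for s in (0, 3, 6, 9, 12)]
        rows += [("w1", 2, s, "walking") for s in ALL_SLOTS[:8]]
        rows += [("w1", 3, s, "walking") for s in ALL_SLOTS[:7]]
        records = make_records(rows)  # 20 scans, 5 foraging
        props = behaviour_proportions(records)
        assert props.loc["w1", "n_scans"] == 20
        assert props.loc["w1", "foraging"] == pytest.approx(0.25)

    def test_proportions_sum_to_one_per_ant(self, small_colony):
        props = behaviour_proportions(small_colony.records)
        sums = props.drop(columns="n_scans").sum(axis=1)
        assert np.allclose(sums, 1.0)


class TestAgeRegression:
    def test_exact_linear_data_recovered_perfectly(self):
        ages = pd.Series(np.arange(10, dtype=float) * 30, index=[f"w{i}" for i in range(10)])
        props = pd.DataFrame(
            {"foraging": 0.001 * ages + 0.1, "n_scans": 24}, index=ages.index
        )
        res = age_regression(props, ages, "foraging")
        assert res.slope == pytest.approx(0.001)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_aged_ants_rejected(self):
        ages = pd.Series([1.0, 2.0], index=["w0", "w1"])
        props = pd.DataFrame({"foraging": [0.1, 0.2], "n_scans": 24}, index=ages.index)
        with pytest.raises(ValueError):
            age_regression(props, ages, "foraging")

    def test_missing_ages_dropped(self):
        idx = [f"w{i}" for i in range(6)]
        ages = pd.Series([10, 20, np.nan, 40, 50, np.nan], index=idx, dtype=float)
        props = pd.DataFrame({"foraging": np.linspace(0, 1, 6), "n_scans": 24}, index=idx)
        assert age_regression(props, ages, "foraging").n == 4


class TestSteelDwass:
    def test_identical_distributions_share_one_letter(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 10, 30)
        groups = {m: vals.copy() for m in (1, 2, 3)}
        table = steel_dwass(groups, seed=0)
        assert (table["p_value"] > 0.05).all()
        letters = compact_letter_display(table, [1, 2, 3])
        assert len({letters[m] for m in (1, 2, 3)}) == 1

    def test_well_separated_modules_detected(self):
        rng = np.random.default_rng(1)
        groups = {
            "young": rng.uniform(0, 30, 15),
            "old": rng.uniform(200, 300, 15),
        }
        table = steel_dwass(groups, seed=1)
        assert (table["p_value"] < 0.05).all()
        # permutation route agrees on the rejection
        table_p = steel_dwass(groups, method="permutation", n_perm=2000, seed=1)
        assert (table_p["p_value"] < 0.05).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_two_groups_match_rank_sum_decision(self, seed):
        """With exactly two modules the all-pairs test reduces to a two-sample
        rank-sum comparison: the alpha=0.05 decision must agree."""
        rng = np.random.default_rng(seed)
        shift = rng.uniform(0, 15)
        x = rng.normal(0, 10, 20)
        y = rng.normal(shift, 10, 20)
        table = steel_dwass({"a": x, "b": y})
        mwu = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert (table["p_value"].iloc[0] < 0.05) == (mwu.pvalue < 0.05)

    def test_small_groups_use_permutation_reference(self):
        rng = np.random.default_rng(2)
        groups = {1: rng.normal(0, 1, 5), 2: rng.normal(0, 1, 5), 3: rng.normal(3, 1, 20)}
        table = steel_dwass(groups, seed=3, n_perm=500)
        assert (table.loc[table["group_a"] == 1, "method"] == "permutation").all()


def test_letter_display_is_valid_clique_cover():
    """Groups share a letter iff their pair is not significant."""
    rng = np.random.default_rng(4)
    groups = list(range(5))
    import itertools

    for _ in range(10):
        rows = [
            (a, b, 0.0, rng.choice([0.001, 0.5]), "x")
            for a, b in itertools.combinations(groups, 2)
        ]
        table = pd.DataFrame(
            rows, columns=["group_a", "group_b", "statistic", "p_value", "method"]
        )
        letters = compact_letter_display(table, groups)
        for row in table.itertuples(index=False):
            shared = set(letters[row.group_a]) & set(letters[row.group_b])
            if row.p_value < 0.05:
                assert not shared
            else:
                assert shared


class TestAgeModuleComparison:
    def test_separated_ages_yield_distinct_letters(self):
        rng = np.random.default_rng(5)
        ants = [f"w{i}" for i in range(30)]
        ages = pd.Series(
            np.concatenate([rng.uniform(0, 30, 15), rng.uniform(200, 300, 15)]),
            index=ants,
        )
        part = pd.Series([1] * 15 + [2] * 15, index=ants)
        res = age_module_comparison(ages, part, seed=0)
        assert (res.pairwise["p_value"] < 0.05).all()
        assert res.letters[1] != res.letters[2]

    def test_small_modules_dropped_and_reported(self):
        ants = [f"w{i}" for i in range(11)]
        ages = pd.Series(np.linspace(0, 300, 11), index=ants)
        part = pd.Series([1] * 5 + [2] * 5 + [3], index=ants)
        res = age_module_comparison(ages, part, seed=0)
        assert res.dropped == [3]
        assert set(res.letters) == {1, 2}

    def test_needs_two_usable_modules(self):
        ants = ["w0", "w1", "w2"]
        ages = pd.Series([1.0, 2.0, 3.0], index=ants)
        part = pd.Series([1, 1, 2], index=ants)
        with pytest.raises(ValueError):
            age_module_comparison(ages, part)


def test_planted_polyethism_orders_module_median_ages():
    """With strong age coupling the forage-dominated module is older than the
    brood-care-dominated module."""
    from polyethnet import SyntheticColonyConfig, generate_colony

    cfg = SyntheticColonyConfig(n_ants=80, age_coupling=3.0, seed=6)
    colony = generate_colony(cfg)
    net = build_network(colony.records)
    res = maximize_modularity(net, n_restarts=10, seed=6)
    ages = colony.metadata.set_index("ant_id")["age_days"]

    def module_of(behaviour):
        weights = {}
        for j, lab in enumerate(net.col_labels):
            if lab.startswith(behaviour + "|"):
                m = res.partition.col_modules[j]
                weights[m] = weights.get(m, 0) + net.z[j]
        return max(weights, key=weights.get)

    forage_mod = module_of("foraging")
    brood_mod = module_of("larva_care")
    assert forage_mod != brood_mod
    med = {
        m: ages.loc[[a for a, g in zip(net.row_labels, res.partition.row_modules) if g == m]].median()
        for m in (forage_mod, brood_mod)
    }
    assert med[forage_mod] > med[brood_mod]
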