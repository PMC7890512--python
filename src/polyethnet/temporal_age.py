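"""Day/night partition analysis and age polyethism analyses.

Two biological questions sit here: (1) do task groups track time of day?
The scan data are split into daytime (09:00-18:00 scans) and nighttime
(21:00-06:00 scans), a behaviour x period bipartite network is built, and we
ask whether each behaviour's daytime and nighttime nodes land in the same
module ("mixing" indicates no daily rhythm in task allocation). (2) does task
change with age? Module membership is compared against age with the
Steel-Dwass all-pairs nonparametric test (compact letter display at alpha),
and per-behaviour execution proportions are regressed on age with OLS
(positive foraging slopes and negative brood-care/inactive slopes are the
classic age-polyethism signature).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .community import Partition
from .io_network import BEHAVIOURS, SLOTS, BipartiteNetwork, validate_observations

DAYTIME_SLOTS: frozenset[int] = frozenset({9, 12, 15, 18})
NIGHTTIME_SLOTS: frozenset[int] = frozenset({21, 0, 3, 6})

#: Default slot -> period map: daytime 9:00-18:00, nighttime 21:00-6:00.
DEFAULT_PERIOD_MAP: dict[int, str] = {
    **{s: "daytime" for s in DAYTIME_SLOTS},
    **{s: "nighttime" for s in NIGHTTIME_SLOTS},
}


def split_by_period(
    records: pd.DataFrame, period_map: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Annotate each record with its day/night period (record count conserved)."""
    period_map = dict(period_map or DEFAULT_PERIOD_MAP)
    missing = sorted(set(SLOTS) - set(period_map))
    if missing:
        raise ValueError(f"period_map must cover all slots; missing {missing}")
    records = validate_observations(records)
    out = records.copy()
    out["period"] = out["slot"].map(period_map)
    return out


@dataclass
class PeriodMixing:
    """Day/night co-modularity of behaviours on a behaviour x period network."""

    co_modular: dict[str, bool]  # behaviour -> day & night nodes share a module
    mixed_module_fraction: float  # fraction of behaviour-bearing modules with both periods
    excluded: list[str] = field(default_factory=list)  # behaviours seen in one period only


def period_mixing(net: BipartiteNetwork, partition: Partition) -> PeriodMixing:
    """Assess whether detected modules mix daytime and nighttime behaviour-nodes."""
    if net.scheme != "behaviour_by_period":
        raise ValueError("period_mixing needs a behaviour_by_period network")
    if len(partition.col_modules) != net.s:
        raise ValueError("partition does not match network")
    node_info = [
        (net.column_behaviour(j), net.column_scope(j), partition.col_modules[j])
        for j in range(net.s)
    ]
    co_modular: dict[str, bool] = {}
    excluded: list[str] = []
    for b in BEHAVIOURS:
        modules_by_period: dict[str, set[int]] = {}
        for beh, period, mod in node_info:
            if beh == b:
                modules_by_period.setdefault(period, set()).add(int(mod))
        if not modules_by_period:
            continue
        if len(modules_by_period) < 2:
            excluded.append(b)
            continue
        day_mods, night_mods = modules_by_period.values()
        co_modular[b] = bool(day_mods & night_mods)

    module_periods: dict[int, set[str]] = {}
    for _, period, mod in node_info:
        module_periods.setdefault(int(mod), set()).add(period)
    n_both = sum(1 for periods in module_periods.values() if len(periods) == 2)
    fraction = n_both / len(module_periods) if module_periods else float("nan")
    # a single module trivially mixes everything it contains
    if len(module_periods) == 1:
        fraction = 1.0
    return PeriodMixing(
        co_modular=co_modular, mixed_module_fraction=fraction, excluded=excluded
    )


def behaviour_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-ant proportion of scans spent in each behaviour.

    Denominator is the number of scans actually observed for that ant (24 for
    a complete 3-day record). Proportions sum to 1 per ant. Ants with zero
    scans cannot appear in a record table, so none are dropped here; callers
    merging with metadata should treat absent ants as unobserved.
    """
    records = validate_observations(records)
    counts = (
        records.groupby(["ant_id", "behaviour"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(BEHAVIOURS), fill_value=0)
    )
    n_scans = counts.sum(axis=1)
    props = counts.div(n_scans, axis=0)
    props["n_scans"] = n_scans
    return props


@dataclass
class RegressionResult:
    slope: float  # change in proportion per day of age
    intercept: float
    r_squared: float
    p_value: float
    n: int
    conf_int: tuple[float, float]  # 95% CI of the slope


def age_regression(
    proportions: pd.DataFrame,
    ages: pd.Series,
    behaviour: str,
) -> RegressionResult:
    """OLS of a behaviour's per-ant proportion on age in days."""
    if behaviour not in proportions.columns:
        raise ValueError(f"unknown behaviour {behaviour!r}")
    ages = pd.to_numeric(ages, errors="coerce")
    joined = proportions[[behaviour]].join(ages.rename("age_days"), how="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 ants with known age")
    x = joined["age_days"].to_numpy(dtype=float)
    y = joined[behaviour].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    # 95% CI for the slope from the t distribution
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
        conf_int=(float(ci[0]), float(ci[1])),
    )


# -- Steel-Dwass all-pairs comparison ---------------------------------------


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one group pair."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    expect = n1 * (n + 1) / 2.0
    var = n1 * n2 / (n * (n - 1.0)) * ((ranks**2).sum() - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((w - expect) / math.sqrt(var))


def steel_dwass(
    values: Mapping[int | str, np.ndarray] | pd.Series,
    groups: pd.Series | None = None,
    method: str = "auto",
    n_perm: int = 10_000,
    min_n_asymptotic: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """All-pairs Steel-Dwass comparisons.

    Each pair's tie-corrected rank statistic ``t`` is referred to the
    studentized range distribution via ``q = sqrt(2)*|t|`` with the total
    number of groups as the range parameter (large-df reference), which
    controls the family-wise error across all pairs. For small groups
    (either side below ``min_n_asymptotic``; or ``method='permutation'``)
    the reference is a seeded permutation distribution of ``q`` instead.

    Returns a DataFrame with columns group_a, group_b, statistic, p_value,
    method.
    """
    if isinstance(values, pd.Series):
        if groups is None:
            raise ValueError("groups required when values is a Series")
        data = {
            g: values[groups == g].dropna().to_numpy(dtype=float)
            for g in pd.unique(groups)
        }
    else:
        data = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    data = {g: v for g, v in data.items() if len(v) > 0}
    k = len(data)
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    labels = sorted(data, key=str)
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x, y = data[a], data[b]
        t = _pair_statistic(x, y)
        q = math.sqrt(2.0) * abs(t)
        use_perm = method == "permutation" or (
            method == "auto" and min(len(x), len(y)) < min_n_asymptotic
        )
        if use_perm:
            pooled = np.concatenate([x, y])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                t_p = _pair_statistic(perm[: len(x)], perm[len(x):])
                if math.sqrt(2.0) * abs(t_p) >= q - 1e-12:
                    count += 1
            p = (1 + count) / (1 + n_perm)
            how = "permutation"
        else:
            p = float(stats.studentized_range.sf(q, k, 1e6))
            how = "studentized-range"
        rows.append((a, b, t, p, how))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "statistic", "p_value", "method"]
    )


def compact_letter_display(
    pairs: pd.DataFrame, groups: list, alpha: float = 0.05
) -> dict:
    """Letters such that two groups share a letter iff their pair is not significant.

    Greedy clique cover of the non-significant-pair graph; isolated groups get
    their own letter.
    """
    sig = {
        frozenset((row.group_a, row.group_b)): row.p_value < alpha
        for row in pairs.itertuples(index=False)
    }

    def compatible(a, b) -> bool:
        return not sig.get(frozenset((a, b)), False)

    cliques: list[list] = []
    for a, b in itertools.combinations(groups, 2):
        if not compatible(a, b):
            continue
        if any(a in c and b in c for c in cliques):
            continue
        clique = [a, b]
        for g in groups:
            if g not in clique and all(compatible(g, m) for m in clique):
                clique.append(g)
        cliques.append(clique)
    for g in groups:
        if not any(g in c for c in cliques):
            cliques.append([g])
    letters = {g: "" for g in groups}
    for letter_idx, clique in enumerate(cliques):
        letter = chr(ord("a") + letter_idx) if letter_idx < 26 else f"z{letter_idx}"
        for g in groups:
            if g in clique:
                letters[g] += letter
    return letters


@dataclass
class AgeAnalysisResult:
    """Module-wise age distributions, all-pairs tests and letter display."""

    group_values: dict  # module -> ages used
    pairwise: pd.DataFrame  # Steel-Dwass table
    letters: dict  # module -> compact letters
    dropped: list = field(default_factory=list)  # modules with <2 usable values
    alpha: float = 0.05


def age_module_comparison(
    ages: pd.Series,
    partition: pd.Series | Mapping[str, int],
    alpha: float = 0.05,
    value_name: str = "age",
    seed: int | None = None,
    method: str = "auto",
) -> AgeAnalysisResult:
    """Compare ages (or any per-ant value, e.g. c-scores) among modules.

    ``ages`` is indexed by ant_id; ``partition`` maps ant_id -> module label.
    Modules with fewer than 2 usable values are dropped and reported.
    """
    if not isinstance(partition, pd.Series):
        partition = pd.Series(dict(partition))
    df = pd.DataFrame({"value": pd.to_numeric(ages, errors="coerce")}).join(
        partition.rename("module"), how="inner"
    ).dropna()
    groups = {}
    dropped = []
    for mod, sub in df.groupby("module"):
        vals = sub["value"].to_numpy(dtype=float)
        if len(vals) >= 2:
            groups[mod] = vals
        else:
            dropped.append(mod)
    if len(groups) < 2:
        raise ValueError("need at least 2 modules with >= 2 valued individuals")
    pairwise = steel_dwass(groups, seed=seed, method=method)
    letters = compact_letter_display(pairwise, sorted(groups, key=str), alpha=alpha)
    return AgeAnalysisResult(
        group_values=groups,
        pairwise=pairwise,
        letters=letters,
        dropped=dropped,
        alpha=alpha,
    )
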