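"""Module-level network (q_ij) and individual specialization (c-score, d').

Once modules (task groups) are detected, two complementary individual metrics
describe specialization:

* the c-score, an among-module connectivity: c_i = 1 - sum_j (d_ij / d_i)^2,
  where d_ij is i's weight into module j's behaviour-nodes and d_i its total
  weight. c_i = 0 means the individual works only inside one module;
  the maximum 1 - 1/N_M means its weight is spread evenly over all modules.
* d' (standardized Kullback-Leibler specialization), which ignores modules and
  compares an individual's behaviour-use proportions with overall behaviour
  availability, rescaled between the most-even and most-exclusive integer
  allocations attainable for its total weight. 0 = opportunistic, 1 = perfect
  specialist.

The module network summarizes flows between task groups: q_ij is the mean
weight per individual of module i into the behaviour-nodes of module j
(q_ii is the self-loop — the task group's own specialization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import Partition
from .io_network import BipartiteNetwork


@dataclass
class ModuleNetwork:
    """q: N_M x N_M mean-weight matrix among modules, plus module membership."""

    q: np.ndarray
    module_sizes: np.ndarray  # individuals per module
    behaviour_members: dict[int, list[str]]  # module -> behaviour-node labels


def module_network(
    net: BipartiteNetwork,
    partition: Partition,
    require_individuals: bool = False,
) -> ModuleNetwork:
    """Mean per-individual weight q_ij from module i's ants to module j's behaviours.

    A module may contain only behaviour-nodes (it can still receive weight);
    its own q row is then undefined and filled with NaN. With
    ``require_individuals`` such modules raise instead.
    """
    if len(partition.row_modules) != net.r or len(partition.col_modules) != net.s:
        raise ValueError("partition does not match network")
    n_m = partition.n_modules
    sizes = np.array(
        [np.count_nonzero(partition.row_modules == m) for m in range(1, n_m + 1)]
    )
    if require_individuals and (sizes == 0).any():
        empty = [int(m) + 1 for m in np.flatnonzero(sizes == 0)]
        raise ValueError(f"module(s) {empty} contain no individuals; q undefined")
    q = np.full((n_m, n_m), np.nan)
    for i in range(n_m):
        if sizes[i] == 0:
            continue
        rows = partition.row_modules == i + 1
        for j in range(n_m):
            cols = partition.col_modules == j + 1
            q[i, j] = net.A[np.ix_(rows, cols)].sum() / sizes[i]
    members = {
        m: [net.col_labels[j] for j in np.flatnonzero(partition.col_modules == m)]
        for m in range(1, n_m + 1)
    }
    return ModuleNetwork(q=q, module_sizes=sizes, behaviour_members=members)


def c_scores(net: BipartiteNetwork, partition: Partition) -> pd.DataFrame:
    """Among-module connectivity c_i = 1 - sum_j (d_ij/d_i)^2 per individual.

    Returns a DataFrame indexed by ant_id with columns ``module``, ``d_i``,
    ``c_score`` and one ``d_to_module_<j>`` column per module.
    """
    if len(partition.row_modules) != net.r or len(partition.col_modules) != net.s:
        raise ValueError("partition does not match network")
    n_m = partition.n_modules
    d_ij = np.stack(
        [net.A[:, partition.col_modules == m].sum(axis=1) for m in range(1, n_m + 1)],
        axis=1,
    ).astype(float)
    d_i = d_ij.sum(axis=1)
    if (d_i == 0).any():
        bad = [net.row_labels[i] for i in np.flatnonzero(d_i == 0)]
        raise ValueError(f"individual(s) with zero total weight: {bad}; prune first")
    c = 1.0 - ((d_ij / d_i[:, None]) ** 2).sum(axis=1)
    out = pd.DataFrame(
        {
            "module": partition.row_modules,
            "d_i": d_i,
            "c_score": c,
        },
        index=pd.Index(net.row_labels, name="ant_id"),
    )
    for m in range(1, n_m + 1):
        out[f"d_to_module_{m}"] = d_ij[:, m - 1]
    return out


# -- d' (standardized specialization) ---------------------------------------


def _d_of_allocation(a: np.ndarray, z_others: np.ndarray, M: float) -> float:
    """Kullback-Leibler d of one row's integer allocation, availabilities recomputed."""
    y = a.sum()
    nz = a > 0
    p = a[nz] / y
    q = (z_others[nz] + a[nz]) / M
    return float((p * np.log(p / q)).sum())


def _dmin_allocation(y: int, z_others: np.ndarray, M: float) -> float:
    """Most-even attainable integer allocation (largest-remainder + local moves)."""
    s = len(z_others)
    if z_others.sum() == 0:
        return 0.0
    target = y * z_others / z_others.sum()
    a = np.floor(target).astype(int)
    remainder = target - a
    for j in np.argsort(-remainder)[: y - a.sum()]:
        a[j] += 1
    best = _d_of_allocation(a, z_others, M)
    improved = True
    while improved:  # single-unit moves until no decrease
        improved = False
        donors = np.flatnonzero(a > 0)
        for j in donors:
            for k in range(s):
                if k == j:
                    continue
                a[j] -= 1
                a[k] += 1
                d = _d_of_allocation(a, z_others, M)
                if d < best - 1e-12:
                    best = d
                    improved = True
                else:
                    a[j] += 1
                    a[k] -= 1
    return best


def d_prime(net: BipartiteNetwork) -> pd.DataFrame:
    """Standardized specialization d' per individual (0 opportunist .. 1 specialist).

    Raw d_i = sum_j p_ij ln(p_ij / q_j) with p_ij = A_ij/y_i and q_j = z_j/M.
    d_max concentrates the row's weight on the column least used by others;
    d_min spreads it as evenly as availability allows (integer allocations,
    availabilities recomputed under the reallocation). d' = (d - d_min) /
    (d_max - d_min), clipped to [0, 1]; 0 when the range degenerates (e.g. a
    single-column network).
    """
    A = net.A.astype(int)
    M = float(net.M)
    z = net.z.astype(float)
    rows = []
    for i, ant in enumerate(net.row_labels):
        a_obs = A[i]
        y = int(a_obs.sum())
        if y == 0:
            raise ValueError(f"individual {ant!r} has zero total weight; prune first")
        z_others = z - a_obs
        d_obs = _d_of_allocation(a_obs, z_others, M)
        if net.s < 2:
            rows.append((ant, y, d_obs, 0.0))
            continue
        d_max = float(np.log(M / (z_others.min() + y)))
        d_min = _dmin_allocation(y, z_others, M)
        if d_max - d_min < 1e-12:
            dp = 0.0
        else:
            dp = float(np.clip((d_obs - d_min) / (d_max - d_min), 0.0, 1.0))
        rows.append((ant, y, d_obs, dp))
    return pd.DataFrame(
        rows, columns=["ant_id", "d_i", "d_raw", "d_prime"]
    ).set_index("ant_id")


def specialization_scores(net: BipartiteNetwork, partition: Partition) -> pd.DataFrame:
    """Joined per-individual table: module, d_i, c-score and d'."""
    c = c_scores(net, partition)
    d = d_prime(net)
    out = c.join(d[["d_raw", "d_prime"]])
    return out


def score_correlation(scores: pd.DataFrame | list[pd.DataFrame]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between c-score and d' (colonies pooled)."""
    if isinstance(scores, list):
        scores = pd.concat(scores)
    c = scores["c_score"].to_numpy(dtype=float)
    d = scores["d_prime"].to_numpy(dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 individuals for a correlation")
    if np.ptp(c) == 0 or np.ptp(d) == 0:
        raise ValueError("correlation undefined: a score vector is constant")
    r, p = stats.pearsonr(c, d)
    return float(r), float(p)
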