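"""Fixed-margin (r2d) null matrices and empirical p-values.

The null hypothesis for every network statistic here is "each individual
allocates its scans across behaviour-nodes in proportion to overall task
demand": random non-negative integer contingency tables with exactly the
empirical row and column totals, but a free number of realized links. Draws
use the Patefield algorithm (sequential conditional fills). Significance is
the position of the empirical statistic in the null ensemble, with an add-one
rule so p is never 0 and ties count against significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class NullEnsemble:
    """Null-replicate statistics for one network statistic."""

    statistics: np.ndarray
    statistic_name: str
    seed: int | None = None

    @property
    def n_null(self) -> int:
        return len(self.statistics)


def r2d_sample(
    row_totals,
    col_totals,
    seed: int | np.random.Generator | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw random contingency table(s) with the given margins (Patefield).

    Returns one ``(r, s)`` integer matrix, or a ``(size, r, s)`` stack when
    ``size`` is given. Margins are conserved exactly in every draw.
    """
    row_totals = np.asarray(row_totals, dtype=int)
    col_totals = np.asarray(col_totals, dtype=int)
    if (row_totals < 0).any() or (col_totals < 0).any():
        raise ValueError("margins must be non-negative")
    if row_totals.sum() != col_totals.sum():
        raise ValueError(
            f"margin mismatch: sum(row_totals)={row_totals.sum()} "
            f"!= sum(col_totals)={col_totals.sum()}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # single-row/column tables are fully determined by the margins (and the
    # sequential-fill sampler misbehaves on them)
    if len(row_totals) == 1 or len(col_totals) == 1:
        fixed = np.outer(row_totals, col_totals) // max(row_totals.sum(), 1)
        if size is None:
            return fixed
        return np.broadcast_to(fixed, (size, *fixed.shape)).copy()
    dist = stats.random_table(row_totals, col_totals)
    draws = dist.rvs(size=size, method="patefield", random_state=rng)
    return np.asarray(draws, dtype=int)


def empirical_pvalue(observed: float, nulls, tail: str = "upper") -> float:
    """Position of ``observed`` in a null ensemble: p = (1 + #{as or more extreme}) / (1 + n).

    Ties count as "as extreme" (against significance); the add-one rule bounds
    p in [1/(n+1), 1].
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null ensemble")
    if tail == "upper":
        k = int(np.count_nonzero(nulls >= observed))
    elif tail == "lower":
        k = int(np.count_nonzero(nulls <= observed))
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return (1 + k) / (1 + nulls.size)


def spawn_seeds(seed: int | None, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one root seed.

    Uses NumPy's SeedSequence spawning so results do not depend on execution
    order if replicates are ever parallelized.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
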