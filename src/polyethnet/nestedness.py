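"""Weighted nestedness (WNODF) and its null-model significance.

WNODF measures whether the behavioural repertoires of low-activity
individuals are nested subsets of those of high-activity individuals (and
symmetrically for behaviour-nodes). Rows and columns are ordered internally
by decreasing fill (number of realized cells), margin totals breaking ties;
for an ordered pair (u above v) the pair score is 0 unless v has strictly
fewer realized cells than u (decreasing fill), and otherwise it is the
percentage of v's realized cells whose weight is positive but strictly below
u's weight in the same column. WNODFr / WNODFc average the row / column pair
scores; WNODF averages all pairs together. All three lie in [0, 100]. The
conventions match the reference implementation (vegan's nested functions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_network import BipartiteNetwork
from .null_models import empirical_pvalue, r2d_sample, spawn_seeds


@dataclass
class NestednessResult:
    WNODF: float
    WNODFr: float
    WNODFc: float
    p_value: float | None = None
    null_WNODF: np.ndarray | None = None


def _pair_scores(A: np.ndarray) -> np.ndarray:
    """Scores of all ordered row pairs of a fill-sorted matrix."""
    fills = (A > 0).sum(axis=1)
    n = A.shape[0]
    scores = []
    for u in range(n):
        for v in range(u + 1, n):
            if fills[v] < fills[u] and fills[v] > 0:
                overlap = np.count_nonzero((A[v] > 0) & (A[v] < A[u]))
                scores.append(100.0 * overlap / fills[v])
            else:
                scores.append(0.0)
    return np.asarray(scores)


def _fill_order(A: np.ndarray) -> np.ndarray:
    fills = (A > 0).sum(axis=1)
    margins = A.sum(axis=1)
    return np.lexsort((-margins, -fills))  # fill first, margin breaks ties


def wnodf(net: BipartiteNetwork | np.ndarray) -> NestednessResult:
    """Weighted NODF of a pruned network (ordering is internal; input not mutated)."""
    A = net.A if isinstance(net, BipartiteNetwork) else np.asarray(net)
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("WNODF needs at least 2 rows and 2 columns")
    A = np.asarray(A, dtype=float)
    A = A[_fill_order(A)][:, _fill_order(A.T)]
    row_scores = _pair_scores(A)
    col_scores = _pair_scores(A.T)
    all_scores = np.concatenate([row_scores, col_scores])
    return NestednessResult(
        WNODF=float(all_scores.mean()),
        WNODFr=float(row_scores.mean()),
        WNODFc=float(col_scores.mean()),
    )


def wnodf_pvalue(
    net: BipartiteNetwork,
    n_null: int = 1000,
    seed: int | None = None,
) -> NestednessResult:
    """Upper-tail empirical p of WNODF against the fixed-margin (r2d) null."""
    result = wnodf(net)
    rngs = spawn_seeds(seed, n_null)
    null_vals = np.empty(n_null)
    for k, rng in enumerate(rngs):
        null_vals[k] = wnodf(r2d_sample(net.y, net.z, seed=rng)).WNODF
    result.null_WNODF = null_vals
    result.p_value = empirical_pvalue(result.WNODF, null_vals, tail="upper")
    return result
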