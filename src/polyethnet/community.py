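"""Weighted bipartite modularity: evaluation, maximization, normalization, significance.

Modularity of a weighted bipartite network is

    Q_W = (1/M) * sum_i sum_j (A_ij - y_i * z_j / M) * delta(g_i, h_j)

where ``A`` is the r x s individual x behaviour-node weight matrix, ``M`` the
total weight, ``y_i``/``z_j`` the margins, and ``delta`` is 1 when row i and
column j carry the same module label. Maximization uses a label-propagation +
agglomeration search in the style of LPAwb+, wrapped in restarts from random
initial label counts (the DIRT strategy): (1) alternately reassign each row
to the module of columns that maximizes its modularity contribution (and vice
versa), which is monotone in Q_W given the other side's labels; (2) greedily
merge module pairs while Q_W increases; repeat until no gain, and keep the
best partition over restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_network import BipartiteNetwork
from .null_models import empirical_pvalue, r2d_sample, spawn_seeds

_EPS = 1e-12


@dataclass
class Partition:
    """Module labels for both node classes (1..n_modules, no empty module)."""

    row_modules: np.ndarray
    col_modules: np.ndarray

    def __post_init__(self) -> None:
        self.row_modules = np.asarray(self.row_modules, dtype=int)
        self.col_modules = np.asarray(self.col_modules, dtype=int)
        labels = np.union1d(self.row_modules, self.col_modules)
        if labels.size and (labels.min() < 1 or labels.max() != labels.size or
                            not np.array_equal(labels, np.arange(1, labels.size + 1))):
            # canonicalize: contiguous labels 1..N_M in first-appearance order
            order = {}
            for lab in np.concatenate([self.row_modules, self.col_modules]):
                if lab not in order:
                    order[lab] = len(order) + 1
            self.row_modules = np.array([order[g] for g in self.row_modules])
            self.col_modules = np.array([order[h] for h in self.col_modules])

    @property
    def n_modules(self) -> int:
        return int(max(self.row_modules.max(initial=0), self.col_modules.max(initial=0)))


@dataclass
class ModularityResult:
    """Best partition found, its modularity, normalization and (optionally) significance."""

    Q_W: float
    Q_norm: float
    partition: Partition
    p_value: float | None = None
    null_Q: np.ndarray | None = None
    restarts_used: int = 0
    seed: int | None = None


def _check_partition(net: BipartiteNetwork, partition: Partition) -> None:
    if len(partition.row_modules) != net.r or len(partition.col_modules) != net.s:
        raise ValueError("partition does not label every row and column of the network")


def modularity(net: BipartiteNetwork, partition: Partition) -> float:
    """Evaluate Q_W for a given partition (double sum over all cells)."""
    _check_partition(net, partition)
    A = net.A.astype(float)
    M = net.M
    if M <= 0:
        raise ValueError("network has zero total weight")
    B = A - np.outer(net.y, net.z) / M
    same = partition.row_modules[:, None] == partition.col_modules[None, :]
    return float(B[same].sum() / M)


def _Q_from_labels(B: np.ndarray, M: float, g: np.ndarray, h: np.ndarray) -> float:
    return float(B[g[:, None] == h[None, :]].sum() / M)


def _argmax_random_tie(scores: np.ndarray, rng: np.random.Generator) -> int:
    best = scores.max()
    ties = np.flatnonzero(scores >= best - _EPS)
    return int(ties[0] if ties.size == 1 else rng.choice(ties))


def _sweep_side(
    B: np.ndarray, own: np.ndarray, other: np.ndarray, rng: np.random.Generator,
    next_label: int,
) -> tuple[np.ndarray, int]:
    """Reassign each node on one side to its best module given the other side.

    ``B`` is oriented (n_own, n_other). A node whose best attainable
    contribution is negative gets a fresh singleton label (contribution 0).
    """
    labels = np.unique(other)
    S = np.zeros((B.shape[0], labels.size))
    for idx, lab in enumerate(labels):
        S[:, idx] = B[:, other == lab].sum(axis=1)
    new = own.copy()
    for i in range(B.shape[0]):
        j = _argmax_random_tie(S[i], rng)
        if S[i, j] < -_EPS:
            new[i] = next_label
            next_label += 1
        else:
            new[i] = labels[j]
    return new, next_label


def _local_maximisation(
    B: np.ndarray, M: float, g: np.ndarray, h: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternate row/column label updates until Q_W stops increasing."""
    next_label = int(max(g.max(initial=0), h.max(initial=0))) + 1
    Q = _Q_from_labels(B, M, g, h)
    while True:
        h, next_label = _sweep_side(B.T, h, g, rng, next_label)
        g, next_label = _sweep_side(B, g, h, rng, next_label)
        Q_new = _Q_from_labels(B, M, g, h)
        if Q_new <= Q + _EPS:
            return g, h, max(Q, Q_new)
        Q = Q_new


def _agglomerate(
    B: np.ndarray, M: float, g: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Greedily merge module pairs while Q_W increases."""
    labels = list(np.union1d(g, h))
    relab = {lab: i for i, lab in enumerate(labels)}
    g = np.array([relab[x] for x in g])
    h = np.array([relab[x] for x in h])
    L = len(labels)
    G = np.zeros((len(g), L))
    G[np.arange(len(g)), g] = 1.0
    H = np.zeros((len(h), L))
    H[np.arange(len(h)), h] = 1.0
    K = G.T @ B @ H  # K[a, b]: weight-above-expectation from rows in a to cols in b
    alive = np.ones(L, dtype=bool)
    merged_any = False
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        gains = K[np.ix_(idx, idx)] + K[np.ix_(idx, idx)].T
        np.fill_diagonal(gains, -np.inf)
        a, b = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[a, b] <= _EPS:
            break
        a, b = idx[a], idx[b]
        K[a, :] += K[b, :]
        K[:, a] += K[:, b]
        alive[b] = False
        g[g == b] = a
        h[h == b] = a
        merged_any = True
    Q = float(np.trace(K[np.ix_(alive, alive)]) / M)
    return g, h, Q, merged_any


def _lpawb_plus(
    B: np.ndarray, M: float, g0: np.ndarray, h0: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """One full two-stage search from an initial labelling."""
    g, h, Q = _local_maximisation(B, M, g0, h0, rng)
    while True:
        g, h, Q_m, merged = _agglomerate(B, M, g, h)
        g, h, Q_new = _local_maximisation(B, M, g, h, rng)
        if not merged or Q_new <= Q + _EPS:
            return g, h, max(Q, Q_m, Q_new)
        Q = Q_new


def maximize_modularity(
    net: BipartiteNetwork,
    n_restarts: int = 20,
    seed: int | None = None,
) -> ModularityResult:
    """Search for the partition maximizing Q_W (best of ``n_restarts`` runs).

    The first restart initializes every row as its own module (plain LPAwb+
    start); the others draw a random number of initial labels between 2 and
    min(r, s) and assign rows/columns to them uniformly (DIRT strategy).
    Tie-breaks are uniform under the seeded RNG.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if (net.y == 0).any() or (net.z == 0).any():
        raise ValueError("network must be pruned of empty rows/columns first")
    A = net.A.astype(float)
    M = float(net.M)
    B = A - np.outer(net.y, net.z) / M
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rep in range(n_restarts):
        if rep == 0:
            g0 = np.arange(net.r)
            h0 = np.array([int(np.argmax(A[:, j])) for j in range(net.s)])
        else:
            k = int(rng.integers(2, min(net.r, net.s) + 1)) if min(net.r, net.s) > 1 else 1
            g0 = rng.integers(0, k, size=net.r)
            h0 = rng.integers(0, k, size=net.s)
        g, h, Q = _lpawb_plus(B, M, g0, h0, rng)
        if best is None or Q > best[0] + _EPS:
            best = (Q, g, h)

    Q, g, h = best
    partition = Partition(row_modules=g + 1, col_modules=h + 1)
    result = ModularityResult(
        Q_W=modularity(net, partition),
        Q_norm=normalized_modularity(net, partition),
        partition=partition,
        restarts_used=n_restarts,
        seed=seed,
    )
    return result


def normalized_modularity(net: BipartiteNetwork, partition: Partition) -> float:
    """Q_W divided by the maximum attainable under perfect module separation.

    The idealized configuration keeps every margin and the total weight but
    concentrates each row's weight entirely within its own module, so
    Q_max = 1 - sum_{within-module (i,j)} y_i z_j / M^2 (independent of how
    weight is spread inside a module). Defined as 0 for a single module.
    """
    _check_partition(net, partition)
    if partition.n_modules <= 1:
        return 0.0
    M = float(net.M)
    same = partition.row_modules[:, None] == partition.col_modules[None, :]
    Q_max = 1.0 - float(np.outer(net.y, net.z)[same].sum()) / M**2
    if Q_max <= _EPS:
        return 0.0
    return float(np.clip(modularity(net, partition) / Q_max, 0.0, 1.0))


def modularity_pvalue(
    net: BipartiteNetwork,
    n_null: int = 1000,
    n_restarts: int = 20,
    null_restarts: int = 2,
    seed: int | None = None,
) -> ModularityResult:
    """Upper-tail significance of the maximized Q_W against the r2d null.

    Each null replicate redraws a fixed-margin matrix and re-maximizes
    modularity on it (``null_restarts`` restarts each; the empirical network
    gets ``n_restarts``). p = (1 + #{null >= observed}) / (1 + n_null).
    """
    observed = maximize_modularity(net, n_restarts=n_restarts, seed=seed)
    rngs = spawn_seeds(seed, n_null)
    null_Q = np.empty(n_null)
    for k, rng in enumerate(rngs):
        A_null = r2d_sample(net.y, net.z, seed=rng)
        null_net = BipartiteNetwork(
            A=A_null,
            row_labels=net.row_labels,
            col_labels=net.col_labels,
            scheme=net.scheme,
            colony_id=net.colony_id,
        )
        null_Q[k] = maximize_modularity(
            null_net, n_restarts=null_restarts, seed=int(rng.integers(2**31))
        ).Q_W
    observed.null_Q = null_Q
    observed.p_value = empirical_pvalue(observed.Q_W, null_Q, tail="upper")
    return observed
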