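"""Path-consistency skeleton pruning with part mutual information (PCA-PMI).

The algorithm starts from the complete graph over all variables and removes
edges stage by stage.  Stage 0 tests every pair with MI (the "zero-order
PMI").  Stage L >= 1 tests each surviving edge e(i, j) against every size-L
subset of the common neighbours of i and j, keeping the edge iff the maximal
order-L PMI over those subsets reaches the threshold epsilon.

Two modes are provided:

* ``sequential`` — edges are visited in lexicographic order of the (permuted)
  variable indices and removals take effect immediately.  Later tests see
  earlier deletions, so the result depends on the variable order: this is the
  order dependence the SPCA ensemble exploits.
* ``stable`` — within a stage every edge is tested against the graph as it
  stood when the stage began, and removals are applied only once the stage
  completes.  The result is then invariant to the variable order.

Because every information value depends only on WHICH variables are involved
and never on their order, MI and PMI values are permutation invariant; both
are cached and shared across ensemble runs (the per-run permutation only
changes the edge visit order).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .information import (
    DataMatrix,
    InfiniteInformationError,
    pmi_from_covariance,
)

__all__ = [
    "NetworkState",
    "PruneConfig",
    "init_complete",
    "common_neighbors",
    "mi_matrix",
    "prune_order0",
    "prune_orderL",
    "run_pcapmi",
]

Mode = Literal["sequential", "stable"]

UNTESTED = -1  # sentinel in last_order for pairs never scored

#: cache of PMI values keyed by (i, j, conditioning subset), i < j
PmiCache = dict[tuple[int, int, tuple[int, ...]], float]


@dataclass
class NetworkState:
    """Working object of the pruning algorithms.

    adjacency  — symmetric 0/1 int matrix, zero diagonal.
    last_score — per pair, the most recent information value tested
                 (MI at order 0, then the maximal order-L PMI); NaN where
                 never tested.
    last_order — the order L at which last_score was computed; -1 untested.
    """

    adjacency: np.ndarray
    last_score: np.ndarray
    last_order: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def edge_set(self) -> frozenset[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return frozenset(zip(ii.tolist(), jj.tolist()))

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.adjacency.copy(), self.last_score.copy(), self.last_order.copy()
        )

    def validate(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")


@dataclass(frozen=True)
class PruneConfig:
    """Threshold, order budget, mode and variable order for one run."""

    epsilon: float
    max_order: int | Literal["auto"] = "auto"
    mode: Mode = "sequential"
    order: tuple[int, ...] | None = None  # None = identity permutation

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.max_order != "auto" and int(self.max_order) < 0:
            raise ValueError("max_order must be >= 0 or 'auto'")
        if self.mode not in ("sequential", "stable"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.order is not None:
            order = tuple(int(i) for i in self.order)
            if sorted(order) != list(range(len(order))):
                raise ValueError("order must be a permutation of 0..n-1")
            object.__setattr__(self, "order", order)


def init_complete(n: int) -> NetworkState:
    """The complete network on n nodes: every off-diagonal entry is 1."""
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    adj = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(adj, 0)
    return NetworkState(
        adjacency=adj,
        last_score=np.full((n, n), np.nan),
        last_order=np.full((n, n), UNTESTED, dtype=np.int64),
    )


def common_neighbors(net: NetworkState, i: int, j: int) -> list[int]:
    """Nodes adjacent to both i and j in the current graph."""
    if i == j:
        raise ValueError("i and j must differ")
    mask = (net.adjacency[i] == 1) & (net.adjacency[j] == 1)
    mask[i] = mask[j] = False
    return np.nonzero(mask)[0].tolist()


def _correlation(D: DataMatrix) -> np.ndarray:
    sd = D.values.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        bad = [D.variable_ids[k] for k in np.nonzero(sd <= 0)[0]]
        raise ValueError(f"zero-variance variable(s): {bad}")
    c = np.corrcoef(D.values)
    return (c + c.T) / 2.0


def mi_matrix(D: DataMatrix) -> np.ndarray:
    """Pairwise Gaussian MI, -0.5 ln(1 - r^2), for all variable pairs.

    MI is invariant under variable permutation, so this matrix is computed
    once and shared across ensemble runs.  Perfectly correlated pairs get
    +inf (they can never be pruned by a finite threshold).
    """
    c = _correlation(D)
    r2 = np.clip(c**2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log1p(-r2)
    np.fill_diagonal(mi, 0.0)
    return mi


def prune_order0(
    D: DataMatrix,
    net: NetworkState,
    cfg: PruneConfig,
    *,
    mi: np.ndarray | None = None,
) -> NetworkState:
    """Stage L=0: remove every edge whose MI falls below epsilon.

    Every pair is tested, so this stage is order-independent in both modes.
    """
    out = net.copy()
    if mi is None:
        mi = mi_matrix(D)
    out.last_score = mi.copy()
    out.last_order = np.zeros_like(out.last_order)
    np.fill_diagonal(out.last_order, UNTESTED)
    keep = (mi >= cfg.epsilon).astype(np.int8)
    out.adjacency = out.adjacency * keep
    return out


def _pmi_order1(corr: np.ndarray, i: int, j: int, ks: np.ndarray) -> np.ndarray:
    """Vectorized first-order PMI(i, j | k) for every k in ``ks``.

    Scalar specialisation of the general closed form to a 3 x 3 correlation
    submatrix; clamped at 0 from below.
    """
    rxy = corr[i, j]
    rxz = corr[i, ks]
    ryz = corr[j, ks]
    det_xy_z = (1 - rxz**2) * (1 - ryz**2) - (rxy - rxz * ryz) ** 2

    def star(r_to, r_tz, r_oz):
        # regression of the target on (other, z); variances are 1
        det0 = 1 - r_oz**2
        b_o = (r_to - r_tz * r_oz) / det0
        c = (r_tz - r_to * r_oz) / det0
        resid = 1 - (r_to * b_o + r_tz * c)
        v_star = resid + b_o**2
        e_sq = 1 - 2 * c * r_tz + c**2
        return np.log(v_star), e_sq / v_star

    with np.errstate(divide="ignore", invalid="ignore"):
        lvx, ex = star(rxy, rxz, ryz)
        lvy, ey = star(rxy, ryz, rxz)
        val = 0.5 * (lvx + lvy - np.log(det_xy_z)) + 0.5 * (ex + ey) - 1.0
    val = np.where(det_xy_z <= 1e-12, np.inf, val)
    return np.where(np.isnan(val), np.inf, np.maximum(val, 0.0))


def _pmi_value(
    corr: np.ndarray,
    i: int,
    j: int,
    S: tuple[int, ...],
    cache: PmiCache | None,
) -> float:
    a, b = (i, j) if i < j else (j, i)
    key = (a, b, S)
    if cache is not None and key in cache:
        return cache[key]
    idx = [i, j, *S]
    try:
        val = pmi_from_covariance(corr[np.ix_(idx, idx)])
    except InfiniteInformationError:
        val = float("inf")
    if cache is not None:
        cache[key] = val
    return val


def _pmi_max(
    corr: np.ndarray,
    i: int,
    j: int,
    K: Sequence[int],
    L: int,
    cache: PmiCache | None,
) -> float:
    """Maximal order-L PMI of (i, j) over all size-L subsets of K."""
    if L == 1 and cache is None:
        return float(_pmi_order1(corr, i, j, np.asarray(K)).max())
    best = -np.inf
    if L == 1:
        a, b = (i, j) if i < j else (j, i)
        missing = [k for k in K if (a, b, (k,)) not in cache]
        if missing:
            vals = _pmi_order1(corr, i, j, np.asarray(missing))
            for k, v in zip(missing, vals):
                cache[(a, b, (int(k),))] = float(v)
        return max(cache[(a, b, (k,))] for k in K)
    for S in itertools.combinations(sorted(K), L):
        val = _pmi_value(corr, i, j, S, cache)
        if val > best:
            best = val
    return best


def _visit_order(
    edges: list[tuple[int, int]], order: tuple[int, ...] | None
) -> list[tuple[int, int]]:
    """Sort edges lexicographically by their labels under the permutation.

    Running the algorithm on data whose rows were reordered by ``order`` and
    visiting pairs (i < j) lexicographically is equivalent to visiting the
    original pairs sorted by their permuted labels: information values do not
    depend on variable order, only the visit sequence does.
    """
    if order is None:
        return sorted(edges)
    pos = {v: r for r, v in enumerate(order)}
    def key(e: tuple[int, int]) -> tuple[int, int]:
        a, b = pos[e[0]], pos[e[1]]
        return (a, b) if a < b else (b, a)
    return sorted(edges, key=key)


def prune_orderL(
    D: DataMatrix | None,
    net: NetworkState,
    L: int,
    cfg: PruneConfig,
    *,
    corr: np.ndarray | None = None,
    cache: PmiCache | None = None,
) -> NetworkState:
    """One order-L stage (L >= 1) of the pruning algorithm.

    For each surviving edge, with K the common neighbours and T = |K|:
    if T < L the edge cannot be tested and is kept; otherwise the maximal
    PMI over all C(T, L) conditioning subsets is recorded and the edge is
    removed iff it falls below epsilon.  T = L is treated as testable with
    its single subset.
    """
    if L < 1:
        raise ValueError("stage order L must be >= 1")
    if corr is None:
        if D is None:
            raise ValueError("need either data or a correlation matrix")
        corr = _correlation(D)
    out = net.copy()
    frozen = net if cfg.mode == "stable" else out
    to_remove: list[tuple[int, int]] = []
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    edges = list(zip(ii.tolist(), jj.tolist()))
    for i, j in _visit_order(edges, cfg.order):
        if cfg.mode == "sequential" and out.adjacency[i, j] == 0:
            continue  # removed earlier in this stage
        K = common_neighbors(frozen, i, j)
        if len(K) < L:
            continue
        pmi_max = _pmi_max(corr, i, j, K, L, cache)
        out.last_score[i, j] = out.last_score[j, i] = pmi_max
        out.last_order[i, j] = out.last_order[j, i] = L
        if pmi_max < cfg.epsilon:
            if cfg.mode == "sequential":
                out.adjacency[i, j] = out.adjacency[j, i] = 0
            else:
                to_remove.append((i, j))
    for i, j in to_remove:
        out.adjacency[i, j] = out.adjacency[j, i] = 0
    return out


def run_pcapmi(
    D: DataMatrix,
    cfg: PruneConfig,
    *,
    mi: np.ndarray | None = None,
    cache: PmiCache | None = None,
) -> NetworkState:
    """Full PCA-PMI run: order 0, then orders 1, 2, ... per ``cfg``.

    ``cfg.order`` re-labels the variables before the run, which fixes the
    edge visit sequence in sequential mode — the single source of order
    dependence.  All returned matrices are in the original indexing.
    ``mi`` and ``cache`` may carry a precomputed MI matrix and a PMI value
    cache, shared across ensemble runs (both are permutation invariant).

    With ``max_order='auto'`` stages continue until a stage removes nothing
    and no surviving edge has enough common neighbours for the next order.
    """
    n = D.n_variables
    if cfg.order is not None and len(cfg.order) != n:
        raise ValueError("cfg.order length must equal the number of variables")
    corr = _correlation(D)

    net = init_complete(n)
    net = prune_order0(D, net, cfg, mi=mi)

    max_order = cfg.max_order
    L = 1
    while True:
        if max_order != "auto" and L > int(max_order):
            break
        if net.n_edges == 0:
            break
        before = net.n_edges
        t_counts = [len(common_neighbors(net, i, j)) for i, j in net.edge_set()]
        max_t = max(t_counts, default=0)
        if max_t < L:
            break
        net = prune_orderL(D, net, L, cfg, corr=corr, cache=cache)
        removed = before - net.n_edges
        if max_order == "auto" and removed == 0 and max_t <= L:
            break
        if L >= n - 2:
            break
        L += 1
    return net
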