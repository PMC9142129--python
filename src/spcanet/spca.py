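"""Statistical path-consistency algorithm (SPCA).

Sequential PCA-PMI is order dependent: the same data under two variable
orders can yield different skeletons.  SPCA turns that liability into a
statistic — it runs PCA-PMI under N random variable orders and aggregates
per-edge evidence across the ensemble:

* mean weight        MW_ij   = (1/N) sum_k w_ij^(k)           (presence rate)
* average PMI        APMI_ij = (1/N) sum_k PMI_ij^(k) w_ij^(k)
* maximal PMI        MPMI_ij = max_k PMI_ij^(k)

where w_ij^(k) is 1 iff edge (i, j) survived run k and PMI_ij^(k) is the
highest-order score recorded for the pair in run k.  Edges present in all /
some / none of the runs are labelled Case 1 / 2 / 3.  The final network is
the top M pairs under the chosen criterion, optionally forced connected by
a maximum-weight spanning tree (MST completion).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .information import DataMatrix
from .pcapmi import NetworkState, PruneConfig, mi_matrix, run_pcapmi

__all__ = [
    "EnsembleResult",
    "EdgeScoreTable",
    "sample_orders",
    "run_ensemble",
    "aggregate",
    "select_top_m",
    "variation_ratio",
    "mst_completion",
    "edge_frequency_histogram",
    "check_threshold_guidance",
]

logger = logging.getLogger("spcanet")

Criterion = Literal["MW", "APMI", "MPMI"]


@dataclass(frozen=True)
class EnsembleResult:
    """Per-order inference results, all in the ORIGINAL variable indexing."""

    orders: tuple[tuple[int, ...], ...]
    weights: np.ndarray  # (N, n, n) 0/1
    scores: np.ndarray  # (N, n, n) last_score of each run
    edge_counts: np.ndarray  # (N,)

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @property
    def n(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class EdgeScoreTable:
    """Aggregated per-pair evidence: MW, APMI, MPMI and Case 1/2/3 label."""

    mw: np.ndarray
    apmi: np.ndarray
    mpmi: np.ndarray
    case: np.ndarray  # int: 1 in all runs, 2 in some, 3 in none

    @property
    def n(self) -> int:
        return self.mw.shape[0]

    def criterion(self, name: Criterion) -> np.ndarray:
        try:
            return {"MW": self.mw, "APMI": self.apmi, "MPMI": self.mpmi}[name]
        except KeyError:
            raise ValueError(f"unknown criterion {name!r}") from None

    def pairs(self) -> list[tuple[int, int]]:
        n = self.n
        return [(i, j) for i in range(n) for j in range(i + 1, n)]


def sample_orders(n: int, N: int, seed: int) -> list[tuple[int, ...]]:
    """N uniformly random variable orders from a seeded generator."""
    if n < 2 or N < 1:
        raise ValueError("need n >= 2 and N >= 1")
    rng = np.random.default_rng(seed)
    return [tuple(rng.permutation(n).tolist()) for _ in range(N)]


def run_ensemble(
    D: DataMatrix, cfg: PruneConfig, N: int, seed: int
) -> EnsembleResult:
    """N sequential PCA-PMI runs under random variable orders.

    The MI matrix is permutation invariant and computed once, then shared by
    every run.  Mode is fixed to sequential: a stable-mode ensemble would
    collapse to N identical runs.
    """
    n = D.n_variables
    orders = sample_orders(n, N, seed)
    mi = mi_matrix(D)
    pmi_cache: dict = {}  # PMI values are permutation invariant too
    weights = np.zeros((N, n, n), dtype=np.int8)
    scores = np.zeros((N, n, n))
    counts = np.zeros(N, dtype=np.int64)
    for k, order in enumerate(orders):
        run_cfg = replace(cfg, mode="sequential", order=order)
        net: NetworkState = run_pcapmi(D, run_cfg, mi=mi, cache=pmi_cache)
        weights[k] = net.adjacency
        scores[k] = net.last_score
        counts[k] = net.n_edges
    logger.info(
        "ensemble: N=%d, epsilon=%g, edge counts %d..%d (mean %.1f)",
        N, cfg.epsilon, counts.min(), counts.max(), counts.mean(),
    )
    return EnsembleResult(tuple(orders), weights, scores, counts)


def aggregate(
    ens: EnsembleResult, *, absent_scores: Literal["last", "zero"] = "last"
) -> EdgeScoreTable:
    """Aggregate an ensemble into MW / APMI / MPMI and Case labels.

    ``absent_scores`` controls what MPMI sees for runs in which an edge was
    removed: ``"last"`` (default) uses the failing score recorded at
    removal — Eq-style MPMI has no presence factor, and for any surviving
    edge the max is dominated by a surviving run anyway; ``"zero"`` scores
    those runs as 0.
    """
    w = ens.weights.astype(float)
    s = np.nan_to_num(ens.scores, nan=0.0, posinf=np.inf)
    mw = w.mean(axis=0)
    apmi = (s * w).mean(axis=0)
    if absent_scores == "last":
        mpmi = s.max(axis=0)
    elif absent_scores == "zero":
        mpmi = (s * w).max(axis=0)
    else:
        raise ValueError(f"unknown absent_scores {absent_scores!r}")
    present = ens.weights.sum(axis=0)
    case = np.full(mw.shape, 2, dtype=np.int64)
    case[present == ens.N] = 1
    case[present == 0] = 3
    np.fill_diagonal(case, 0)
    for a in (mw, apmi, mpmi):
        np.fill_diagonal(a, 0.0)
    return EdgeScoreTable(mw, apmi, mpmi, case)


def _ranked_pairs(
    table: EdgeScoreTable, criterion: Criterion
) -> list[tuple[int, int, float]]:
    """All pairs sorted by score descending, ties by ascending (i, j)."""
    sc = table.criterion(criterion)
    pairs = table.pairs()
    return sorted(
        ((i, j, float(sc[i, j])) for i, j in pairs),
        key=lambda t: (-t[2], t[0], t[1]),
    )


def select_top_m(
    table: EdgeScoreTable, criterion: Criterion, M: int
) -> list[tuple[int, int, float]]:
    """The M pairs with the largest criterion value.

    Ties are broken deterministically: descending score, then ascending
    (i, j) index pair.
    """
    total = table.n * (table.n - 1) // 2
    if not 1 <= M <= total:
        raise ValueError(f"M must be in [1, {total}], got {M}")
    return _ranked_pairs(table, criterion)[:M]


def variation_ratio(edge_counts: Sequence[int]) -> float:
    """(max - min) / mean of per-run edge counts; 0 iff counts constant."""
    counts = np.asarray(edge_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("edge_counts must be non-empty")
    mean = counts.mean()
    if mean <= 0:
        raise ValueError("variation ratio undefined: mean edge count is 0")
    return float((counts.max() - counts.min()) / mean)


def mst_completion(
    table: EdgeScoreTable, criterion: Criterion, M: int
) -> list[tuple[int, int, float]]:
    """Top-M selection forced connected via a maximum-weight spanning tree.

    A spanning tree under the criterion scores guarantees connectivity
    (n - 1 edges); the remaining M - (n - 1) slots are filled with the
    highest-scoring non-tree pairs.
    """
    n = table.n
    if M < n - 1:
        raise ValueError(f"cannot connect {n} nodes with M={M} < n-1 edges")
    sc = table.criterion(criterion)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in table.pairs():
        g.add_edge(i, j, weight=float(sc[i, j]))
    tree = nx.maximum_spanning_tree(g, weight="weight")
    tree_edges = {tuple(sorted(e)) for e in tree.edges()}
    out = [(i, j, float(sc[i, j])) for i, j in sorted(tree_edges)]
    for i, j, s in _ranked_pairs(table, criterion):
        if len(out) >= M:
            break
        if (i, j) not in tree_edges:
            out.append((i, j, s))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def edge_frequency_histogram(
    table: EdgeScoreTable, bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the mean weight over Case-2 edges only.

    Returns (counts, bin_edges) over [0, 1]; counts sum to the number of
    Case-2 edges.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    iu = np.triu_indices(table.n, 1)
    mask = table.case[iu] == 2
    vals = table.mw[iu][mask]
    return np.histogram(vals, bins=bins, range=(0.0, 1.0))


def check_threshold_guidance(
    table: EdgeScoreTable, expected_edges: int
) -> bool:
    """Warn if epsilon was chosen poorly for the expected network size.

    Guidance: the Case-1 count should be below the expected edge number and
    the Case-1 + Case-2 count above it, so that ranking Case-2 edges is what
    decides the final network.  Returns True when the guidance holds.
    """
    iu = np.triu_indices(table.n, 1)
    c1 = int((table.case[iu] == 1).sum())
    c12 = c1 + int((table.case[iu] == 2).sum())
    ok = c1 < expected_edges and c12 > expected_edges
    if not ok:
        warnings.warn(
            f"threshold guidance violated: Case-1 edges={c1}, "
            f"Case-1+2 edges={c12}, expected edges={expected_edges}; "
            "consider adjusting epsilon",
            stacklevel=2,
        )
    return ok
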