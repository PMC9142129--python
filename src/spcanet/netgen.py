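"""Synthetic gold-standard networks with matched Gaussian expression data.

The generator emulates DREAM4-scale benchmarks (100 genes x 100 samples,
~170-240 edges, density 0.035-0.05, heavy-tailed degrees) through a Gaussian
graphical model: the gold standard is a sparse random graph, its edges
become the nonzero off-diagonal entries of a precision matrix, and the
expression matrix is drawn i.i.d. from N(0, Omega^{-1}).  Edges therefore
coincide exactly with the model's conditional dependencies — precisely what
PMI-based path-consistency pruning tests — so recovery performance can be
scored against an exact ground truth without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .information import DataMatrix

__all__ = [
    "GoldStandard",
    "SimulationSpec",
    "generate_gold",
    "gold_to_precision",
    "simulate_expression",
    "simulate_dataset",
    "worked_fixture",
]

Topology = Literal["erdos_renyi", "preferential_attachment"]
Link = Literal["linear", "sigmoidal"]


@dataclass(frozen=True)
class GoldStandard:
    """A known true edge set over n named genes."""

    n: int
    edges: frozenset[tuple[int, int]]
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        edges = frozenset(tuple(sorted(e)) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(self.ids) != self.n:
            raise ValueError("ids must have length n")
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-edge ({i}, {j}) not allowed")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i}, {j}) out of range")

    @property
    def density(self) -> float:
        return len(self.edges) / (self.n * (self.n - 1) / 2)


def default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"G{i + 1}" for i in range(n))


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and strength parameters of one synthetic benchmark instance.

    partial_correlation_range sets the magnitude of precision-matrix
    off-diagonals before diagonal regularisation; noise_sd adds optional
    i.i.d. observation noise on top of the Gaussian draw; link='sigmoidal'
    applies a monotone tanh transform (robustness testing only — the
    Gaussian estimators see a misspecified marginal).
    """

    n: int = 100
    m: int = 100
    target_edges: int | None = None
    density: float | None = 0.04
    topology: Topology = "preferential_attachment"
    partial_correlation_range: tuple[float, float] = (0.3, 0.6)
    noise_sd: float = 0.0
    link: Link = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 3:
            raise ValueError("need n >= 2 and m >= 3")
        lo, hi = self.partial_correlation_range
        if not (0 < lo <= hi < 1):
            raise ValueError("partial correlation range must satisfy 0 < lo <= hi < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def edge_target(self) -> int:
        total = self.n * (self.n - 1) // 2
        if self.target_edges is not None:
            t = int(self.target_edges)
        elif self.density is not None:
            t = int(round(self.density * total))
        else:
            raise ValueError("specify target_edges or density")
        if not 0 < t < total:
            raise ValueError(f"infeasible edge target {t} for n={self.n}")
        return t


def generate_gold(spec: SimulationSpec) -> GoldStandard:
    """A random graph hitting the spec's edge target exactly.

    erdos_renyi uses a uniform G(n, m) draw.  preferential_attachment grows
    a Barabasi-Albert graph (heavy-tailed degrees, mimicking hub genes) and
    then adds or removes uniformly random edges to reach the target count.
    """
    target = spec.edge_target
    rng = np.random.default_rng(spec.seed)
    nx_seed = int(rng.integers(2**31))
    if spec.topology == "erdos_renyi":
        g = nx.gnm_random_graph(spec.n, target, seed=nx_seed)
    elif spec.topology == "preferential_attachment":
        attach = max(1, round(target / spec.n))
        g = nx.barabasi_albert_graph(spec.n, attach, seed=nx_seed)
        edges = {tuple(sorted(e)) for e in g.edges()}
        all_pairs = [
            (i, j) for i in range(spec.n) for j in range(i + 1, spec.n)
        ]
        while len(edges) > target:  # drop uniformly random edges
            drop = list(edges)[rng.integers(len(edges))]
            edges.discard(drop)
        candidates = [p for p in all_pairs if p not in edges]
        rng.shuffle(candidates)
        for p in candidates:
            if len(edges) >= target:
                break
            edges.add(p)
        g = nx.Graph()
        g.add_nodes_from(range(spec.n))
        g.add_edges_from(edges)
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    return GoldStandard(
        spec.n,
        frozenset(tuple(sorted(e)) for e in g.edges()),
        default_ids(spec.n),
    )


#: minimum eigenvalue enforced on generated precision matrices
_MIN_EIG = 0.1


def gold_to_precision(gold: GoldStandard, spec: SimulationSpec) -> np.ndarray:
    """A sparse SPD precision matrix whose support is exactly the gold edges.

    The precision has unit diagonal, so each off-diagonal entry is (minus)
    the partial correlation of its edge.  Magnitudes are drawn from
    partial_correlation_range with random signs.  If the resulting matrix is
    not positive definite with minimum eigenvalue >= 0.1 — typical around
    hub genes, whose many strong partial correlations cannot coexist — the
    magnitudes are uniformly shrunk (bisection) but never below lo / 2, so
    every edge stays detectable; only if even the floored weights are too
    strong is the diagonal boosted as a last resort.  Keeping the diagonal
    at 1 keeps the implied covariance well conditioned, which is what makes
    the marginal correlation structure sparse, like real benchmark data.
    """
    rng = np.random.default_rng(spec.seed + 1)
    lo, hi = spec.partial_correlation_range
    n = gold.n
    edges = sorted(gold.edges)
    mags = rng.uniform(lo, hi, size=len(edges))
    signs = rng.choice((-1.0, 1.0), size=len(edges))
    floor = lo / 2.0

    def build(tau: float) -> np.ndarray:
        omega = np.eye(n)
        w = signs * np.maximum(floor, tau * mags)
        for (i, j), wij in zip(edges, w):
            omega[i, j] = omega[j, i] = wij
        return omega

    def min_eig(a: np.ndarray) -> float:
        return float(np.linalg.eigvalsh(a)[0])

    omega = build(1.0)
    if min_eig(omega) >= _MIN_EIG:
        return omega
    omega_floor = build(0.0)
    if min_eig(omega_floor) < _MIN_EIG:
        lam = min_eig(omega_floor)
        omega_floor += (_MIN_EIG - lam) * np.eye(n)
        return omega_floor
    hi_tau, lo_tau = 1.0, 0.0
    for _ in range(40):
        mid = (hi_tau + lo_tau) / 2.0
        if min_eig(build(mid)) >= _MIN_EIG:
            lo_tau = mid
        else:
            hi_tau = mid
    return build(lo_tau)


def simulate_expression(
    omega: np.ndarray, m: int, link: Link = "linear", seed: int = 0,
    *, noise_sd: float = 0.0, ids: tuple[str, ...] | None = None,
) -> DataMatrix:
    """m i.i.d. draws from N(0, Omega^{-1}), genes in rows."""
    omega = np.asarray(omega, dtype=float)
    n = omega.shape[0]
    if m < 3:
        raise ValueError("need m >= 3 observations")
    lam = np.linalg.eigvalsh(omega)[0]
    if lam <= 0:
        raise ValueError("precision matrix must be positive definite")
    cov = np.linalg.inv(omega)
    cov = (cov + cov.T) / 2.0
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(n), cov, size=m, method="cholesky").T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    if link == "sigmoidal":
        x = np.tanh(x)
    elif link != "linear":
        raise ValueError(f"unknown link {link!r}")
    return DataMatrix(x, ids if ids is not None else default_ids(n))


def simulate_dataset(spec: SimulationSpec) -> tuple[DataMatrix, GoldStandard]:
    """Gold standard + matched expression matrix in one seeded call."""
    gold = generate_gold(spec)
    omega = gold_to_precision(gold, spec)
    D = simulate_expression(
        omega, spec.m, spec.link, spec.seed + 2,
        noise_sd=spec.noise_sd, ids=gold.ids,
    )
    return D, gold


#: edges of the pinned 5-gene documentation fixture: a chain with a fork
_FIXTURE_EDGES = frozenset({(0, 1), (1, 2), (2, 3), (2, 4)})


def worked_fixture() -> tuple[DataMatrix, GoldStandard]:
    """A pinned 5-gene, 500-sample chain/fork instance for examples and tests.

    Gold skeleton: G1-G2-G3, with G3 branching to G4 and G5 (4 edges).
    All non-adjacent pairs are conditionally independent given the chain
    interior, so path-consistency pruning at moderate epsilon recovers the
    skeleton exactly.
    """
    spec = SimulationSpec(
        n=5, m=500, target_edges=4, density=None,
        topology="erdos_renyi",
        partial_correlation_range=(0.35, 0.45), seed=0,
    )
    gold = GoldStandard(5, _FIXTURE_EDGES, default_ids(5))
    omega = gold_to_precision(gold, spec)
    D = simulate_expression(omega, spec.m, "linear", spec.seed + 2, ids=gold.ids)
    return D, gold
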