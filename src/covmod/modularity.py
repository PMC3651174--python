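"""Weighted Newman modularity, module detection, and module/node metrics.

For a weighted network with total edge weight L and a partition into modules
s = 1..N_m, modularity is

    Q = sum_s [ l_s / L - (d_s / 2L)^2 ]

where l_s is the sum of edge weights inside module s and d_s the sum of node
strengths (a node's strength is the sum of its incident edge weights) over the
module. The optimizer is a Louvain-style greedy agglomeration — repeated local
node moves followed by module aggregation — restarted from random node orders;
on small networks it is validated against exhaustive enumeration of all set
partitions. Module-level connectivity (MC, IMC) and node roles (intra-module
degree z-score MD, participation coefficient PC) follow the standard
definitions used for brain networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from covmod.cohort import Partition

logger = logging.getLogger(__name__)


def _weights_of(network) -> np.ndarray:
    """Accept a CorrelationNetwork or a raw symmetric weight matrix."""
    weights = getattr(network, "weights", network)
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(weights, weights.T):
        raise ValueError("weight matrix must be symmetric")
    return weights


def _check_partition(weights: np.ndarray, partition: Partition) -> np.ndarray:
    if partition.n_nodes != weights.shape[0]:
        raise ValueError(
            f"partition has {partition.n_nodes} nodes, network has {weights.shape[0]}"
        )
    return partition.as_array()


def _membership(assign: np.ndarray) -> np.ndarray:
    """One-hot nodes x modules indicator (modules 1..N_m)."""
    n_modules = assign.max()
    onehot = np.zeros((assign.size, n_modules))
    onehot[np.arange(assign.size), assign - 1] = 1.0
    return onehot


def _q_terms(weights: np.ndarray, assign: np.ndarray):
    onehot = _membership(assign)
    strengths = weights.sum(axis=1)
    total = weights.sum() / 2.0  # L; diagonal carries 2x internal weight in aggregates
    block = onehot.T @ weights @ onehot
    l_s = np.diag(block) / 2.0
    d_s = onehot.T @ strengths
    return l_s, d_s, total


def modularity_q(network, partition: Partition) -> float:
    """Newman's weighted modularity of a partition."""
    weights = _weights_of(network)
    assign = _check_partition(weights, partition)
    l_s, d_s, total = _q_terms(weights, assign)
    if total <= 0:
        raise ValueError("total weight must be positive")
    return float(l_s.sum() / total - ((d_s / (2.0 * total)) ** 2).sum())


@dataclass
class ModularityResult:
    """Optimal (or evaluated) partition with its Q decomposition and an audit
    trace of the optimizer restarts."""

    partition: Partition
    q: float
    l_s: np.ndarray
    d_s: np.ndarray
    total_weight: float
    optimizer_trace: tuple[float, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": np.arange(1, len(self.l_s) + 1),
                "intra_module_weight": self.l_s,
                "strength_sum": self.d_s,
            }
        )


def _louvain_local_pass(
    weights: np.ndarray, comm: np.ndarray, rng: np.random.Generator
) -> bool:
    """One sweep of greedy node moves; returns True if anything moved."""
    n = weights.shape[0]
    strengths = weights.sum(axis=1)
    two_m = weights.sum()
    if two_m <= 0:
        return False
    n_comm = comm.max() + 1
    sigma_tot = np.bincount(comm, weights=strengths, minlength=n_comm)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ki = strengths[i]
            # links from i to each community, excluding the diagonal
            row = weights[i].copy()
            row[i] = 0.0
            w_ic = np.bincount(comm, weights=row, minlength=n_comm)
            old = comm[i]
            sigma_tot[old] -= ki
            gains = w_ic - ki * sigma_tot / two_m
            best = int(np.flatnonzero(gains >= gains.max() - 1e-15)[0])
            if gains[best] <= gains[old] + 1e-15:
                best = old
            comm[i] = best
            sigma_tot[best] += ki
            if best != old:
                improved = True
                moved_any = True
    return moved_any


def _compress_labels(comm: np.ndarray) -> np.ndarray:
    _, compressed = np.unique(comm, return_inverse=True)
    return compressed


def _louvain_once(
    weights: np.ndarray, rng: np.random.Generator, init: np.ndarray | None = None
) -> np.ndarray:
    """Full Louvain run: local moves + aggregation, then node-level refinement,
    cycled until neither phase improves the partition.

    The refinement sweep matters: aggregation locks single nodes into merged
    modules, and moving them individually on the original graph can escape
    such local optima; a refinement move re-opens the aggregation phase.
    ``init`` seeds the run from an arbitrary partition instead of singletons.
    """
    n = weights.shape[0]
    node_comm = np.arange(n) if init is None else np.asarray(init, dtype=int)
    while True:
        # aggregation phase, starting from the current partition
        node_comm = _compress_labels(node_comm)
        onehot = _membership(node_comm + 1)
        level_weights = onehot.T @ weights @ onehot
        level_comm = np.arange(level_weights.shape[0])
        while True:
            moved = _louvain_local_pass(level_weights, level_comm, rng)
            level_comm = _compress_labels(level_comm)
            node_comm = level_comm[node_comm]
            if not moved or level_comm.max() + 1 == level_weights.shape[0]:
                break
            onehot = _membership(level_comm + 1)
            level_weights = onehot.T @ level_weights @ onehot
            level_comm = np.arange(level_weights.shape[0])
        # node-level refinement phase
        node_comm = _compress_labels(node_comm)
        if not _louvain_local_pass(weights, node_comm, rng):
            return _compress_labels(node_comm)


def optimize_partition(network, n_restarts: int = 100, seed: int = 0) -> ModularityResult:
    """Best partition over ``n_restarts`` randomized Louvain runs.

    Deterministic given the seed. Modules of the returned partition are
    relabelled canonically (module 1 contains the lowest-index node, etc.);
    among equal-Q restarts the first found is kept.
    """
    weights = _weights_of(network)
    if (weights < 0).any():
        raise ValueError("optimize_partition requires non-negative weights; apply a policy")
    if np.any(np.diag(weights) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    rng = np.random.default_rng(seed)
    best_q = -np.inf
    best_assign = None
    trace = []
    n = weights.shape[0]
    for restart in range(max(1, n_restarts)):
        # greedy agglomeration from singletons funnels into one basin for many
        # node orders; odd restarts start from a random coarse partition instead
        init = None
        if restart % 2 == 1:
            init = rng.integers(0, int(rng.integers(2, min(n, 8) + 1)), n)
        assign = _louvain_once(weights, rng, init=init)
        partition = Partition.from_labels(assign)
        q = modularity_q(weights, partition)
        trace.append(q)
        if q > best_q + 1e-13:
            best_q, best_assign = q, assign
    partition = Partition.from_labels(best_assign)
    l_s, d_s, total = _q_terms(weights, partition.as_array())
    return ModularityResult(
        partition=partition,
        q=best_q,
        l_s=l_s,
        d_s=d_s,
        total_weight=total,
        optimizer_trace=tuple(trace),
    )


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)
    maxima = np.zeros(n, dtype=int)  # maxima[i] = max(labels[:i+1])
    while True:
        yield labels.copy()
        # next restricted growth string
        i = n - 1
        while i > 0 and labels[i] == maxima[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        labels[i] += 1
        maxima[i] = max(maxima[i - 1], labels[i])
        for j in range(i + 1, n):
            labels[j] = 0
            maxima[j] = maxima[i]


def exhaustive_best_partition(network, max_nodes: int = 12) -> ModularityResult:
    """Globally optimal partition by enumerating every set partition.

    Independent brute-force oracle for the heuristic optimizer; feasible only
    for small networks (Bell(12) ~ 4.2 million).
    """
    weights = _weights_of(network)
    n = weights.shape[0]
    if n > max_nodes:
        raise ValueError(f"exhaustive search capped at {max_nodes} nodes, got {n}")
    strengths = weights.sum(axis=1)
    total = weights.sum() / 2.0
    if total <= 0:
        raise ValueError("total weight must be positive")
    best_q = -np.inf
    best_labels = None
    idx = np.arange(n)
    for labels in _set_partitions(n):
        n_mod = labels.max() + 1
        onehot = np.zeros((n, n_mod))
        onehot[idx, labels] = 1.0
        l_sum = float(np.einsum("is,ij,js->", onehot, weights, onehot)) / 2.0
        d_s = onehot.T @ strengths
        q = l_sum / total - float(((d_s / (2.0 * total)) ** 2).sum())
        if q > best_q + 1e-13:
            best_q, best_labels = q, labels
    best = Partition.from_labels(best_labels)
    l_s, d_s, total = _q_terms(weights, best.as_array())
    return ModularityResult(partition=best, q=best_q, l_s=l_s, d_s=d_s, total_weight=total)


def intra_module_connectivity(network, partition: Partition, module_id: int) -> float:
    """MC_s: the sum of edge weights with both endpoints in module s."""
    weights = _weights_of(network)
    assign = _check_partition(weights, partition)
    if not 1 <= module_id <= partition.n_modules:
        raise KeyError(f"unknown module id {module_id}")
    members = assign == module_id
    return float(weights[np.ix_(members, members)].sum() / 2.0)


def inter_module_connectivity(network, partition: Partition, s: int, t: int) -> float:
    """IMC_st: the sum of edge weights with one endpoint in s and one in t."""
    if s == t:
        raise ValueError("inter-module connectivity requires two distinct modules")
    weights = _weights_of(network)
    assign = _check_partition(weights, partition)
    for m in (s, t):
        if not 1 <= m <= partition.n_modules:
            raise KeyError(f"unknown module id {m}")
    return float(weights[np.ix_(assign == s, assign == t)].sum())


@dataclass
class NodeRoleProfile:
    """Per-node intra-module degree z-scores and participation coefficients.

    ``kappa`` is the nodes x modules matrix of node-to-module weight sums and
    ``strength`` the total node strength k_i; MD_i z-scores the within-module
    column of kappa inside each module (population SD; 0 when the SD is 0),
    and PC_i = 1 - sum_s (kappa_is / k_i)^2 (0 for isolated nodes).
    """

    md: np.ndarray
    pc: np.ndarray
    kappa: np.ndarray
    strength: np.ndarray
    partition: Partition
    node_labels: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        labels = self.node_labels or tuple(f"node{i}" for i in range(len(self.md)))
        return pd.DataFrame(
            {
                "roi": labels,
                "module": self.partition.assignment,
                "MD": self.md,
                "PC": self.pc,
                "strength": self.strength,
            }
        )


def node_roles(network, partition: Partition) -> NodeRoleProfile:
    """Intra-module degree (MD) and participation coefficient (PC) per node."""
    weights = _weights_of(network)
    assign = _check_partition(weights, partition)
    onehot = _membership(assign)
    kappa = weights @ onehot
    strength = weights.sum(axis=1)

    own = kappa[np.arange(len(assign)), assign - 1]
    md = np.zeros(len(assign))
    for s in range(1, partition.n_modules + 1):
        members = assign == s
        vals = own[members]
        sd = vals.std()  # population convention
        if sd > 0:
            md[members] = (vals - vals.mean()) / sd

    pc = np.zeros(len(assign))
    positive = strength > 0
    if not positive.all():
        logger.info("%d isolated node(s); PC set to 0 by convention", (~positive).sum())
    frac = kappa[positive] / strength[positive, None]
    pc[positive] = 1.0 - (frac**2).sum(axis=1)

    labels = getattr(network, "node_labels", None)
    return NodeRoleProfile(
        md=md, pc=pc, kappa=kappa, strength=strength, partition=partition, node_labels=labels
    )
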