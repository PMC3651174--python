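"""Group-level structural covariance networks.

A network is the dense symmetric matrix of pairwise Pearson correlations of
residualized thickness across subjects (zero diagonal). The raw signed matrix
is always retained for edge-wise Fisher comparisons; modularity-facing weights
are derived from it by an explicit policy (negative values truncated to zero
by default) and then normalized so the total network weight is 1, which makes
module-connectivity sums comparable across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHT_POLICIES = ("truncate_negative", "absolute", "keep_signed")


@dataclass
class CorrelationNetwork:
    """A weighted covariance network over a fixed node set.

    Attributes
    ----------
    weights : modularity-facing weight matrix (symmetric, zero diagonal).
    signed_r : the raw signed Pearson matrix, always preserved.
    node_labels : ROI abbreviations in canonical order.
    group : group label of the subjects the network was built from.
    n_subjects : sample size used (needed for the Fisher SE).
    policy : the applied weight policy, or ``None`` before one is applied.
    normalized : whether weights were divided by the total network weight.
    """

    weights: np.ndarray
    signed_r: np.ndarray
    node_labels: tuple[str, ...]
    group: str
    n_subjects: int
    policy: str | None = None
    normalized: bool = False

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def total_weight(self) -> float:
        """L: the sum of weights over the upper triangle."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return float(self.weights[iu].sum())

    @property
    def safe_for_modularity(self) -> bool:
        """Newman's weighted Q assumes non-negative weights."""
        return self.policy in ("truncate_negative", "absolute")

    def to_edge_list(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "roi_a": [self.node_labels[i] for i in iu],
                "roi_b": [self.node_labels[j] for j in ju],
                "r_signed": self.signed_r[iu, ju],
                "weight": self.weights[iu, ju],
            }
        )

    def to_graphml(self, path) -> None:
        import networkx as nx

        graph = nx.Graph(group=self.group, n_subjects=self.n_subjects)
        graph.add_nodes_from(self.node_labels)
        for _, row in self.to_edge_list().iterrows():
            graph.add_edge(
                row["roi_a"], row["roi_b"], weight=float(row["weight"]), r=float(row["r_signed"])
            )
        nx.write_graphml(graph, path)


def build_correlation_network(residuals) -> CorrelationNetwork:
    """Pairwise Pearson correlation of residualized thickness across subjects.

    Requires at least 4 subjects (the Fisher transform's standard error,
    1/sqrt(n-3), is undefined below that) and non-constant ROI columns.
    """
    values = residuals.values.to_numpy(dtype=float)
    n_subjects, _ = values.shape
    if n_subjects < 4:
        raise ValueError(f"need at least 4 subjects to correlate, got {n_subjects}")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [residuals.values.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI column(s), correlation undefined: {', '.join(bad)}")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationNetwork(
        weights=corr.copy(),
        signed_r=corr,
        node_labels=tuple(residuals.values.columns),
        group=residuals.group,
        n_subjects=n_subjects,
    )


def apply_weight_policy(network: CorrelationNetwork, policy: str) -> CorrelationNetwork:
    """Derive modularity-facing weights from the signed matrix.

    ``truncate_negative`` zeroes negative correlations, ``absolute`` takes
    magnitudes, ``keep_signed`` passes negatives through (and the resulting
    network is flagged unsafe for Newman Q). The signed matrix is untouched.
    """
    if policy not in WEIGHT_POLICIES:
        raise ValueError(f"unknown weight policy {policy!r}; choose from {WEIGHT_POLICIES}")
    r = network.signed_r
    if policy == "truncate_negative":
        weights = np.where(r > 0, r, 0.0)
    elif policy == "absolute":
        weights = np.abs(r)
    else:
        weights = r.copy()
        if (r < 0).any():
            logger.warning(
                "keep_signed retains negative weights; Newman Q is not well-defined"
            )
    return replace(network, weights=weights, policy=policy, normalized=False)


def normalize_by_total_weight(network: CorrelationNetwork) -> CorrelationNetwork:
    """Divide every weight by L so the upper-triangle sum becomes 1."""
    if network.policy is None:
        raise ValueError("apply a weight policy before normalizing")
    total = network.total_weight
    if total <= 0:
        raise ValueError(f"degenerate network: total weight {total:.3g} <= 0")
    return replace(network, weights=network.weights / total, normalized=True)
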