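"""Group-level inference: random-network null, subject-relabeling permutation
tests, and edge-wise Fisher r-to-z comparison with FDR control.

The random-network null shuffles the multiset of edge weights over the fixed
node-pair set (preserving N, K and the weight multiset, hence L exactly) and
re-scores — or optionally re-optimizes — modularity. The permutation test
reassigns subjects to groups (original sizes preserved) and recomputes any
network statistic through the full residualize -> correlate -> weight-policy ->
normalize pipeline. Edge differences between two groups' correlation matrices
are tested with the classical two-sample Fisher z statistic,
Z = (z_b - z_a) / sqrt(1/(n_a-3) + 1/(n_b-3)), under Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from covmod.cohort import Partition, ThicknessCohort
from covmod.modularity import modularity_q, node_roles, optimize_partition, _q_terms
from covmod.network import (
    CorrelationNetwork,
    apply_weight_policy,
    build_correlation_network,
    normalize_by_total_weight,
)
from covmod.residualize import residualize

logger = logging.getLogger(__name__)


@dataclass
class RandomNullResult:
    """Observed Q against the weight-reshuffled random-network null."""

    observed_q: float
    null_q: np.ndarray
    t_statistic: float
    p_two_sided: float
    p_one_sided: float
    n_reps: int
    seed: int


def _shuffled_network(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    shuffled = np.zeros_like(weights)
    shuffled[iu] = rng.permutation(weights[iu])
    return shuffled + shuffled.T


def random_modularity_null(
    network,
    partition: Partition | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    reoptimize: bool = False,
    n_restarts: int = 10,
) -> RandomNullResult:
    """Compare a network's modularity against weight-reshuffled random networks.

    Each replicate permutes the upper-triangle weight multiset uniformly over
    node pairs and either re-scores Q on the given partition (default) or
    re-optimizes the partition from scratch. Significance is a one-sample
    t-test of the null sample against the observed Q.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    weights = np.asarray(getattr(network, "weights", network), dtype=float)
    if partition is None:
        result = optimize_partition(weights, seed=seed)
        partition, observed_q = result.partition, result.q
    else:
        observed_q = modularity_q(weights, partition)
    rng = np.random.default_rng(seed)
    null_q = np.empty(n_reps)
    for rep in range(n_reps):
        shuffled = _shuffled_network(weights, rng)
        if reoptimize:
            null_q[rep] = optimize_partition(
                shuffled, n_restarts=n_restarts, seed=int(rng.integers(2**31))
            ).q
        else:
            null_q[rep] = modularity_q(shuffled, partition)
    if np.allclose(null_q, observed_q):
        # exchangeable weights: the null is degenerate at the observed value
        t_stat, p_two, p_one = 0.0, 1.0, 1.0
    else:
        t_stat, p_two = stats.ttest_1samp(null_q, observed_q)
        # one-sided: observed larger than the null mean
        p_one = p_two / 2.0 if null_q.mean() < observed_q else 1.0 - p_two / 2.0
        t_stat, p_two = float(t_stat), float(p_two)
    return RandomNullResult(
        observed_q=observed_q,
        null_q=null_q,
        t_statistic=t_stat,
        p_two_sided=p_two,
        p_one_sided=float(p_one),
        n_reps=n_reps,
        seed=seed,
    )


@dataclass
class PermutationResult:
    """Observed group difference(s) with the permutation null distribution.

    For a vector-valued statistic every field is per-component (arrays /
    Series); ``null_diffs`` has one row per permutation.
    """

    observed_diff: np.ndarray | float
    null_diffs: np.ndarray
    p_value: np.ndarray | float
    n_perm: int
    seed: int
    names: tuple[str, ...] | None = None

    def to_frame(self) -> pd.DataFrame:
        obs = np.atleast_1d(np.asarray(self.observed_diff, dtype=float))
        pvals = np.atleast_1d(np.asarray(self.p_value, dtype=float))
        names = self.names or tuple(f"stat{i}" for i in range(obs.size))
        return pd.DataFrame({"measure": names, "observed_diff": obs, "p_value": pvals})


def network_statistic(
    measure: str,
    partition: Partition,
    policy: str = "truncate_negative",
    normalize: bool = True,
    module_id: int | None = None,
    module_pair: tuple[int, int] | None = None,
) -> Callable[[ThicknessCohort], np.ndarray]:
    """A deterministic cohort -> statistic function for permutation testing.

    Runs residualize -> correlate -> weight policy -> normalize, then evaluates
    ``measure`` under the fixed reference partition:

    - ``"Q"``: modularity (scalar);
    - ``"MC"`` / ``"IMC"``: one module's (pair's) connectivity if ``module_id``
      (``module_pair``) is given, else the full per-module (per-pair) vector;
    - ``"MD"`` / ``"PC"``: per-node vectors;
    - ``"all"``: Q, every MC_s, every IMC_st, every MD_i and PC_i concatenated.

    The returned callable carries component names in a ``names`` attribute.
    """
    measure = measure.upper() if measure.lower() != "all" else "all"
    n_mod = partition.n_modules

    def evaluate(cohort: ThicknessCohort) -> np.ndarray:
        resid = residualize(cohort, within_group=True)
        if len(resid) != 1:
            raise ValueError("network_statistic expects a single-group cohort")
        net = build_correlation_network(next(iter(resid.values())))
        net = apply_weight_policy(net, policy)
        if normalize:
            net = normalize_by_total_weight(net)
        weights = net.weights
        assign = partition.as_array()
        parts: list[np.ndarray] = []
        if measure in ("Q", "all"):
            parts.append(np.array([modularity_q(weights, partition)]))
        if measure in ("MC", "all"):
            l_s, _, _ = _q_terms(weights, assign)
            mc = l_s if module_id is None or measure == "all" else l_s[[module_id - 1]]
            parts.append(np.atleast_1d(mc))
        if measure in ("IMC", "all"):
            vals = []
            pairs = (
                [module_pair]
                if module_pair is not None and measure != "all"
                else [(s, t) for s in range(1, n_mod + 1) for t in range(s + 1, n_mod + 1)]
            )
            for s, t in pairs:
                vals.append(weights[np.ix_(assign == s, assign == t)].sum())
            parts.append(np.array(vals))
        if measure in ("MD", "PC", "all"):
            roles = node_roles(weights, partition)
            if measure in ("MD", "all"):
                parts.append(roles.md)
            if measure in ("PC", "all"):
                parts.append(roles.pc)
        if not parts:
            raise ValueError(f"unknown measure {measure!r}")
        return np.concatenate(parts)

    names: list[str] = []
    if measure in ("Q", "all"):
        names.append("Q")
    if measure in ("MC", "all"):
        if module_id is not None and measure != "all":
            names.append(f"MC_{module_id}")
        else:
            names.extend(f"MC_{s}" for s in range(1, n_mod + 1))
    if measure in ("IMC", "all"):
        if module_pair is not None and measure != "all":
            names.append(f"IMC_{module_pair[0]}_{module_pair[1]}")
        else:
            names.extend(
                f"IMC_{s}_{t}"
                for s in range(1, n_mod + 1)
                for t in range(s + 1, n_mod + 1)
            )
    if measure in ("MD", "all"):
        names.extend(f"MD_{i}" for i in range(partition.n_nodes))
    if measure in ("PC", "all"):
        names.extend(f"PC_{i}" for i in range(partition.n_nodes))
    evaluate.names = tuple(names)  # type: ignore[attr-defined]
    return evaluate


def permutation_group_test(
    cohort_a: ThicknessCohort,
    cohort_b: ThicknessCohort,
    statistic: Callable[[ThicknessCohort], np.ndarray | float],
    n_perm: int = 10_000,
    seed: int = 0,
    add_one: bool = True,
) -> PermutationResult:
    """Two-tailed subject-relabeling permutation test of stat(a) - stat(b).

    Subjects are pooled and reassigned to two groups of the original sizes;
    the statistic is recomputed for both permuted groups. With ``add_one``
    (default) p = (1 + #{|null| >= |obs|}) / (n_perm + 1), guaranteeing p > 0;
    ``add_one=False`` gives the plain u / n_perm proportion.
    """
    n_a, n_b = cohort_a.n_subjects, cohort_b.n_subjects
    pooled_cov = pd.concat(
        [cohort_a.covariates, cohort_b.covariates], ignore_index=True
    )
    pooled_thk = pd.concat(
        [cohort_a.thickness, cohort_b.thickness], ignore_index=True
    )
    pooled = ThicknessCohort(
        covariates=pooled_cov, thickness=pooled_thk, atlas=cohort_a.atlas
    )

    def subcohort(indices: np.ndarray, label: str) -> ThicknessCohort:
        covariates = pooled.covariates.iloc[indices].reset_index(drop=True).copy()
        covariates["group"] = label  # permuted membership defines the group
        return ThicknessCohort(
            covariates=covariates,
            thickness=pooled.thickness.iloc[indices].reset_index(drop=True),
            atlas=pooled.atlas,
        )

    def stat_of(indices_a: np.ndarray, indices_b: np.ndarray):
        sub_a = subcohort(indices_a, "a")
        sub_b = subcohort(indices_b, "b")
        return np.atleast_1d(np.asarray(statistic(sub_a), dtype=float)) - np.atleast_1d(
            np.asarray(statistic(sub_b), dtype=float)
        )

    observed = stat_of(np.arange(n_a), np.arange(n_a, n_a + n_b))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for rep in range(n_perm):
        order = rng.permutation(n_a + n_b)
        diff = stat_of(order[:n_a], order[n_a:])
        if not np.all(np.isfinite(diff)):
            raise FloatingPointError(
                f"statistic returned a non-finite value at permutation {rep}"
            )
        null[rep] = diff
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    if add_one:
        pvals = (1.0 + exceed) / (n_perm + 1.0)
    else:
        pvals = exceed / float(n_perm)
    names = getattr(statistic, "names", None)
    scalar = observed.size == 1 and names is None
    return PermutationResult(
        observed_diff=float(observed[0]) if scalar else observed,
        null_diffs=null,
        p_value=float(pvals[0]) if scalar else pvals,
        n_perm=n_perm,
        seed=seed,
        names=tuple(names) if names else None,
    )


def fisher_z_statistic(r_a: float, r_b: float, n_a: int, n_b: int) -> float:
    """Two-sample Fisher z statistic Z = (z_b - z_a)/sqrt(1/(n_a-3)+1/(n_b-3)).

    With group a the case group, a correlation decreased in a gives Z > 0.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("Fisher comparison needs more than 3 subjects per group")
    z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    return float((z_b - z_a) / se)


def fisher_edge_comparison(
    net_a: CorrelationNetwork, net_b: CorrelationNetwork, q: float = 0.01
) -> pd.DataFrame:
    """Edge-wise Fisher r-to-z comparison of two groups' correlation matrices.

    Returns one row per node pair with the signed correlations, their Fisher
    transforms, the Z statistic (sign: b minus a, so correlations decreased in
    group a are positive), the two-tailed normal p, and a BH-FDR rejection
    flag at level ``q``. Edges with |r| = 1 (infinite z) are flagged
    ``degenerate`` and excluded from the FDR family with a warning.
    """
    if net_a.node_labels != net_b.node_labels:
        raise ValueError("networks are over different node sets")
    if net_a.n_subjects <= 3 or net_b.n_subjects <= 3:
        raise ValueError("Fisher comparison needs more than 3 subjects per group")
    n = net_a.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    r_a = net_a.signed_r[iu, ju]
    r_b = net_b.signed_r[iu, ju]
    with np.errstate(divide="ignore"):
        z_a = np.arctanh(r_a)
        z_b = np.arctanh(r_b)
    se = np.sqrt(1.0 / (net_a.n_subjects - 3) + 1.0 / (net_b.n_subjects - 3))
    z_stat = (z_b - z_a) / se
    degenerate = ~np.isfinite(z_stat)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} edge(s) with |r| = 1 excluded from the FDR family",
            stacklevel=2,
        )
    pvals = np.full(z_stat.shape, np.nan)
    pvals[~degenerate] = 2.0 * stats.norm.sf(np.abs(z_stat[~degenerate]))
    flags = np.zeros(z_stat.shape, dtype=bool)
    flags[~degenerate] = bh_fdr(pvals[~degenerate], q)
    return pd.DataFrame(
        {
            "roi_a": [net_a.node_labels[i] for i in iu],
            "roi_b": [net_a.node_labels[j] for j in ju],
            "r_a": r_a,
            "r_b": r_b,
            "z_a": z_a,
            "z_b": z_b,
            "Z": z_stat,
            "p": pvals,
            "fdr_significant": flags,
            "degenerate": degenerate,
        }
    )


def bh_fdr(p_values, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject
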