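"""End-to-end orchestration: cohort -> networks -> modules -> inference tables.

The analysis follows the baseline-partition strategy: the control group's
optimal modular organization is taken as the reference, imposed on the case
group's network, and every module-level comparison (Q, MC, IMC, MD, PC) is
made under that single partition, with subject-relabeling permutation
p-values. Edge-wise correlation differences are tested with Fisher r-to-z
under BH-FDR. A run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version
from covmod.cohort import Partition, ThicknessCohort, read_cohort, write_partition
from covmod.inference import (
    PermutationResult,
    RandomNullResult,
    fisher_edge_comparison,
    network_statistic,
    permutation_group_test,
    random_modularity_null,
)
from covmod.modularity import node_roles, optimize_partition
from covmod.network import apply_weight_policy, build_correlation_network, normalize_by_total_weight
from covmod.residualize import residualize
from covmod.synth import CohortSpec, make_autism_like_pair

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run.

    Exactly one of ``cohort_path`` (a cohort CSV/TSV containing both groups)
    or ``synthetic`` (a CohortSpec mapping; a matched case/control pair is
    generated) must be set.
    """

    cohort_path: str | None = None
    synthetic: dict | None = None
    case_label: str = "autism"
    control_label: str = "control"
    weight_policy: str = "truncate_negative"
    within_group_residualization: bool = True
    n_restarts: int = 100
    n_perm: int = 10_000
    n_random: int = 10_000
    reoptimize_null: bool = False
    q: float = 0.01
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.synthetic is None):
            raise ValueError("set exactly one of cohort_path or synthetic")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class AnalysisResult:
    """All tables produced by one run; ``write`` persists them as CSV/JSON."""

    config: AnalysisConfig
    control_partition: Partition
    metrics: pd.DataFrame
    node_role_table: pd.DataFrame
    edge_comparison: pd.DataFrame
    random_nulls: dict[str, RandomNullResult]
    permutation: PermutationResult
    run_log: dict = field(default_factory=dict)

    def write(self, output_dir) -> None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            for name, frame in (
                ("metrics.csv", self.metrics),
                ("node_roles.csv", self.node_role_table),
                ("edge_comparison.csv", self.edge_comparison),
            ):
                path = outdir / name
                frame.to_csv(path, index=False, float_format="%.10g")
                written.append(path)
            path = outdir / "control_partition.csv"
            write_partition(self.control_partition, path)
            written.append(path)
            path = outdir / "run_log.json"
            with open(path, "w") as fh:
                json.dump(self.run_log, fh, indent=2, sort_keys=True)
            written.append(path)
        except Exception:
            for path in written:  # no partial result directories
                path.unlink(missing_ok=True)
            raise


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return decorate


@_stage("load")
def _load_cohort(config: AnalysisConfig) -> ThicknessCohort:
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        spec = CohortSpec.from_dict({**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        case, control = make_autism_like_pair(spec)
        cohort = ThicknessCohort(
            covariates=pd.concat([case.covariates, control.covariates], ignore_index=True),
            thickness=pd.concat([case.thickness, control.thickness], ignore_index=True),
            atlas=case.atlas,
        )
    sizes = cohort.group_sizes()
    for label in (config.case_label, config.control_label):
        if label not in sizes:
            raise ValueError(f"cohort has no subjects labelled {label!r}; groups: {sizes}")
    logger.info("cohort loaded: %s", sizes)
    return cohort


def run_full_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Execute the full analysis; returns every result surface in memory.

    Stages: residualize per group -> correlation networks -> weight policy +
    total-weight normalization -> optimize the control partition -> impose it
    on the case network -> permutation tests on (Q, MC, IMC, MD, PC) ->
    random-network modularity nulls -> edge-wise Fisher table with FDR.
    All group differences are oriented case minus control.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    cohort = _load_cohort(config)
    case = cohort.subset(config.case_label)
    control = cohort.subset(config.control_label)

    resid = _stage("residualize")(residualize)(cohort, config.within_group_residualization)

    @_stage("network")
    def _network(group):
        net = build_correlation_network(resid[group])
        net = apply_weight_policy(net, config.weight_policy)
        return normalize_by_total_weight(net)

    net_case = _network(config.case_label)
    net_control = _network(config.control_label)

    control_result = _stage("optimize")(optimize_partition)(
        net_control, n_restarts=config.n_restarts, seed=int(seeds[0])
    )
    partition = control_result.partition

    @_stage("permutation")
    def _permutation():
        stat = network_statistic("all", partition, policy=config.weight_policy)
        return permutation_group_test(
            case, control, stat, n_perm=config.n_perm, seed=int(seeds[1])
        )

    permutation = _permutation()

    @_stage("random-null")
    def _nulls():
        out = {}
        for label, net, part in (
            (config.case_label, net_case, None),
            (config.control_label, net_control, partition),
        ):
            out[label] = random_modularity_null(
                net,
                partition=part,
                n_reps=config.n_random,
                seed=int(seeds[2]),
                reoptimize=config.reoptimize_null,
            )
        return out

    nulls = _nulls()

    @_stage("metrics")
    def _tables():
        stat = network_statistic("all", partition, policy=config.weight_policy)
        vals_case = stat(case.with_groups([config.case_label] * case.n_subjects))
        vals_control = stat(control.with_groups([config.control_label] * control.n_subjects))
        names = list(stat.names)
        pvals = np.atleast_1d(np.asarray(permutation.p_value))
        table = pd.DataFrame(
            {
                "measure": names,
                "case": vals_case,
                "control": vals_control,
                "diff_case_minus_control": vals_case - vals_control,
                "perm_p": pvals,
            }
        )
        labels = list(net_control.node_labels)
        table["roi"] = [
            labels[int(m.split("_")[1])] if m.startswith(("MD_", "PC_")) else ""
            for m in names
        ]
        global_rows = table[~table["measure"].str.startswith(("MD_", "PC_"))]
        roles_case = node_roles(net_case, partition)
        roles_control = node_roles(net_control, partition)
        node_table = pd.DataFrame(
            {
                "roi": labels,
                "module": partition.assignment,
                "MD_case": roles_case.md,
                "MD_control": roles_control.md,
                "MD_perm_p": table.loc[table["measure"].str.startswith("MD_"), "perm_p"].to_numpy(),
                "PC_case": roles_case.pc,
                "PC_control": roles_control.pc,
                "PC_perm_p": table.loc[table["measure"].str.startswith("PC_"), "perm_p"].to_numpy(),
            }
        )
        return global_rows.drop(columns="roi"), node_table

    metrics, node_table = _tables()

    @_stage("fisher")
    def _edges():
        table = fisher_edge_comparison(net_case, net_control, q=config.q)
        assign = partition.as_array()
        labels = list(net_control.node_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        table["module_a"] = [assign[index[r]] for r in table["roi_a"]]
        table["module_b"] = [assign[index[r]] for r in table["roi_b"]]
        return table.rename(columns={"r_a": "r_case", "r_b": "r_control"})

    edges = _edges()

    run_log = {
        "package_version": _pkg_version("covmod"),
        "seed": config.seed,
        "stage_seeds": [int(s) for s in seeds],
        "group_sizes": cohort.group_sizes(),
        "weight_policy": config.weight_policy,
        "within_group_residualization": config.within_group_residualization,
        "n_restarts": config.n_restarts,
        "n_perm": config.n_perm,
        "n_random": config.n_random,
        "reoptimize_null": config.reoptimize_null,
        "fdr_q": config.q,
        "control_partition_n_modules": partition.n_modules,
        "control_partition_q": control_result.q,
        "case_q_under_control_partition": float(metrics.loc[metrics["measure"] == "Q", "case"].iloc[0]),
        "random_null": {
            label: {
                "observed_q": res.observed_q,
                "null_q_mean": float(res.null_q.mean()),
                "p_one_sided": res.p_one_sided,
                "p_two_sided": res.p_two_sided,
            }
            for label, res in nulls.items()
        },
        "n_fdr_significant_edges": int(edges["fdr_significant"].sum()),
        "n_decreased_in_case": int((edges["fdr_significant"] & (edges["Z"] > 0)).sum()),
        "n_increased_in_case": int((edges["fdr_significant"] & (edges["Z"] < 0)).sum()),
        "sign_convention": "all differences are case minus control; Z > 0 means the correlation is lower in the case group",
    }

    result = AnalysisResult(
        config=config,
        control_partition=partition,
        metrics=metrics,
        node_role_table=node_table,
        edge_comparison=edges,
        random_nulls=nulls,
        permutation=permutation,
        run_log=run_log,
    )
    if config.output_dir is not None:
        _stage("write")(result.write)(config.output_dir)
    return result
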