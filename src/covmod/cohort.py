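"""Cohort tables and node partitions: in-memory containers and CSV/TSV I/O.

A cohort file has one row per subject with columns ``subject_id``, ``group``,
``age``, ``sex`` followed by one thickness column (mm) per ROI, named by the
atlas abbreviations. Sex is stored as ``M``/``F`` in files and coded 1/0
internally. A partition file is a two-column table (roi, module_id).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from covmod.atlas import ROIAtlas, builtin_dk_atlas

_COVARIATE_COLUMNS = ["subject_id", "group", "age", "sex"]
_SEX_CODES = {"M": 1, "F": 0}


class SchemaError(ValueError):
    """Input table does not match the expected cohort/partition schema."""


@dataclass
class ThicknessCohort:
    """Per-subject covariates plus regional mean cortical thickness (mm).

    Attributes
    ----------
    covariates : pandas.DataFrame
        Columns ``subject_id``, ``group``, ``age`` (years), ``sex`` (1=male,
        0=female), one row per subject.
    thickness : pandas.DataFrame
        Subjects x ROIs matrix of mean thickness values in mm; columns in
        canonical atlas order, row index aligned with ``covariates``.
    atlas : ROIAtlas
    """

    covariates: pd.DataFrame
    thickness: pd.DataFrame
    atlas: ROIAtlas = field(default_factory=builtin_dk_atlas)

    def __post_init__(self) -> None:
        if list(self.thickness.columns) != self.atlas.labels:
            raise SchemaError("thickness columns must follow atlas order")
        if len(self.covariates) != len(self.thickness):
            raise SchemaError("covariates and thickness row counts differ")
        values = self.thickness.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise SchemaError("thickness contains missing or non-finite values")
        if (values < 0).any():
            raise SchemaError("thickness contains negative values")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def n_rois(self) -> int:
        return self.thickness.shape[1]

    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        return list(dict.fromkeys(self.covariates["group"]))

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.covariates["group"] == g).sum()) for g in self.groups()}

    def subset(self, group: str) -> "ThicknessCohort":
        """The sub-cohort with the given group label."""
        mask = (self.covariates["group"] == group).to_numpy()
        if not mask.any():
            raise KeyError(f"no subjects with group label {group!r}")
        return ThicknessCohort(
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            thickness=self.thickness.loc[mask].reset_index(drop=True),
            atlas=self.atlas,
        )

    def with_groups(self, labels) -> "ThicknessCohort":
        """A copy with reassigned group labels (used by permutation tests)."""
        covariates = self.covariates.copy()
        covariates["group"] = list(labels)
        return ThicknessCohort(covariates=covariates, thickness=self.thickness, atlas=self.atlas)


@dataclass(frozen=True)
class Partition:
    """Non-overlapping assignment of network nodes to modules 1..N_m.

    ``assignment[i]`` is the module id of node ``i`` (canonical atlas order).
    Module ids must be contiguous from 1 with no empty module.
    """

    assignment: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment))
        if not self.assignment:
            raise ValueError("empty partition")
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(
                f"module ids must be contiguous 1..N_m with no empty module, got {ids}"
            )

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        """Build from arbitrary hashable labels, canonicalized so that module 1
        is the module of the lowest-index node, module 2 the next unseen, etc."""
        mapping: dict = {}
        assignment = []
        for lab in labels:
            if lab not in mapping:
                mapping[lab] = len(mapping) + 1
            assignment.append(mapping[lab])
        return cls(assignment=tuple(assignment))

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    @property
    def n_modules(self) -> int:
        return max(self.assignment)

    def members(self, module_id: int) -> np.ndarray:
        """Node indices (0-based) belonging to a module."""
        if not 1 <= module_id <= self.n_modules:
            raise KeyError(f"unknown module id {module_id}")
        return np.flatnonzero(np.asarray(self.assignment) == module_id)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)


def _detect_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    return "\t" if sample.count("\t") > sample.count(",") else ","


def read_cohort(path, atlas: ROIAtlas | None = None) -> ThicknessCohort:
    """Read and validate a cohort CSV/TSV, reordering ROI columns to atlas order.

    Raises
    ------
    SchemaError
        If a required or atlas ROI column is absent, an unknown column is
        present, or a thickness value fails to parse (the error names the
        column / 1-based data row).
    """
    path = Path(path)
    atlas = atlas or builtin_dk_atlas()
    frame = pd.read_csv(path, sep=_detect_delimiter(path), dtype=str)
    for col in _COVARIATE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    expected = set(atlas.labels)
    present = [c for c in frame.columns if c not in _COVARIATE_COLUMNS]
    missing = expected.difference(present)
    if missing:
        raise SchemaError(f"missing ROI column(s): {', '.join(sorted(missing))}")
    unknown = set(present).difference(expected)
    if unknown:
        raise SchemaError(f"unknown ROI column(s): {', '.join(sorted(unknown))}")

    thickness = pd.DataFrame(index=frame.index)
    for col in atlas.labels:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise SchemaError(f"non-numeric thickness in column {col!r} at data row {row}")
        thickness[col] = parsed.astype(float)

    sex_raw = frame["sex"].str.strip().str.upper()
    if not sex_raw.isin(_SEX_CODES).all():
        bad = sex_raw[~sex_raw.isin(_SEX_CODES)].iloc[0]
        raise SchemaError(f"sex must be M or F, got {bad!r}")
    covariates = pd.DataFrame(
        {
            "subject_id": frame["subject_id"],
            "group": frame["group"],
            "age": pd.to_numeric(frame["age"]),
            "sex": sex_raw.map(_SEX_CODES).astype(int),
        }
    )
    return ThicknessCohort(covariates=covariates, thickness=thickness, atlas=atlas)


def write_cohort(cohort: ThicknessCohort, path, sep: str = ",") -> None:
    """Write a cohort in the layout ``read_cohort`` expects (sex as M/F)."""
    out = cohort.covariates.copy()
    out["sex"] = out["sex"].map({1: "M", 0: "F"})
    out = pd.concat([out, cohort.thickness], axis=1)
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_partition(path, atlas: ROIAtlas | None = None) -> Partition:
    """Read a (roi, module_id) table into a Partition in atlas node order."""
    atlas = atlas or builtin_dk_atlas()
    path = Path(path)
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=_detect_delimiter(path))
        header = next(reader)
        if len(header) < 2:
            raise SchemaError("partition file needs two columns (roi, module_id)")
        for row in reader:
            if not row:
                continue
            roi, module_id = row[0].strip(), int(row[1])
            if roi in mapping:
                raise SchemaError(f"ROI {roi!r} listed twice in partition file")
            mapping[roi] = module_id
    missing = [lab for lab in atlas.labels if lab not in mapping]
    if missing:
        raise SchemaError(f"partition missing ROI(s): {', '.join(missing)}")
    unknown = sorted(set(mapping).difference(atlas.labels))
    if unknown:
        raise SchemaError(f"partition has unknown ROI(s): {', '.join(unknown)}")
    return Partition.from_labels([mapping[lab] for lab in atlas.labels])


def write_partition(partition: Partition, path, atlas: ROIAtlas | None = None) -> None:
    atlas = atlas or builtin_dk_atlas()
    if partition.n_nodes != atlas.n_rois:
        raise ValueError("partition size does not match atlas")
    frame = pd.DataFrame({"roi": atlas.labels, "module_id": partition.assignment})
    frame.to_csv(path, index=False)
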