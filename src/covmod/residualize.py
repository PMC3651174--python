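"""Covariate removal before correlation: per-ROI ordinary least squares.

Each ROI's thickness is regressed, across subjects, on an intercept, the
subject's global mean thickness (mean over all ROIs), age, sex and the
age x sex interaction; the residuals replace the raw values. Fitting is done
separately per group by default because the correlation networks are built
per group; a pooled mode fits one design over all subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from covmod.cohort import ThicknessCohort

logger = logging.getLogger(__name__)

_DESIGN_TERMS = ("intercept", "global_mean", "age", "sex", "age_x_sex")
_RANK_TOL = 1e-9


@dataclass
class ResidualMatrix:
    """Subjects x ROIs residual thickness (mm) for one group, plus the fitted
    coefficients (ROIs x design terms) for audit."""

    values: pd.DataFrame
    group: str
    coefficients: pd.DataFrame
    dropped_terms: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False, float_format="%.12g")


def _design_matrix(
    cohort: ThicknessCohort, include_global_mean: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Full design with rank-deficient columns dropped (logged, left-to-right)."""
    thickness = cohort.thickness.to_numpy(dtype=float)
    age = cohort.covariates["age"].to_numpy(dtype=float)
    sex = cohort.covariates["sex"].to_numpy(dtype=float)
    columns = {
        "intercept": np.ones(len(age)),
        "global_mean": thickness.mean(axis=1),
        "age": age,
        "sex": sex,
        "age_x_sex": age * sex,
    }
    kept: list[str] = []
    dropped: list[str] = []
    design = np.empty((len(age), 0))
    terms = [t for t in _DESIGN_TERMS if include_global_mean or t != "global_mean"]
    for term in terms:
        candidate = np.column_stack([design, columns[term]])
        s = np.linalg.svd(candidate, compute_uv=False)
        if s[-1] > _RANK_TOL * max(s[0], 1.0):
            design = candidate
            kept.append(term)
        else:
            dropped.append(term)
            logger.warning(
                "design term %r is collinear with earlier terms and was dropped", term
            )
    return design, kept, dropped


def _fit_group(
    cohort: ThicknessCohort, group: str, include_global_mean: bool = True
) -> ResidualMatrix:
    design, kept, dropped = _design_matrix(cohort, include_global_mean)
    if cohort.n_subjects < design.shape[1] + 2:
        raise ValueError(
            f"group {group!r} has {cohort.n_subjects} subjects; need at least "
            f"{design.shape[1] + 2} to fit {design.shape[1]} design terms"
        )
    thickness = cohort.thickness.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, thickness, rcond=None)
    residuals = thickness - design @ beta
    coefficients = pd.DataFrame(beta.T, index=cohort.thickness.columns, columns=kept)
    return ResidualMatrix(
        values=pd.DataFrame(residuals, columns=cohort.thickness.columns),
        group=group,
        coefficients=coefficients,
        dropped_terms=tuple(dropped),
    )


def residualize(
    cohort: ThicknessCohort,
    within_group: bool = True,
    include_global_mean: bool = True,
) -> dict[str, ResidualMatrix]:
    """Remove covariate effects from each ROI; returns residuals per group.

    With ``within_group=True`` (default) the regression is fitted separately
    in each group; otherwise a single pooled design is fitted over all
    subjects and the pooled residuals are split by group afterwards.
    ``include_global_mean=False`` drops the subject global-mean covariate:
    global-mean correction deliberately removes shared variance and therefore
    attenuates all inter-regional correlations, which matters when comparing
    against a known planted structure.
    """
    groups = cohort.groups()
    if within_group:
        return {g: _fit_group(cohort.subset(g), g, include_global_mean) for g in groups}
    pooled = _fit_group(cohort, "pooled", include_global_mean)
    out: dict[str, ResidualMatrix] = {}
    for g in groups:
        mask = (cohort.covariates["group"] == g).to_numpy()
        out[g] = ResidualMatrix(
            values=pooled.values.loc[mask].reset_index(drop=True),
            group=g,
            coefficients=pooled.coefficients,
            dropped_terms=pooled.dropped_terms,
        )
    return out
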