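"""Individualized structural covariance network (SCN) construction.

Pipeline, for a case-control morphometry design:

1. residualize regional volumes against covariates, with the ordinary
   least-squares fit estimated on the control group only and applied to
   every subject (the controls define the normative reference);
2. build the group SCN as the region-by-region Pearson correlation matrix
   of control residuals;
3. record the control reference (per-region mean and SD of residuals);
4. for each subject, z-score residuals against the reference and form the
   inter-regional effect-size-difference (ESD) weight matrix
   ``W[j, k] = exp(-|z_j - z_k|)`` — 1 when the subject deviates
   identically at the two regions, decaying smoothly as the deviations
   diverge (the transform is pluggable, see ``ESD_TRANSFORMS``);
5. individualize: element-wise product of W with the group SCN.

Because W lies in (0, 1], every individualized edge keeps the sign of the
group edge and can only shrink toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .synthetic_data import CohortTable

#: Named ESD -> weight transforms; both are bounded in (0, 1] and equal 1 at 0.
ESD_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exponential": lambda d: np.exp(-d),
    "reciprocal": lambda d: 1.0 / (1.0 + d),
}


@dataclass
class ResidualTable:
    """Covariate-adjusted volumes for a set of subjects (one row each)."""

    subject_ids: np.ndarray
    groups: np.ndarray
    residuals: np.ndarray           # n_subjects x n_regions
    region_labels: list[str]

    def __post_init__(self) -> None:
        if self.residuals.shape != (len(self.subject_ids), len(self.region_labels)):
            raise ValueError("residual matrix shape does not match ids/labels")

    def subset(self, mask: np.ndarray) -> "ResidualTable":
        return ResidualTable(self.subject_ids[mask], self.groups[mask],
                             self.residuals[mask], self.region_labels)

    def row(self, subject_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.subject_ids == subject_id)
        if len(idx) != 1:
            raise KeyError(f"subject {subject_id!r} not found")
        return self.residuals[idx[0]]


@dataclass
class ControlReference:
    """Normative per-region statistics of the control residuals."""

    mean: np.ndarray
    sd: np.ndarray                  # sample SD, denominator n-1
    fit_coefficients: np.ndarray    # (1 + n_covariates) x n_regions, row 0 = intercept
    covariates: list[str]
    region_labels: list[str]

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            bad = self.region_labels[int(np.argmin(self.sd))]
            raise ValueError(f"control residual SD is not positive for region {bad!r}")


@dataclass
class GroupSCN:
    """Region-by-region Pearson correlation matrix of control residuals."""

    matrix: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("group SCN matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("group SCN matrix must be symmetric")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.region_labels,
                     columns=self.region_labels).to_csv(path)


@dataclass
class IndividualSCN:
    """Per-subject weighted network: ``matrix = weight_matrix * group SCN``."""

    subject_id: str
    weight_matrix: np.ndarray
    matrix: np.ndarray
    region_labels: list[str]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.region_labels,
                     columns=self.region_labels).to_csv(path)


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    # QR diagonal reveals which columns are (nearly) linear combinations of
    # earlier ones, so the error can name the offenders.
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = [names[i] for i in np.flatnonzero(diag / scale < 1e-10)]
    if bad:
        raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")


def residualize(cohort: CohortTable,
                covariates: list[str] = ("age", "sex", "tiv"),
                ) -> tuple[ResidualTable, np.ndarray]:
    """OLS-adjust volumes for covariates using control-group coefficients.

    Per region, volume is regressed on the covariates (plus intercept) over
    the CONTROL subjects; the fitted coefficients are then used to compute
    ``residual = observed - predicted`` for every subject in every group.

    Returns the residual table for the whole cohort and the coefficient
    matrix (row 0 the intercept, then one row per covariate).
    """
    covariates = list(covariates)
    controls = cohort.group_mask("control")
    n_ctrl = int(controls.sum())
    if n_ctrl < len(covariates) + 2:
        raise ValueError(
            f"need at least {len(covariates) + 2} control subjects to fit "
            f"{len(covariates)} covariates; got {n_ctrl}")

    x_all = np.column_stack([np.ones(cohort.n_subjects),
                             cohort.covariate_matrix(covariates)])
    names = ["intercept"] + covariates
    _check_full_rank(x_all[controls], names)

    y_ctrl = cohort.volumes[controls]
    coef, *_ = np.linalg.lstsq(x_all[controls], y_ctrl, rcond=None)
    residuals = cohort.volumes - x_all @ coef
    table = ResidualTable(subject_ids=cohort.subject_ids,
                          groups=cohort.groups,
                          residuals=residuals,
                          region_labels=list(cohort.region_labels))
    return table, coef


def build_group_scn(controls: ResidualTable) -> GroupSCN:
    """Pearson-correlate control residuals across subjects for each region pair."""
    res = controls.residuals
    if res.shape[0] < 3:
        raise ValueError("need at least 3 control subjects for a group SCN")
    sd = res.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = controls.region_labels[int(np.argmin(sd))]
        raise ValueError(f"zero residual variance for region {bad!r}")
    matrix = np.corrcoef(res, rowvar=False)
    np.fill_diagonal(matrix, 1.0)
    return GroupSCN(matrix=matrix, region_labels=list(controls.region_labels))


def control_reference(controls: ResidualTable,
                      fit_coefficients: np.ndarray | None = None,
                      covariates: list[str] | None = None) -> ControlReference:
    """Per-region sample mean and SD (denominator n-1) of control residuals."""
    res = controls.residuals
    if res.shape[0] < 2:
        raise ValueError("need at least 2 control subjects for reference statistics")
    sd = res.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = controls.region_labels[int(np.argmin(sd))]
        raise ValueError(f"zero residual SD for region {bad!r}")
    n_regions = res.shape[1]
    if fit_coefficients is None:
        fit_coefficients = np.zeros((1, n_regions))
    return ControlReference(mean=res.mean(axis=0), sd=sd,
                            fit_coefficients=fit_coefficients,
                            covariates=list(covariates or []),
                            region_labels=list(controls.region_labels))


def individual_weight_matrix(residuals: np.ndarray,
                             ref: ControlReference,
                             transform: str = "exponential") -> np.ndarray:
    """ESD weight matrix W for one subject's residual vector.

    ``z = (residual - ref.mean) / ref.sd`` per region; the inter-regional
    effect-size difference is ``|z_j - z_k|`` and ``W = transform(ESD)``,
    symmetric with unit diagonal, entries in (0, 1].
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.shape != ref.mean.shape:
        raise ValueError(
            f"subject has {residuals.shape} residuals, reference expects "
            f"{ref.mean.shape}")
    try:
        func = ESD_TRANSFORMS[transform]
    except KeyError:
        raise ValueError(f"unknown ESD transform {transform!r}; "
                         f"available: {sorted(ESD_TRANSFORMS)}") from None
    z = (residuals - ref.mean) / ref.sd
    esd = np.abs(z[:, None] - z[None, :])
    w = func(esd)
    np.fill_diagonal(w, 1.0)
    return w


def individualize(weight: np.ndarray, group_scn: GroupSCN,
                  subject_id: str) -> IndividualSCN:
    """Element-wise product of the subject weight matrix and the group SCN."""
    if weight.shape != group_scn.matrix.shape:
        raise ValueError(
            f"weight matrix shape {weight.shape} does not match group SCN "
            f"{group_scn.matrix.shape}")
    return IndividualSCN(subject_id=subject_id,
                         weight_matrix=weight,
                         matrix=weight * group_scn.matrix,
                         region_labels=list(group_scn.region_labels))


def build_individual_scns(residual_table: ResidualTable,
                          ref: ControlReference,
                          group_scn: GroupSCN,
                          subjects: np.ndarray | None = None,
                          transform: str = "exponential") -> list[IndividualSCN]:
    """Individualized SCNs for ``subjects`` (default: all rows in the table)."""
    if subjects is None:
        subjects = residual_table.subject_ids
    out = []
    for sid in subjects:
        w = individual_weight_matrix(residual_table.row(sid), ref, transform)
        out.append(individualize(w, group_scn, sid))
    return out
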