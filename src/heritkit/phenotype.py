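"""Regional cortical phenotypes: parcel aggregation, global normalization,
and covariate residualization.

Vertex-level surface-area measures are collapsed to regional values through
a fuzzy parcellation (partial membership weights per vertex), divided by
each subject's total surface area so effects are region-specific rather
than global, and then residualized on age (natural cubic spline basis, so
nonlinear lifespan trends are absorbed), sex, an age-spline x sex
interaction, and categorical scanner / diagnosis / cohort indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .datatypes import HeritkitError

__all__ = ["ParcelDefinition", "parcel_area", "normalize_global",
           "natural_spline_basis", "residualize"]


@dataclass
class ParcelDefinition:
    """Vertex x region partial-membership weights."""

    membership_weights: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.membership_weights = np.asarray(self.membership_weights, dtype=float)
        v, r = self.membership_weights.shape
        if len(self.region_names) != r:
            raise HeritkitError("region_names length must match weight columns")
        if (self.membership_weights < 0).any():
            raise HeritkitError("membership weights must be nonnegative")
        if (self.membership_weights.sum(axis=1) > 1 + 1e-8).any():
            raise HeritkitError("per-vertex memberships must sum to <= 1")
        totals = self.membership_weights.sum(axis=0)
        if (totals <= 0).any():
            empty = [self.region_names[i] for i in np.flatnonzero(totals <= 0)]
            raise HeritkitError(f"regions with zero total weight: {empty}")


def parcel_area(vertex_areas: np.ndarray, parcels: ParcelDefinition,
                mode: str = "average") -> np.ndarray:
    """Per-region area from vertex areas.

    ``mode='average'`` (default) returns the membership-weighted average
    ``sum_v w_vr area_v / sum_v w_vr``; ``mode='sum'`` returns the weighted
    sum.  Accepts one subject (1-D) or a subjects x vertices matrix.
    """
    areas = np.asarray(vertex_areas, dtype=float)
    squeeze = areas.ndim == 1
    areas = np.atleast_2d(areas)
    w = parcels.membership_weights
    if areas.shape[1] != w.shape[0]:
        raise HeritkitError(
            f"{areas.shape[1]} vertex areas but weights are for {w.shape[0]} vertices"
        )
    out = areas @ w
    if mode == "average":
        out = out / w.sum(axis=0)
    elif mode != "sum":
        raise HeritkitError(f"unknown mode {mode!r}")
    return out[0] if squeeze else out


def normalize_global(region_values: np.ndarray, total_area) -> np.ndarray:
    """Divide each region value by the subject's total surface area."""
    total = np.asarray(total_area, dtype=float)
    if (total <= 0).any():
        raise HeritkitError("total surface area must be positive")
    values = np.asarray(region_values, dtype=float)
    if values.ndim == 2:
        return values / total[:, None] if total.ndim == 1 else values / total
    return values / total


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots).

    The truncated-power construction with ``df + 1`` knots at quantiles of
    ``x``: columns are ``x`` itself plus ``df - 1`` curvature terms
    ``d_k(x) - d_{K-1}(x)`` with ``d_k(x) = [(x - k_k)^3_+ - (x - k_K)^3_+]
    / (k_K - k_k)``.  The constant function is deliberately excluded so the
    basis can sit next to an explicit intercept; together they span all
    linear functions of ``x`` (``df = 1`` reduces to plain linear).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise HeritkitError("spline df must be >= 1")
    if df == 1:
        return x[:, None]
    knots = np.quantile(x, np.linspace(0, 1, df + 1))
    if len(np.unique(knots)) < df + 1:
        raise HeritkitError("too few distinct age values for the requested df")

    def d(k):
        return ((np.clip(x - knots[k], 0, None) ** 3
                 - np.clip(x - knots[-1], 0, None) ** 3)
                / (knots[-1] - knots[k]))

    cols = [x] + [d(k) - d(df - 1) for k in range(df - 1)]
    return np.column_stack(cols)


def _design_matrix(covariates: pd.DataFrame, age_basis_df: int
                   ) -> tuple[np.ndarray, list[str]]:
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if "age" in covariates.columns:
        basis = natural_spline_basis(covariates["age"].to_numpy(dtype=float),
                                     age_basis_df)
        cols += list(basis.T)
        names += [f"ns(age)[{j}]" for j in range(basis.shape[1])]
    if "sex" in covariates.columns:
        sex = pd.factorize(covariates["sex"])[0].astype(float)
        cols.append(sex)
        names.append("sex")
        if "age" in covariates.columns:
            cols += [b * sex for b in basis.T]
            names += [f"ns(age)[{j}]:sex" for j in range(basis.shape[1])]
    for cat in ("scanner", "diagnosis", "cohort"):
        if cat in covariates.columns:
            dummies = pd.get_dummies(covariates[cat], prefix=cat, drop_first=True)
            cols += [dummies[c].to_numpy(dtype=float) for c in dummies.columns]
            names += list(dummies.columns)
    for extra in covariates.columns:
        if extra not in ("age", "sex", "scanner", "diagnosis", "cohort"):
            cols.append(covariates[extra].to_numpy(dtype=float))
            names.append(str(extra))
    return np.column_stack(cols), names


def residualize(values: np.ndarray, covariates: pd.DataFrame,
                age_basis_df: int = 4) -> tuple[np.ndarray, list[str]]:
    """OLS residuals of a phenotype on the standard covariate design.

    The design holds an intercept, a natural cubic spline basis of age with
    ``age_basis_df`` degrees of freedom, sex, the age-spline x sex
    interaction, and treatment-coded scanner / diagnosis / cohort factors
    (whichever columns are present).  Returns ``(residuals, column_names)``.
    A rank-deficient design raises, naming the aliased columns.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if len(covariates) != n:
        raise HeritkitError("covariate rows must match phenotype length")
    x, names = _design_matrix(covariates, age_basis_df)
    if n < x.shape[1] + 2:
        raise HeritkitError(f"need at least p + 2 = {x.shape[1] + 2} observations")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = sla.qr(x, pivoting=True)
        aliased = sorted(names[i] for i in piv[rank:])
        raise HeritkitError(f"rank-deficient design; aliased columns: {aliased}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, names
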