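"""Covariate-adjusted correlations and locally weighted smoothing.

Partial correlation residualizes both variables on the covariates (with
intercept) by least squares and correlates the residuals; the p-value uses
a t reference with n - k - 2 degrees of freedom for k covariates.  Sex is
coded 0/1 when passed through :func:`partial_correlation_matrix`.

LOWESS curves (tricube-weighted local linear fits over the span-fraction
nearest neighbours, optional bisquare robustness passes) summarize the
shape of index-score relationships; an ordinary least-squares R^2 of the
same data quantifies how much a straight line explains.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .cohort import Sex
from .errors import (
    CollinearityError,
    DegeneracyError,
    SpanTooSmallError,
)


@dataclass(frozen=True)
class PartialCorrelationResult:
    pair: tuple[str, str]
    r: float
    p_value: float
    n: int
    covariates: tuple[str, ...]


@dataclass(frozen=True)
class SmoothedCurve:
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    r_squared_linear: float


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x,
    y,
    covariates=None,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: Sequence[str] = (),
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing covariate effects.

    With no covariates this reduces exactly to the plain Pearson
    correlation.  Raises :class:`CollinearityError` for a rank-deficient
    covariate matrix and :class:`DegeneracyError` when either variable has
    (essentially) zero residual variance.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(xv)
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise DegeneracyError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    rx = _residualize(xv, design)
    ry = _residualize(yv, design)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    scale = max(np.abs(xv).max(), np.abs(yv).max(), 1.0)
    if sx <= 1e-10 * scale * np.sqrt(n) or sy <= 1e-10 * scale * np.sqrt(n):
        raise DegeneracyError("zero residual variance after adjustment")
    r = float((rx @ ry) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    if not covariate_names:
        covariate_names = tuple(f"z{i}" for i in range(k))
    return PartialCorrelationResult(
        pair=names, r=r, p_value=p, n=n, covariates=tuple(covariate_names)
    )


def partial_correlation_matrix(
    df: pd.DataFrame,
    columns: Sequence[str],
    covariate_columns: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Pairwise partial correlations among ``columns``, adjusted for the
    covariates.  A ``sex`` covariate is coded female=0, male=1."""
    Z = []
    for c in covariate_columns:
        col = df[c]
        if c == "sex":
            Z.append((col.astype(str) == Sex.MALE.value).to_numpy(dtype=float))
        else:
            Z.append(col.to_numpy(dtype=float))
    Zm = np.column_stack(Z) if Z else None
    out = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for i, a in enumerate(columns):
        for b in columns[i + 1 :]:
            res = partial_correlation(
                df[a], df[b], Zm, names=(a, b), covariate_names=covariate_columns
            )
            out.loc[a, b] = out.loc[b, a] = res.r
    return out


def lowess_curve(
    x,
    y,
    span: float = 2.0 / 3.0,
    robustness_iters: int = 0,
    grid=None,
) -> SmoothedCurve:
    """Tricube local-linear smooth of y on x plus a straight-line R^2.

    ``span`` is the fraction of points in each local window; fitted values
    are interpolated onto ``grid`` (default: the sorted unique x values).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(xv)
    if n < 10:
        raise SpanTooSmallError(f"need at least 10 points, got {n}")
    if len(np.unique(xv)) < 2:
        raise SpanTooSmallError("x needs at least 2 distinct values")
    if span * n < 3:
        raise SpanTooSmallError(
            f"span {span} leaves {span * n:.1f} < 3 points per window"
        )
    fitted_xy = sm.nonparametric.lowess(
        yv, xv, frac=span, it=robustness_iters, return_sorted=True
    )
    if grid is None:
        grid = np.unique(xv)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise SpanTooSmallError("grid must be strictly increasing")
    fitted = np.interp(grid, fitted_xy[:, 0], fitted_xy[:, 1])
    # straight-line benchmark on the same data
    sy = np.std(yv)
    if sy <= 1e-12 * max(1.0, float(np.abs(yv).max())):
        r2 = 0.0
    else:
        r = stats.pearsonr(xv, yv).statistic
        r2 = float(r * r)
    return SmoothedCurve(
        grid=grid, fitted=fitted, span=float(span), r_squared_linear=r2
    )


def correlation_table(
    df: pd.DataFrame,
    score_col: str = "mets_score",
    index_cols: Sequence[str] = ("bmi", "fmi", "tmi"),
    group_col: str = "age_group",
    covariate_columns: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-age-group partial correlations of each index with the score
    (and among the indices), adjusted for age and sex."""
    rows = []
    cols = list(index_cols) + [score_col]
    for label, grp in df.groupby(group_col, sort=True):
        mat = partial_correlation_matrix(grp, cols, covariate_columns)
        for a in cols:
            for b in cols:
                if a < b:
                    rows.append(
                        {
                            "age_group": label,
                            "var_a": a,
                            "var_b": b,
                            "r": mat.loc[a, b],
                            "n": len(grp),
                        }
                    )
    return pd.DataFrame(rows, columns=["age_group", "var_a", "var_b", "r", "n"])
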