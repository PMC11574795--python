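"""Covariate-adjusted correlations between reconfiguration and behavior.

For each edge, the reconfiguration values across a group's subjects are
partially correlated with a behavioral measure (task accuracy, reaction
time, an executive-function composite, a language subtest score),
controlling nuisance covariates — age and in-scanner head motion — by
least-squares residualization of both sides.  The resulting per-group
distribution of E coefficients is the object of interest; two groups'
distributions are compared with the rank-sum test.

Missing behavioral values are dropped pairwise per measure (never listwise
across measures) and the per-measure n is recorded.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import CollinearityError
from .group_stats import DistributionComparison, compare_distributions

_ZERO_VAR = 1e-12


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariate table does not match the sample size")
    X = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariates are rank deficient after adding intercept")
    return X


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [intercept | covariates].

    With no covariates this is simple demeaning.  Residuals are orthogonal
    to every covariate column (and to the intercept), which is what makes
    the subsequent correlation a partial correlation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _design(covariates, y.size)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(x, y, covariates=None) -> float:
    """Pearson correlation of x and y after removing the covariates from both.

    Returns NaN (with a warning) when either residual vector is degenerate,
    e.g. when x is itself one of the covariates.
    """
    rx = residualize(np.asarray(x, dtype=float), covariates)
    ry = residualize(np.asarray(y, dtype=float), covariates)
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    if sx < _ZERO_VAR or sy < _ZERO_VAR:
        warnings.warn(
            "zero residual variance; partial correlation undefined", stacklevel=2
        )
        return float("nan")
    return float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))


def edgewise_behavior_correlations(
    recon: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Partial correlation of each edge's reconfiguration with a behavior score.

    Rows with a missing behavior or covariate value are dropped pairwise.
    Returns ``(coefficients, n_used)``; edges whose residual variance
    vanishes get NaN coefficients.
    """
    recon = np.atleast_2d(np.asarray(recon, dtype=float))
    behavior = np.asarray(behavior, dtype=float).ravel()
    if behavior.size != recon.shape[0]:
        raise ValueError("behavior length does not match number of subjects")
    keep = np.isfinite(behavior) & np.all(np.isfinite(recon), axis=1)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != behavior.size:
            cov = cov.T
        keep &= np.all(np.isfinite(cov), axis=1)
        cov = cov[keep]
        k = cov.shape[1]
    else:
        cov = None
        k = 0
    n = int(keep.sum())
    if n < k + 4:
        raise ValueError(
            f"only {n} complete observations for {k} covariates; need >= {k + 4}"
        )
    r_mat = recon[keep]
    b = behavior[keep]
    X = _design(cov, n)
    # residualize everything against the shared design in one least-squares solve
    beta_r, *_ = np.linalg.lstsq(X, r_mat, rcond=None)
    res_r = r_mat - X @ beta_r
    beta_b, *_ = np.linalg.lstsq(X, b, rcond=None)
    res_b = b - X @ beta_b
    norm_r = np.sqrt((res_r**2).sum(axis=0))
    norm_b = float(np.sqrt(res_b @ res_b))
    coeffs = np.full(recon.shape[1], np.nan)
    if norm_b >= _ZERO_VAR:
        ok = norm_r >= _ZERO_VAR
        coeffs[ok] = np.clip((res_b @ res_r[:, ok]) / (norm_b * norm_r[ok]), -1, 1)
        if not ok.all():
            warnings.warn(
                f"{int((~ok).sum())} edge(s) with zero residual variance", stacklevel=2
            )
    else:
        warnings.warn("behavior has zero residual variance", stacklevel=2)
    return coeffs, n


def compare_correlation_distributions(r_a, r_b) -> DistributionComparison:
    """Rank-sum (+ KS) comparison of two groups' edge-coefficient distributions.

    z is positive when group A's coefficients are the more positive.  NaN
    coefficients (degenerate edges) are dropped per side.
    """
    r_a = np.asarray(r_a, dtype=float).ravel()
    r_b = np.asarray(r_b, dtype=float).ravel()
    if r_a.size != r_b.size:
        raise ValueError("coefficient vectors must have the same edge count")
    return compare_distributions(r_a[np.isfinite(r_a)], r_b[np.isfinite(r_b)])
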