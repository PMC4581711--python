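"""Covariate-adjusted linear association engine.

Single-test fits (:func:`fit_ols`), a vectorized many-SNPs x many-traits scan
(:func:`scan_ols`) based on the Frisch–Waugh partialling-out identity, partial
explained variance, leave-one-out jackknife standard errors and the genomic
inflation factor.

Every reported p-value is two-sided from the t distribution with
df = n - (number of regressors); the focal predictor's explained variance is
the partial R^2, t^2 / (t^2 + df).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
from scipy import stats

from trimetaqtl.datatypes import CovariateTable

#: median of the chi-square distribution with 1 df, the null reference for lambda
CHI2_1DF_MEDIAN = 0.45493642311957283


@dataclass(frozen=True)
class OlsFit:
    """Result of a single covariate-adjusted OLS fit for one focal predictor."""

    beta: float
    se: float
    t: float
    p: float
    df: int
    n: int
    beta_covariates: dict[str, float] = field(default_factory=dict)

    @property
    def explained_var(self) -> float:
        return partial_r2(self.t, self.df)


def _as_design(C, n: int) -> tuple[np.ndarray, list[str]]:
    """Covariates -> design matrix columns (no intercept) plus names."""

    if C is None:
        return np.empty((n, 0)), []
    if isinstance(C, CovariateTable):
        return C.matrix(), C.columns
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return C, [f"c{j}" for j in range(C.shape[1])]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # QR with column pivoting: trailing pivots beyond the numerical rank are
    # the linearly dependent columns.
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def fit_ols(y, x, C: CovariateTable | np.ndarray | None = None) -> OlsFit:
    """OLS of ``y`` on the focal predictor ``x`` plus covariates and intercept.

    Listwise deletion over missing values in ``y``, ``x`` or the covariates;
    the complete-case ``n`` is reported.  Raises on a constant (monomorphic)
    focal predictor and on a singular design.
    """

    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError("y and x length mismatch")
    Cmat, cnames = _as_design(C, len(y))
    mask = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(Cmat), axis=1)
    ym, xm, Cm = y[mask], x[mask], Cmat[mask]
    n = int(mask.sum())
    k = 2 + Cm.shape[1]  # intercept + focal + covariates
    if n < k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} regressors")
    if np.ptp(xm) == 0:
        raise ValueError("monomorphic predictor: focal x is constant")
    X = np.column_stack([np.ones(n), xm, Cm])
    names = ["intercept", "x"] + cnames
    coefs, _, rank, _ = np.linalg.lstsq(X, ym, rcond=None)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"singular design; collinear columns: {bad}")
    resid = ym - X @ coefs
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coefs[1])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    cov_betas = {nm: float(b) for nm, b in zip(names, coefs) if nm != "x"}
    return OlsFit(beta=beta, se=se, t=t, p=p, df=df, n=n, beta_covariates=cov_betas)


def partial_r2(t: float, df: int) -> float:
    """Partial explained variance of the focal predictor: t^2 / (t^2 + df)."""

    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = float(t)
    return t * t / (t * t + df)


def jackknife_se(statistic: Callable, data) -> float:
    """Leave-one-out jackknife standard error of ``statistic``.

    ``data`` is either an integer sample count (``statistic`` is then called
    with the kept index array) or an indexable array whose first axis is the
    sample axis (``statistic`` receives the row subset).

    SE = sqrt(((n-1)/n) * sum_i (theta_(-i) - mean(theta_(-.)))^2).
    """

    if isinstance(data, (int, np.integer)):
        n = int(data)
        subsets = lambda keep: keep  # noqa: E731 - pass indices through
    else:
        data = np.asarray(data)
        n = data.shape[0]
        subsets = lambda keep: data[keep]  # noqa: E731
    if n < 3:
        raise ValueError(f"jackknife needs n >= 3, got {n}")
    idx = np.arange(n)
    thetas = np.empty(n)
    for i in range(n):
        keep = np.delete(idx, i)
        try:
            thetas[i] = statistic(subsets(keep))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"statistic failed on leave-one-out index {i}") from exc
    center = thetas.mean()
    return float(np.sqrt((n - 1) / n * np.sum((thetas - center) ** 2)))


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median association chi^2 over the null median."""

    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# vectorized scan
# ---------------------------------------------------------------------------

def scan_ols(
    Y: np.ndarray,
    X: np.ndarray,
    C: CovariateTable | np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """All-pairs OLS scan: each column of ``X`` against each column of ``Y``.

    Equivalent to calling :func:`fit_ols` for every (x, y) pair — the focal
    slope is obtained by partialling the covariates (plus intercept) out of
    both sides (Frisch–Waugh) — but vectorized over predictors.  Missing
    values are handled per trait column by listwise deletion; predictors and
    covariates are assumed complete.

    Returns arrays of shape (n_x, n_y): ``beta``, ``se``, ``t``, ``p``, ``df``,
    ``n``, ``explained_var``.  Pairs whose focal predictor is constant within a
    trait's complete cases come back as NaN.
    """

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X sample counts differ")
    n_all, m = X.shape
    q = Y.shape[1]
    Cmat, _ = _as_design(C, n_all)
    k_cov = Cmat.shape[1]

    beta = np.full((m, q), np.nan)
    se = np.full((m, q), np.nan)
    tstat = np.full((m, q), np.nan)
    pval = np.full((m, q), np.nan)
    dfs = np.zeros((m, q), dtype=int)
    ns = np.zeros((m, q), dtype=int)

    finite_y = np.isfinite(Y)
    # group trait columns by identical missingness pattern so each pattern's
    # covariate projection is computed once
    patterns: dict[bytes, list[int]] = {}
    for j in range(q):
        patterns.setdefault(finite_y[:, j].tobytes(), []).append(j)

    for key, cols in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n = int(mask.sum())
        df = n - k_cov - 2
        if df < 1:
            continue
        D = np.column_stack([np.ones(n), Cmat[mask]])
        Qd, _ = np.linalg.qr(D)
        Xm = X[mask]
        Xr = Xm - Qd @ (Qd.T @ Xm)
        sxx = np.einsum("ij,ij->j", Xr, Xr)
        ok = sxx > 1e-12 * n
        Ym = Y[np.ix_(mask, cols)]
        Yr = Ym - Qd @ (Qd.T @ Ym)
        syy = np.einsum("ij,ij->j", Yr, Yr)
        sxy = Xr.T @ Yr  # (m, len(cols))
        with np.errstate(divide="ignore", invalid="ignore"):
            b = sxy / sxx[:, None]
            rss = syy[None, :] - b * sxy
            rss = np.maximum(rss, 0.0)
            sigma2 = rss / df
            s = np.sqrt(sigma2 / sxx[:, None])
            tt = b / s
        b[~ok] = np.nan
        s[~ok] = np.nan
        tt[~ok] = np.nan
        pp = 2.0 * stats.t.sf(np.abs(tt), df)
        pp = np.clip(pp, np.finfo(float).tiny, 1.0)
        beta[:, cols] = b
        se[:, cols] = s
        tstat[:, cols] = tt
        pval[:, cols] = pp
        dfs[:, cols] = df
        ns[:, cols] = n

    with np.errstate(invalid="ignore"):
        ev = tstat**2 / (tstat**2 + dfs)
    return {
        "beta": beta, "se": se, "t": tstat, "p": pval,
        "df": dfs, "n": ns, "explained_var": ev,
    }


def residualize(M: np.ndarray, C: CovariateTable | np.ndarray | None) -> np.ndarray:
    """Residuals of each column of ``M`` on covariates plus an intercept."""

    M = np.asarray(M, dtype=float)
    Cmat, _ = _as_design(C, M.shape[0])
    D = np.column_stack([np.ones(M.shape[0]), Cmat])
    Qd, _ = np.linalg.qr(D)
    return M - Qd @ (Qd.T @ M)
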