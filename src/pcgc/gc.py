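"""Autoregressive model fitting and (conditional) Granger causality.

Granger causality from a driver x to a target y is the log-ratio of the
residual variances of two nested least-squares AR models of y: the
restricted model regresses y(t) on its own past (plus the past of any
conditioning variables Z), the unrestricted model adds the past of x.
Both models are fitted on the identical sample (rows where all lags are
available), so the causality value is nonnegative by construction and the
improvement is assessed with a standard F-test on the two residual sums of
squares.  Values are reported in natural-log units (nats).

Conditioning on Z removes influences that are merely mediated or shared:
gc(x -> y | Z) is small when the past of Z already carries everything x
knows about y's future.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import TimeSeriesSet


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when an AR design is rank deficient.

    With many redundant predictors the regression coefficients are not
    identifiable and may change erratically with tiny data perturbations;
    the usual cure is to aggregate correlated predictors (see the
    community-aggregated conditioning in :mod:`pcgc.community`) rather
    than to condition on each of them separately.
    """


@dataclass
class ARFit:
    """One least-squares AR fit: coefficients and error bookkeeping."""

    coeffs: np.ndarray
    rss: float
    sigma2: float
    n_obs: int
    n_params: int

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")
        if self.n_obs <= self.n_params:
            raise ValueError(
                f"need n_obs > n_params for a valid fit ({self.n_obs} <= {self.n_params})"
            )


@dataclass
class GCResult:
    """Granger causality value with its F-test."""

    gc: float
    f_stat: float
    p_value: float
    df1: int
    df2: int

    def __post_init__(self) -> None:
        if self.gc < -1e-12:
            raise ValueError(f"gc must be nonnegative, got {self.gc}")
        self.gc = max(self.gc, 0.0)
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class GCMatrix:
    """All-pairs causality: (i, j) holds driver i -> target j."""

    gc: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    df1: int
    df2: int

    def result(self, i: int, j: int) -> GCResult:
        return GCResult(
            gc=float(self.gc[i, j]),
            f_stat=float(self.f_stat[i, j]),
            p_value=float(self.p_value[i, j]),
            df1=self.df1,
            df2=self.df2,
        )

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        sig = self.p_value < alpha
        np.fill_diagonal(sig, False)
        return sig


# ---------------------------------------------------------------------------
# design assembly and OLS


def _lagged_columns(x: np.ndarray, p: int) -> np.ndarray:
    """Columns x(t-1) ... x(t-p) for rows t = p .. T-1."""
    t = x.shape[0]
    return np.column_stack([x[p - l : t - l] for l in range(1, p + 1)])


def build_lagged_design(
    ts: TimeSeriesSet,
    target: int,
    predictors: Sequence[int],
    p: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Response and design for the AR regression of ``target``.

    Response: target values at times p .. T-1.  Design column order is
    documented and fixed: intercept, then lags 1..p of the target, then
    lags 1..p of each predictor in the given order.
    """
    if p < 1:
        raise ValueError("lag order p must be >= 1")
    n_params = 1 + p * (1 + len(predictors))
    n_obs = ts.n_times - p
    if n_obs <= n_params:
        raise ValueError(
            f"insufficient samples: T={ts.n_times} gives {n_obs} usable rows "
            f"for {n_params} parameters; need T > {n_params + p}"
        )
    y = ts.data[p:, target]
    cols = [np.ones(n_obs), _lagged_columns(ts.data[:, target], p)]
    for idx in predictors:
        cols.append(_lagged_columns(ts.data[:, idx], p))
    return y, np.column_stack(cols)


def _ols(y: np.ndarray, design: np.ndarray) -> ARFit:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design ({rank} < {design.shape[1]}); "
            "consider aggregating redundant predictors"
        )
    resid = y - design @ coef
    rss = float(resid @ resid)
    n_obs, n_params = design.shape
    return ARFit(
        coeffs=coef,
        rss=rss,
        sigma2=rss / n_obs,
        n_obs=n_obs,
        n_params=n_params,
    )


def gc_ftest(
    rss_r: float, rss_u: float, df1: int, df2: int
) -> tuple[float, float]:
    """F statistic and upper-tail p-value for nested RSS."""
    if rss_u <= 0:
        raise ValueError("unrestricted rss must be positive")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if rss_r < rss_u * (1 - 1e-9) - 1e-12:
        raise ValueError(
            f"nested-model invariant violated: rss_r={rss_r} < rss_u={rss_u}"
        )
    f = max(0.0, ((rss_r - rss_u) / df1) / (rss_u / df2))
    p = float(stats.f.sf(f, df1, df2))
    return f, p


def gc_from_series(
    target: np.ndarray,
    driver: np.ndarray,
    z: np.ndarray | None = None,
    p: int = 1,
) -> GCResult:
    """Conditional GC from raw 1-D series (z given as a T x m matrix).

    This is the workhorse behind :func:`conditional_gc` and the
    community-aggregated variants, where the conditioning signals are
    derived aggregates rather than original columns.
    """
    target = np.asarray(target, dtype=float)
    driver = np.asarray(driver, dtype=float)
    if z is None:
        zmat = np.empty((target.size, 0))
    else:
        zmat = np.atleast_2d(np.asarray(z, dtype=float))
        if zmat.shape[0] != target.size:
            zmat = zmat.T
    t = target.size
    n_obs = t - p
    n_params_u = 1 + p * (2 + zmat.shape[1])
    if n_obs <= n_params_u:
        raise ValueError(
            f"insufficient samples: T={t} gives {n_obs} rows for "
            f"{n_params_u} unrestricted parameters"
        )
    y = target[p:]
    base = [np.ones(n_obs), _lagged_columns(target, p)]
    base += [_lagged_columns(zmat[:, k], p) for k in range(zmat.shape[1])]
    x_r = np.column_stack(base)
    x_u = np.column_stack(base + [_lagged_columns(driver, p)])
    fit_r = _ols(y, x_r)
    fit_u = _ols(y, x_u)
    gc = float(np.log(fit_r.rss / fit_u.rss)) if fit_u.rss > 0 else np.inf
    df1 = p
    df2 = fit_u.n_obs - fit_u.n_params
    f, pval = gc_ftest(fit_r.rss, fit_u.rss, df1, df2)
    return GCResult(gc=max(gc, 0.0), f_stat=f, p_value=pval, df1=df1, df2=df2)


def conditional_gc(
    ts: TimeSeriesSet,
    driver: int,
    target: int,
    z: Sequence[int] = (),
    p: int = 1,
) -> GCResult:
    """GC from column ``driver`` to column ``target`` given columns ``z``."""
    z = list(z)
    if driver == target:
        raise ValueError("driver and target must differ")
    if driver in z or target in z:
        raise ValueError("driver/target must not appear in the conditioning set")
    zmat = ts.data[:, z] if z else None
    return gc_from_series(ts.data[:, target], ts.data[:, driver], zmat, p)


# ---------------------------------------------------------------------------
# fast all-pairs machinery
#
# All the matrix-level estimators fit the same nested OLS problems over and
# over on subsets of the same lagged columns.  Precomputing the Gram matrix
# of [intercept | current values | lagged values] turns each fit into a
# small symmetric solve: rss = <y, y> - c' G^{-1} c.


class LagCache:
    """Cross-products of [1, X_t, X_{t-1..t-p}] for fast nested OLS."""

    def __init__(self, data: np.ndarray, p: int = 1):
        data = np.asarray(data, dtype=float)
        t, n = data.shape
        if t - p <= 2 + 2 * p:
            raise ValueError("too few time points for the requested lag order")
        self.p = p
        self.n = n
        self.n_obs = t - p
        cur = data[p:]
        lag_blocks = [data[p - l : t - l] for l in range(1, p + 1)]
        z = np.column_stack([np.ones(self.n_obs), cur] + lag_blocks)
        self.m = z.T @ z
        self.icol = 0

    def cur(self, j: int) -> int:
        return 1 + j

    def lags(self, j: int) -> list[int]:
        return [1 + self.n + l * self.n + j for l in range(self.p)]

    def rss(self, target: int, pred_cols: Sequence[int]) -> float:
        """RSS of current-value ``target`` on [intercept + pred_cols]."""
        cols = [self.icol] + list(pred_cols)
        g = self.m[np.ix_(cols, cols)]
        c = self.m[cols, self.cur(target)]
        try:
            beta = np.linalg.solve(g, c)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(g, c, rcond=None)[0]
        syy = self.m[self.cur(target), self.cur(target)]
        return float(max(syy - c @ beta, 0.0))

    def gc_pair(
        self, driver: int, target: int, z: Sequence[int] = ()
    ) -> tuple[float, float, float]:
        """(gc, F, p) for driver -> target conditioned on columns ``z``."""
        base = self.lags(target)
        for k in z:
            base = base + self.lags(k)
        rss_r = self.rss(target, base)
        rss_u = self.rss(target, base + self.lags(driver))
        df1 = self.p
        df2 = self.n_obs - (1 + len(base) + self.p)  # intercept + base + driver lags
        f, pval = gc_ftest(max(rss_r, rss_u), rss_u, df1, df2)
        gc = float(np.log(rss_r / rss_u)) if rss_u > 0 and rss_r >= rss_u else 0.0
        return max(gc, 0.0), f, pval


def pairwise_gc_matrix(ts: TimeSeriesSet | np.ndarray, p: int = 1) -> GCMatrix:
    """Unconditioned GC for every ordered pair (diagonal left at zero).

    Entry (i, j) equals ``conditional_gc(ts, i, j, z=[], p)``; the pairwise
    estimator cannot distinguish direct from mediated influence, which is
    exactly the failure mode conditioning addresses.
    """
    data = ts.data if isinstance(ts, TimeSeriesSet) else np.asarray(ts, float)
    n = data.shape[1]
    if n < 2:
        raise ValueError("need at least 2 variables")
    cache = LagCache(data, p)
    gc = np.zeros((n, n))
    f = np.zeros((n, n))
    pv = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            gc[i, j], f[i, j], pv[i, j] = cache.gc_pair(i, j)
    df2 = cache.n_obs - (2 * p + 1)
    return GCMatrix(gc=gc, f_stat=f, p_value=pv, df1=p, df2=df2)
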