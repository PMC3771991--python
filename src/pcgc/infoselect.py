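"""Gaussian mutual information and greedy conditioning-set selection.

The data-driven variant of partially conditioned Granger causality
(PCGC^d) conditions each driver on the small set of variables that is most
informative about it, instead of on all N-1 others.  Informativeness is
measured with the Gaussian mutual-information estimator

    MI(A; B) = 1/2 [ ln det Sigma_A + ln det Sigma_B - ln det Sigma_{A u B} ]

on sample covariances, and the set is grown greedily: the first pick
maximizes MI with the driver alone, each later pick maximizes the joint MI
of the chosen set plus the candidate.  The incremental gains decay quickly
for redundant data; the knee of the cumulative-gain curve gives a natural
stopping point for the number of conditioning variables n_d.

For lag order 1 a variable's state vector is its current value; for p > 1
each variable is represented by its p most recent values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .gc import GCMatrix, LagCache
from .io import TimeSeriesSet


@dataclass
class SelectionResult:
    """Greedy ranking of conditioning variables for one driver."""

    driver: int
    order: list[int]
    gains: np.ndarray

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if len(set(self.order)) != len(self.order):
            raise ValueError("order contains duplicates")
        if self.driver in self.order:
            raise ValueError("driver cannot condition on itself")
        if np.any(self.gains < -1e-10):
            raise ValueError("information gains must be nonnegative")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.gains)


def _state_matrix(ts: TimeSeriesSet, p: int) -> tuple[np.ndarray, list[list[int]]]:
    """Columns of each variable's p-lag state vector + per-variable groups."""
    data = ts.data
    t, n = data.shape
    if p == 1:
        return data, [[j] for j in range(n)]
    rows = t - p + 1
    cols = []
    groups = []
    k = 0
    for j in range(n):
        grp = []
        for l in range(p):
            cols.append(data[p - 1 - l : t - l, j])
            grp.append(k)
            k += 1
        groups.append(grp)
    return np.column_stack(cols), groups


def _logdet(cov: np.ndarray, idx: Sequence[int]) -> float:
    sub = cov[np.ix_(idx, idx)]
    sign, ld = np.linalg.slogdet(sub)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance submatrix")
    return float(ld)


def gaussian_mi(
    ts: TimeSeriesSet,
    set_a: Sequence[int],
    set_b: Sequence[int],
    p: int = 1,
) -> float:
    """Gaussian mutual information (nats) between two variable sets.

    Symmetric, nonnegative (up to floating point), and invariant under
    per-variable affine rescaling.  Sets must be disjoint and nonempty;
    a singular joint covariance is an error.
    """
    a, b = list(set_a), list(set_b)
    if not a or not b:
        raise ValueError("both sets must be nonempty")
    if set(a) & set(b):
        raise ValueError("sets must be disjoint")
    mat, groups = _state_matrix(ts, p)
    ia = [c for v in a for c in groups[v]]
    ib = [c for v in b for c in groups[v]]
    cov = np.cov(mat, rowvar=False)
    cov = np.atleast_2d(cov)
    # sorted union keeps MI(A;B) == MI(B;A) bit-exact
    mi = 0.5 * (_logdet(cov, ia) + _logdet(cov, ib) - _logdet(cov, sorted(ia + ib)))
    return float(mi)


def _chol_append(l_mat: np.ndarray, new_cross: np.ndarray, new_diag: float) -> np.ndarray:
    """Grow a Cholesky factor by one row/column."""
    m = l_mat.shape[0]
    if m == 0:
        return np.array([[np.sqrt(new_diag)]])
    u = solve_triangular(l_mat, new_cross, lower=True)
    s = new_diag - u @ u
    if s <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    out = np.zeros((m + 1, m + 1))
    out[:m, :m] = l_mat
    out[m, :m] = u
    out[m, m] = np.sqrt(s)
    return out


def greedy_order(
    cov: np.ndarray, driver: int, n_max: int
) -> tuple[list[int], np.ndarray]:
    """Greedy most-informative ranking from a covariance matrix.

    Maximizes MI(chosen u {candidate}; {driver}) at every step; ties break
    on the lowest column index (argmax keeps the first maximum).  Returns
    the ranked indices and the incremental MI gains in nats.
    """
    n = cov.shape[0]
    if not 1 <= n_max <= n - 1:
        raise ValueError(f"n_max must be in [1, {n - 1}], got {n_max}")
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise np.linalg.LinAlgError("zero-variance variable in covariance")
    corr = cov / np.outer(sd, sd)

    chosen: list[int] = []
    mis = []
    l_a = np.empty((0, 0))  # chol of corr over chosen
    l_ad = np.array([[1.0]])  # chol of corr over chosen + driver (driver last? driver first)
    # keep driver FIRST in the A u d factor so appends are symmetric
    candidates = np.array([j for j in range(n) if j != driver])
    for _ in range(n_max):
        # logdet terms that do not depend on the candidate are constant;
        # maximizing MI == maximizing logdet(S_{A,c}) - logdet(S_{A,d,c})
        if chosen:
            v_a = solve_triangular(l_a, corr[np.ix_(chosen, candidates)], lower=True)
            s_a = 1.0 - np.einsum("ij,ij->j", v_a, v_a)
        else:
            s_a = np.ones(candidates.size)
        rows_ad = [driver] + chosen
        v_ad = solve_triangular(l_ad, corr[np.ix_(rows_ad, candidates)], lower=True)
        s_ad = 1.0 - np.einsum("ij,ij->j", v_ad, v_ad)
        score = np.log(np.maximum(s_a, 1e-300)) - np.log(np.maximum(s_ad, 1e-300))
        k = int(np.argmax(score))
        pick = int(candidates[k])
        # bookkeeping: joint MI after this pick
        l_a_new = _chol_append(l_a, corr[chosen, pick] if chosen else np.empty(0), 1.0)
        l_ad_new = _chol_append(l_ad, corr[rows_ad, pick], 1.0)
        ld_a = 2 * np.sum(np.log(np.diag(l_a_new)))
        ld_ad = 2 * np.sum(np.log(np.diag(l_ad_new)))
        mis.append(0.5 * (ld_a + 0.0 - ld_ad))  # logdet of {driver} alone is 0
        chosen.append(pick)
        l_a, l_ad = l_a_new, l_ad_new
        candidates = candidates[candidates != pick]
    gains = np.diff(np.concatenate([[0.0], mis]))
    return chosen, np.maximum(gains, 0.0)


def greedy_select(
    ts: TimeSeriesSet, driver: int, n_max: int, p: int = 1
) -> SelectionResult:
    """Rank the ``n_max`` variables most informative for ``driver``."""
    mat, groups = _state_matrix(ts, p)
    if p == 1:
        cov = np.atleast_2d(np.cov(mat, rowvar=False))
        order, gains = greedy_order(cov, driver, n_max)
        return SelectionResult(driver=driver, order=order, gains=gains)
    # general lag order: greedy over variable blocks via explicit MI calls
    chosen: list[int] = []
    mis = []
    for _ in range(min(n_max, ts.n_vars - 1)):
        best, best_mi = -1, -np.inf
        for c in range(ts.n_vars):
            if c == driver or c in chosen:
                continue
            mi = gaussian_mi(ts, chosen + [c], [driver], p=p)
            if mi > best_mi + 1e-15:
                best, best_mi = c, mi
        chosen.append(best)
        mis.append(best_mi)
    gains = np.diff(np.concatenate([[0.0], mis]))
    return SelectionResult(driver=driver, order=chosen, gains=np.maximum(gains, 0.0))


def knee_point(gains: np.ndarray) -> int:
    """Knee of the cumulative information-gain curve.

    Returns the 1-based count of variables at the point of maximum
    perpendicular distance between the cumulative curve (anchored at the
    origin: zero variables carry zero information) and the chord joining
    its endpoints.  A (near-)linear curve has no knee: the full length is
    returned with a warning.
    """
    gains = np.asarray(gains, dtype=float)
    n = gains.size
    if n < 3:
        raise ValueError("need at least 3 gains to locate a knee")
    y = np.concatenate([[0.0], np.cumsum(gains)])
    x = np.arange(0, n + 1, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        warnings.warn("flat gain curve: no knee", stacklevel=2)
        return n
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    scale = max(abs(y[-1] - y[0]), 1e-300)
    if dist.max() <= 1e-9 * scale:
        warnings.warn("gain curve is linear: no knee", stacklevel=2)
        return n
    return int(np.argmax(dist))


def pcgc_d_matrix(
    ts: TimeSeriesSet, n_d: int = 10, p: int = 1
) -> GCMatrix:
    """All-pairs partially conditioned GC with data-driven conditioning.

    For each driver i, the greedy most-informative ranking is computed one
    entry longer than ``n_d``, and the conditioning set for target j is the
    first ``n_d`` ranked variables once j is excluded — so every pair is
    conditioned on exactly ``n_d`` signals and at n_d = N-2 the estimator
    coincides with the fully conditioned one.
    """
    n = ts.n_vars
    if not 1 <= n_d <= n - 2:
        raise ValueError(f"n_d must be in [1, N-2] = [1, {n - 2}]")
    cache = LagCache(ts.data, p)
    cov = np.atleast_2d(np.cov(ts.data, rowvar=False))
    gc = np.zeros((n, n))
    f = np.zeros((n, n))
    pv = np.ones((n, n))
    df2_full = cache.n_obs - (1 + (2 + n_d) * p)
    for i in range(n):
        order, _ = greedy_order(cov, i, min(n_d + 1, n - 1))
        for j in range(n):
            if i == j:
                continue
            z = [k for k in order if k != j][:n_d]
            gc[i, j], f[i, j], pv[i, j] = cache.gc_pair(i, j, z)
    return GCMatrix(gc=gc, f_stat=f, p_value=pv, df1=p, df2=df2_full)


def selection_gain_table(
    ts: TimeSeriesSet, n_max: int, p: int = 1
) -> np.ndarray:
    """Mean incremental information gain per added variable, over all drivers.

    The returned vector is the package's analogue of the information-gain
    curve used to justify n_d: its knee marks where further conditioning
    variables stop adding substantial information.
    """
    gains = np.zeros(n_max)
    cov = np.atleast_2d(np.cov(ts.data, rowvar=False)) if p == 1 else None
    for d in range(ts.n_vars):
        if p == 1:
            _, g = greedy_order(cov, d, n_max)
        else:
            g = greedy_select(ts, d, n_max, p).gains
        gains += g
    return gains / ts.n_vars
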