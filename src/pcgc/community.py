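"""Community structure and community-aggregated conditioning (PCGC^t).

For voxel-scale data even a "small" conditioning set of individual signals
overfits: neighbouring voxels are so redundant that the regression design
is near singular and coefficients jump erratically with tiny data changes.
The aggregated scheme conditions on *group mean signals* instead.  A
two-level hierarchical partition is built from the Louvain community
structure of the absolute Pearson correlation matrix: large systems at the
top, each refined into subsystems.  For a given driver, the conditioning
set consists of

* the mean signals of every subsystem of the driver's own system (fine
  resolution where the most informative variables live), and
* the mean signal of every other system as a whole (coarse elsewhere).

Regressing on a group mean constrains the group members' AR coefficients
to a single shared weight, which is exactly the cure for multicollinearity
among redundant predictors.  In strict mode (``t``) the driver is removed
from its own aggregate before averaging; the shortcut mode (``ti``) leaves
it in, which saves re-aggregating per driver and changes the values only
negligibly because one voxel barely moves a group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .gc import GCMatrix, GCResult, LagCache, gc_ftest, gc_from_series
from .io import TimeSeriesSet


@dataclass
class HierPartition:
    """Two-level (system / subsystem) assignment of variables."""

    system_of: np.ndarray
    subsystem_of: np.ndarray
    q_top: float

    def __post_init__(self) -> None:
        self.system_of = np.asarray(self.system_of, dtype=int)
        self.subsystem_of = np.asarray(self.subsystem_of, dtype=int)
        if self.system_of.shape != self.subsystem_of.shape:
            raise ValueError("level vectors must have equal length")
        for name, vec in (("system", self.system_of), ("subsystem", self.subsystem_of)):
            uniq = np.unique(vec)
            if not np.array_equal(uniq, np.arange(uniq.size)):
                raise ValueError(f"{name} ids must be contiguous from 0")
        # nestedness: all members of a subsystem share one system
        for s in np.unique(self.subsystem_of):
            if np.unique(self.system_of[self.subsystem_of == s]).size != 1:
                raise ValueError(f"subsystem {s} spans multiple systems")
        if not -1 <= self.q_top <= 1:
            raise ValueError("modularity must lie in [-1, 1]")

    @property
    def n_vars(self) -> int:
        return self.system_of.size

    def members_of_system(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.system_of == s)

    def members_of_subsystem(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.subsystem_of == s)

    @classmethod
    def singletons(cls, n: int) -> "HierPartition":
        """Degenerate partition with every variable its own system."""
        ids = np.arange(n)
        return cls(system_of=ids, subsystem_of=ids.copy(), q_top=0.0)


@dataclass
class ConditioningSet:
    """Aggregate-signal specification for one driver."""

    driver: int
    mode: str
    aggregates: list[list[int]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("t", "ti"):
            raise ValueError("mode must be 't' or 'ti'")
        seen: set[int] = set()
        for members in self.aggregates:
            if not members:
                raise ValueError("empty aggregate")
            if seen & set(members):
                raise ValueError("aggregates must be disjoint")
            seen |= set(members)
        if self.mode == "t" and self.driver in seen:
            raise ValueError("driver must not appear in any aggregate in mode 't'")


# ---------------------------------------------------------------------------
# correlation + modularity


def correlation_matrix(ts: TimeSeriesSet) -> np.ndarray:
    """Pairwise Pearson correlation of the columns."""
    var = ts.data.var(axis=0)
    if np.any(var == 0):
        bad = ts.labels[int(np.flatnonzero(var == 0)[0])]
        raise ValueError(f"zero-variance column {bad!r}")
    r = np.corrcoef(ts.data, rowvar=False)
    return np.clip(np.atleast_2d(r), -1.0, 1.0)


def group_average_abs(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """|mean over subjects| of correlation matrices, diagonal zeroed.

    The average precedes the absolute value, so opposite-sign correlations
    cancel; negative weights play a controversial role in community
    detection, hence only magnitudes of the group-mean matrix are kept.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty matrix list")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError("matrices must share a shape")
    w = np.abs(np.mean(matrices, axis=0))
    np.fill_diagonal(w, 0.0)
    return w


def modularity_q(w: np.ndarray, assignment: np.ndarray) -> float:
    """Newman weighted modularity of a partition.

    Q = (1/2m) sum_ij [w_ij - k_i k_j / 2m] delta(c_i, c_j) with k_i the
    node strength and 2m the total strength; invariant to relabeling.
    """
    w = np.asarray(w, dtype=float)
    assignment = np.asarray(assignment)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("w must be square")
    if not np.allclose(w, w.T):
        raise ValueError("w must be symmetric")
    if (w < 0).any():
        raise ValueError("w must be nonnegative")
    if np.diag(w).any():
        raise ValueError("w must have a zero diagonal")
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("all-zero weight matrix")
    same = assignment[:, None] == assignment[None, :]
    return float(((w - np.outer(k, k) / two_m) * same).sum() / two_m)


def _canonical_labels(assignment: np.ndarray) -> np.ndarray:
    """Relabel community ids contiguously in order of first appearance."""
    out = np.empty_like(assignment)
    mapping: dict[int, int] = {}
    for i, a in enumerate(assignment):
        if a not in mapping:
            mapping[a] = len(mapping)
        out[i] = mapping[a]
    return out


def louvain_partition(
    w: np.ndarray, restarts: int = 100, seed: int | None = 0
) -> tuple[np.ndarray, float]:
    """Best-of-``restarts`` Louvain partition of a weighted graph.

    Louvain is stochastic; the restart with the highest modularity Q is
    returned, and the reported Q equals :func:`modularity_q` of the
    returned assignment exactly.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    w = np.asarray(w, dtype=float)
    if w.sum() == 0:
        raise ValueError("all-zero weight matrix")
    g = nx.from_numpy_array(w)
    g.add_nodes_from(range(w.shape[0]))
    rng = np.random.default_rng(seed)
    best_q, best = -np.inf, None
    for _ in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", seed=int(rng.integers(2**31))
        )
        assignment = np.empty(w.shape[0], dtype=int)
        for cid, nodes in enumerate(comms):
            for node in nodes:
                assignment[node] = cid
        q = modularity_q(w, assignment)
        if q > best_q:
            best_q, best = q, assignment
    return _canonical_labels(best), float(best_q)


def build_hier_partition(
    w: np.ndarray, restarts: int = 100, seed: int | None = 0
) -> HierPartition:
    """Two-level partition: Louvain systems, each re-partitioned into subsystems.

    Singleton systems (and systems whose induced subgraph carries no
    weight) become a single subsystem.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n < 4:
        raise ValueError("need at least 4 variables for a two-level partition")
    rng = np.random.default_rng(seed)
    system_of, q_top = louvain_partition(w, restarts, int(rng.integers(2**31)))
    subsystem_of = np.full(n, -1, dtype=int)
    next_id = 0
    for s in range(system_of.max() + 1):
        members = np.flatnonzero(system_of == s)
        if members.size == 1:
            subsystem_of[members] = next_id
            next_id += 1
            continue
        sub_w = w[np.ix_(members, members)]
        if sub_w.sum() == 0:
            subsystem_of[members] = next_id
            next_id += 1
            continue
        sub_assign, _ = louvain_partition(sub_w, restarts, int(rng.integers(2**31)))
        subsystem_of[members] = sub_assign + next_id
        next_id += sub_assign.max() + 1
    return HierPartition(system_of=system_of, subsystem_of=subsystem_of, q_top=q_top)


# ---------------------------------------------------------------------------
# conditioning-set construction and the aggregated causality index


def build_conditioning_set(
    hier: HierPartition, driver: int, target: int, mode: str = "t"
) -> ConditioningSet:
    """Aggregate specification for one driver.

    Fine (subsystem) resolution inside the driver's own system, coarse
    (whole-system) resolution elsewhere.  In mode ``t`` the driver is
    dropped from its subsystem's member list (the list itself is dropped
    if emptied); mode ``ti`` leaves the driver in.  The target always
    stays inside whichever aggregate contains it — its own past enters the
    regression separately.
    """
    n = hier.n_vars
    if not (0 <= driver < n and 0 <= target < n) or driver == target:
        raise ValueError(f"invalid driver/target pair ({driver}, {target})")
    own_sys = hier.system_of[driver]
    aggregates: list[list[int]] = []
    provenance: list[str] = []
    own_subs = np.unique(hier.subsystem_of[hier.system_of == own_sys])
    for sub in own_subs:
        members = list(hier.members_of_subsystem(sub))
        if mode == "t" and driver in members:
            members = [m for m in members if m != driver]
        if not members:
            continue
        aggregates.append(members)
        provenance.append("subsystem-of-driver-system")
    for s in range(hier.system_of.max() + 1):
        if s == own_sys:
            continue
        aggregates.append(list(hier.members_of_system(s)))
        provenance.append("other-system")
    return ConditioningSet(
        driver=driver, mode=mode, aggregates=aggregates, provenance=provenance
    )


def aggregate_signals(
    data: np.ndarray, cset: ConditioningSet, target: int
) -> np.ndarray:
    """Mean member signal per aggregate (T x m).

    An aggregate whose members are all already in the regression — a
    subset of {driver, target} — is dropped: its mean is an exact linear
    combination of the separately modelled driver and target pasts, so it
    adds nothing and would make the design singular.
    """
    redundant = {cset.driver, target}
    cols = [
        data[:, members].mean(axis=1)
        for members in cset.aggregates
        if not set(members) <= redundant
    ]
    if not cols:
        return np.empty((data.shape[0], 0))
    return np.column_stack(cols)


def pcgc_t(
    ts: TimeSeriesSet,
    hier: HierPartition,
    driver: int,
    target: int,
    p: int = 1,
    mode: str = "t",
) -> GCResult:
    """Community-aggregated partially conditioned GC for one pair."""
    cset = build_conditioning_set(hier, driver, target, mode)
    z = aggregate_signals(ts.data, cset, target)
    return gc_from_series(ts.data[:, target], ts.data[:, driver], z, p)


def _aggregate_memberships(
    cset: ConditioningSet, n: int
) -> np.ndarray:
    """m x N row-stochastic membership-mean matrix."""
    pmat = np.zeros((len(cset.aggregates), n))
    for r, members in enumerate(cset.aggregates):
        pmat[r, members] = 1.0 / len(members)
    return pmat


def pcgc_t_matrix(
    ts: TimeSeriesSet,
    hier: HierPartition,
    p: int = 1,
    mode: str = "t",
) -> GCMatrix:
    """All-pairs community-aggregated PCGC.

    For lag order 1 the nested regressions are solved from the shared
    lagged Gram matrix (aggregate cross-products are membership-weighted
    block means), which keeps the full N x N sweep tractable; higher lag
    orders fall back to the per-pair series path.
    """
    n = ts.n_vars
    if hier.n_vars != n:
        raise ValueError("partition size does not match data")
    gc = np.zeros((n, n))
    f = np.zeros((n, n))
    pv = np.ones((n, n))
    df2_seen = None
    if p != 1:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                res = pcgc_t(ts, hier, i, j, p, mode)
                gc[i, j], f[i, j], pv[i, j] = res.gc, res.f_stat, res.p_value
                df2_seen = res.df2
        return GCMatrix(gc=gc, f_stat=f, p_value=pv, df1=p, df2=df2_seen or 0)

    cache = LagCache(ts.data, 1)
    m_full = cache.m
    lag0 = 1 + n  # first lag-block column in the Gram
    m_ll = m_full[lag0 : lag0 + n, lag0 : lag0 + n]
    m_l1 = m_full[lag0 : lag0 + n, 0]
    m_lc = m_full[lag0 : lag0 + n, 1 : 1 + n]  # lag x current
    n_obs = cache.n_obs
    for i in range(n):
        cset = build_conditioning_set(hier, i, 0 if i != 0 else 1, mode)
        # target identity only matters through singleton-target dropping,
        # handled per target below; membership itself is target independent
        pmat = _aggregate_memberships(cset, n)
        agg_ll = pmat @ m_ll @ pmat.T
        agg_l1 = pmat @ m_l1
        agg_lc = pmat @ m_lc  # aggregates x current vars
        agg_lv = pmat @ m_ll  # aggregates x lag vars
        member_sets = [set(members) for members in cset.aggregates]
        m_agg = pmat.shape[0]
        for j in range(n):
            if i == j:
                continue
            keep = [r for r in range(m_agg) if not member_sets[r] <= {i, j}]
            k = len(keep)
            # design order: intercept, lag_j, aggregates, lag_i
            dim = 3 + k
            g = np.empty((dim, dim))
            g[0, 0] = n_obs
            g[0, 1] = g[1, 0] = m_l1[j]
            g[0, -1] = g[-1, 0] = m_l1[i]
            g[1, 1] = m_ll[j, j]
            g[1, -1] = g[-1, 1] = m_ll[j, i]
            g[-1, -1] = m_ll[i, i]
            g[0, 2 : 2 + k] = g[2 : 2 + k, 0] = agg_l1[keep]
            g[1, 2 : 2 + k] = g[2 : 2 + k, 1] = agg_lv[keep, j]
            g[-1, 2 : 2 + k] = g[2 : 2 + k, -1] = agg_lv[keep, i]
            g[2 : 2 + k, 2 : 2 + k] = agg_ll[np.ix_(keep, keep)]
            c = np.empty(dim)
            c[0] = m_full[0, 1 + j]
            c[1] = m_lc[j, j]
            c[-1] = m_lc[i, j]
            c[2 : 2 + k] = agg_lc[keep, j]
            syy = m_full[1 + j, 1 + j]
            try:
                beta_u = np.linalg.solve(g, c)
                beta_r = np.linalg.solve(g[:-1, :-1], c[:-1])
            except np.linalg.LinAlgError:
                beta_u = np.linalg.lstsq(g, c, rcond=None)[0]
                beta_r = np.linalg.lstsq(g[:-1, :-1], c[:-1], rcond=None)[0]
            rss_u = max(syy - c @ beta_u, 0.0)
            rss_r = max(syy - c[:-1] @ beta_r, 0.0)
            rss_r = max(rss_r, rss_u)
            df2 = n_obs - dim
            fstat, pval = gc_ftest(rss_r, rss_u, 1, df2)
            gc[i, j] = np.log(rss_r / rss_u) if rss_u > 0 else 0.0
            f[i, j], pv[i, j] = fstat, pval
            df2_seen = df2
    return GCMatrix(gc=gc, f_stat=f, p_value=pv, df1=1, df2=df2_seen or 0)


def partition_table(hier: HierPartition) -> np.ndarray:
    """(variable id, system id, subsystem id) rows for export."""
    ids = np.arange(hier.n_vars)
    return np.column_stack([ids, hier.system_of, hier.subsystem_of])


def communities_to_label_volume(hier, mask, level: str = "system"):
    """Write the community assignment back into voxel space.

    Returns a :class:`pcgc.io.LabelVolume` whose labels are community id
    + 1 (0 stays background) at each mask voxel, in the same fixed scan
    order used for extraction.
    """
    from .io import LabelVolume

    ids = hier.system_of if level == "system" else hier.subsystem_of
    if mask.n_voxels != hier.n_vars:
        raise ValueError("mask voxel count does not match partition size")
    grid = np.zeros(mask.grid.size, dtype=int)
    grid[mask.flat_indices()] = ids + 1
    return LabelVolume(grid=grid.reshape(mask.grid.shape, order="F"), affine=mask.affine)
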