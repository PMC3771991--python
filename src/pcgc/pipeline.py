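"""Seed-based and all-pairs causality mapping across subjects.

The seed map asks, for one source region (the mean signal of its member
voxels), which voxels it drives — or which drive it — after partialling
out the community-aggregated conditioning set.  Reproducibility maps count
across subjects how often each voxel reaches significance.  The voxel-wise
network is the full N x N aggregated-conditioning causality matrix, from
which Granger-causality-density (GCD) maps are read off as in/out degrees
of the thresholded directed graph; the functional-connectivity analogue
(FCD) thresholds the Pearson correlation matrix the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .community import (
    ConditioningSet,
    HierPartition,
    aggregate_signals,
    correlation_matrix,
    pcgc_t_matrix,
)
from .gc import GCMatrix, gc_from_series
from .io import RunConfig, TimeSeriesSet
from .netstats import degree_centrality, threshold_graph


@dataclass
class SeedMap:
    direction: str  # "out": seed drives voxels; "in": voxels drive seed
    gc_values: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        if self.direction not in ("out", "in"):
            raise ValueError("direction must be 'out' or 'in'")
        if not (len(self.gc_values) == len(self.p_values) == len(self.significant)):
            raise ValueError("vector lengths differ")


@dataclass
class ReproducibilityMap:
    fraction: np.ndarray
    n_subjects: int


def seed_map(
    ts: TimeSeriesSet,
    seed_members: Sequence[int],
    hier: HierPartition,
    config: RunConfig | None = None,
    direction: str = "out",
) -> SeedMap:
    """Causal influence between a seed region and every other variable.

    The seed signal is the mean of ``seed_members``.  Conditioning uses the
    hierarchical partition with all seed members removed from the
    aggregates (they are part of the driver/target side of the regression,
    not of the conditioning set).  NaN marks seed members in the output.
    """
    config = config or RunConfig()
    seed_members = sorted(set(int(s) for s in seed_members))
    if not seed_members:
        raise ValueError("seed member list is empty")
    n = ts.n_vars
    if len(seed_members) >= n:
        raise ValueError("seed covers the entire variable set")
    seed_sig = ts.data[:, seed_members].mean(axis=1)

    # aggregates: subsystems of the first seed member's system at fine
    # resolution, other systems coarse; all seed members excluded
    ref = seed_members[0]
    own_sys = hier.system_of[ref]
    aggregates: list[list[int]] = []
    for sub in np.unique(hier.subsystem_of[hier.system_of == own_sys]):
        members = [
            m for m in np.flatnonzero(hier.subsystem_of == sub) if m not in seed_members
        ]
        if members:
            aggregates.append(members)
    for s in range(hier.system_of.max() + 1):
        if s == own_sys:
            continue
        members = [
            m for m in np.flatnonzero(hier.system_of == s) if m not in seed_members
        ]
        if members:
            aggregates.append(members)

    gc_vals = np.full(n, np.nan)
    p_vals = np.full(n, np.nan)
    seed_set = set(seed_members)
    for j in range(n):
        if j in seed_set:
            continue
        cset = ConditioningSet(driver=j, mode="ti", aggregates=aggregates)
        z = aggregate_signals(ts.data, cset, j)
        if direction == "out":
            res = gc_from_series(ts.data[:, j], seed_sig, z, config.p)
        else:
            res = gc_from_series(seed_sig, ts.data[:, j], z, config.p)
        gc_vals[j] = res.gc
        p_vals[j] = res.p_value
    significant = np.where(np.isnan(p_vals), False, p_vals < config.alpha)
    return SeedMap(
        direction=direction,
        gc_values=gc_vals,
        p_values=p_vals,
        significant=significant,
        alpha=config.alpha,
    )


def reproducibility_map(maps: Sequence[SeedMap]) -> ReproducibilityMap:
    """Per-voxel fraction of subjects with a significant F value."""
    maps = list(maps)
    if not maps:
        raise ValueError("empty map list")
    lengths = {len(m.significant) for m in maps}
    if len(lengths) != 1:
        raise ValueError("maps have differing lengths")
    counts = np.sum([m.significant.astype(int) for m in maps], axis=0)
    return ReproducibilityMap(
        fraction=counts / len(maps), n_subjects=len(maps)
    )


def voxelwise_network(
    ts: TimeSeriesSet,
    hier: HierPartition,
    config: RunConfig | None = None,
    mode: str = "t",
) -> tuple[np.ndarray, np.ndarray]:
    """Full aggregated-conditioning causality matrix + p-value matrix."""
    config = config or RunConfig()
    if ts.n_vars < 3:
        raise ValueError("need at least 3 variables")
    mat: GCMatrix = pcgc_t_matrix(ts, hier, p=config.p, mode=mode)
    return mat.gc, mat.p_value


def gcd_maps(
    gc_matrix: np.ndarray,
    p_matrix: np.ndarray | None,
    config: RunConfig | None = None,
    mode: str = "binary",
    threshold_kind: str = "weight",
) -> tuple[np.ndarray, np.ndarray]:
    """Incoming and outgoing Granger-causality-density maps.

    The adjacency comes from thresholding either the causality weights
    (``weight``: strictly above ``config.weight_threshold``) or the
    p-values (``pvalue``: below ``config.alpha``); degrees are counts in
    binary mode and weight sums in weighted mode.  Row i -> column j
    encodes i causes j, so the incoming map is the column degree.
    """
    config = config or RunConfig()
    gc_matrix = np.asarray(gc_matrix, dtype=float)
    if gc_matrix.ndim != 2 or gc_matrix.shape[0] != gc_matrix.shape[1]:
        raise ValueError("gc matrix must be square")
    if threshold_kind == "weight":
        adj = threshold_graph(gc_matrix, config.weight_threshold, mode)
    elif threshold_kind == "pvalue":
        if p_matrix is None:
            raise ValueError("p-value thresholding requires the p matrix")
        keep = np.asarray(p_matrix) < config.alpha
        np.fill_diagonal(keep, False)
        adj = np.where(keep, 1.0 if mode == "binary" else gc_matrix, 0.0)
    else:
        raise ValueError("threshold_kind must be 'weight' or 'pvalue'")
    incoming = degree_centrality(adj, "in")
    outgoing = degree_centrality(adj, "out")
    return incoming, outgoing


def fcd_map(
    ts: TimeSeriesSet,
    config: RunConfig | None = None,
    mode: str = "binary",
) -> np.ndarray:
    """Functional-connectivity-density comparison map.

    Degree of the thresholded absolute Pearson correlation graph — the
    undirected counterpart of the GCD maps, computed with the same
    thresholding conventions.
    """
    config = config or RunConfig()
    r = np.abs(correlation_matrix(ts))
    np.fill_diagonal(r, 0.0)
    adj = threshold_graph(r, config.weight_threshold, mode)
    return degree_centrality(adj, "in")
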