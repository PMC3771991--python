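"""Directed-graph centrality, hub identification and cluster filtering.

Conventions: adjacency row i -> column j encodes "i causes j".  Degree
centrality sums edge weights per node, separately for incoming (column
sums) and outgoing (row sums) links.  Betweenness counts the fraction of
all-pairs shortest paths through each node (edge length = 1/weight on
weighted graphs, so strong links are short).  The directed clustering
coefficient of a node counts the directed links that exist among its out-
(or in-) neighbours relative to the k(k-1) possible ones.

Centralities are compared across subjects after dividing each node's value
by that subject's across-node mean; a node is a hub for a measure when its
normalized value exceeds mean + SD over nodes, and a hub overall at a
hub score (number of measures fulfilled) of 2 or 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage


@dataclass
class CentralityTable:
    """Per-node centralities for one directed graph."""

    dc_in: np.ndarray
    dc_out: np.ndarray
    bc: np.ndarray
    cc_in: np.ndarray
    cc_out: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.dc_in, self.dc_out, self.bc, self.cc_in, self.cc_out])

    header = ("dc_in", "dc_out", "bc", "cc_in", "cc_out")


def threshold_graph(
    w: np.ndarray, threshold: float = 0.3, mode: str = "binary"
) -> np.ndarray:
    """Keep weights strictly above ``threshold``; zero the rest.

    Binary mode sets survivors to 1, weighted mode keeps their values.
    Granger causality weights are nonnegative, so negative entries are
    rejected.
    """
    w = np.asarray(w, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if (w < 0).any():
        raise ValueError("negative weights are not allowed")
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    keep = w > threshold
    np.fill_diagonal(keep, False)
    return np.where(keep, 1.0 if mode == "binary" else w, 0.0)


def degree_centrality(adj: np.ndarray, direction: str = "in") -> np.ndarray:
    """Sum of edge weights per node; in = column sums, out = row sums."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if direction == "in":
        return adj.sum(axis=0)
    if direction == "out":
        return adj.sum(axis=1)
    raise ValueError("direction must be 'in' or 'out'")


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Directed betweenness: shortest-path pair fractions through each node.

    Weighted graphs use edge length 1/weight; disconnected pairs contribute
    nothing.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    n = adj.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j] > 0:
                g.add_edge(i, j, length=1.0 / adj[i, j])
    vals = nx.betweenness_centrality(g, normalized=False, weight="length")
    return np.array([vals[i] for i in range(n)])


def clustering_coefficient(adj: np.ndarray, direction: str = "out") -> np.ndarray:
    """Directed clustering from per-direction neighbour sets.

    For ``out``: the neighbours of node v are its out-neighbours, and the
    coefficient is the number of existing directed links among them over
    k(k-1); nodes with k < 2 get 0.  The graph is binarized internally for
    the neighbour definition.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    b = (adj > 0).astype(float)
    np.fill_diagonal(b, 0.0)
    n = b.shape[0]
    cc = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(b[v] if direction == "out" else b[:, v])
        k = nbrs.size
        if k < 2:
            continue
        sub = b[np.ix_(nbrs, nbrs)]
        cc[v] = sub.sum() / (k * (k - 1))
    return cc


def centrality_table(adj: np.ndarray) -> CentralityTable:
    return CentralityTable(
        dc_in=degree_centrality(adj, "in"),
        dc_out=degree_centrality(adj, "out"),
        bc=betweenness_centrality(adj),
        cc_in=clustering_coefficient(adj, "in"),
        cc_out=clustering_coefficient(adj, "out"),
    )


def normalize_nodal(values: np.ndarray) -> np.ndarray:
    """Cross-subject normalized nodal parameter.

    ``values`` is subjects x nodes.  Each node's value is divided by its
    subject's across-node mean, then averaged over subjects; when every
    subject contributes all nodes the result has across-node mean 1.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    means = values.mean(axis=1)
    if np.any(means <= 0):
        bad = int(np.flatnonzero(means <= 0)[0])
        raise ValueError(f"subject {bad} has nonpositive mean nodal value")
    return (values / means[:, None]).mean(axis=0)


def identify_hubs(
    bc_n: np.ndarray, cc_n: np.ndarray, dc_n: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hub scores (0-3) and the hub mask (score >= 2).

    A node scores one point per measure whose normalized value strictly
    exceeds mean + SD of that measure over the supplied nodes; a constant
    measure (SD = 0) contributes no hubs.
    """
    vecs = [np.asarray(v, dtype=float) for v in (bc_n, cc_n, dc_n)]
    if len({v.size for v in vecs}) != 1:
        raise ValueError("vectors must have equal length")
    score = np.zeros(vecs[0].size, dtype=int)
    for v in vecs:
        score += (v > v.mean() + v.std(ddof=1 if v.size > 1 else 0)).astype(int)
    return score, score >= 2


def cluster_extent_filter(
    mask: np.ndarray, min_voxels: int = 27, connectivity: int = 26
) -> np.ndarray:
    """Drop connected components smaller than ``min_voxels``.

    Contiguity defaults to 26-neighbour (face + edge + corner, the full
    3 x 3 x 3 neighbourhood); 6 selects face-only.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labeled, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
    keep_ids = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(labeled, keep_ids)
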