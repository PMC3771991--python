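"""Directed-network centrality and hub identification.

Thresholds a causality matrix from a small simulated network into a
binary directed graph, computes in/out degree, betweenness and directed
clustering, normalizes across simulated "subjects" and scores hubs.
"""

import numpy as np

from pcgc import (
    TimeSeriesSet,
    betweenness_centrality,
    clustering_coefficient,
    degree_centrality,
    identify_hubs,
    normalize_nodal,
    pairwise_gc_matrix,
    threshold_graph,
)

n, t = 12, 1500
dc_all, bc_all, cc_all = [], [], []
for subject in range(5):
    rng = np.random.default_rng(subject)
    data = rng.standard_normal((t, n))
    # node 0 is a broadcaster: it drives nodes 1..5 with a one-step lag,
    # and node 3 relays the flow onward to nodes 6 and 7
    for j in range(1, 6):
        data[1:, j] += 0.6 * data[:-1, 0]
    for j in (6, 7):
        data[1:, j] += 0.6 * data[:-1, 3]
    # links among the broadcaster's targets give its neighbourhood
    # nonzero clustering
    data[1:, 2] += 0.6 * data[:-1, 1]
    data[1:, 5] += 0.6 * data[:-1, 4]
    mat = pairwise_gc_matrix(TimeSeriesSet(data))
    adj = np.where(mat.significant(0.01), 1.0, 0.0)
    dc_all.append(degree_centrality(adj, "out"))
    bc_all.append(betweenness_centrality(adj))
    cc_all.append(clustering_coefficient(adj, "out"))

dc_n = normalize_nodal(np.array(dc_all))
bc_n = normalize_nodal(np.array(bc_all))
cc_n = normalize_nodal(np.array(cc_all))
score, hubs = identify_hubs(bc_n, cc_n, dc_n)

print("node  dc_norm  bc_norm  cc_norm  hub_score")
for v in range(n):
    mark = "  <- hub" if hubs[v] else ""
    print(f"{v:4d}  {dc_n[v]:7.2f}  {bc_n[v]:7.2f}  {cc_n[v]:7.2f}  {score[v]:9d}{mark}")
print()
print("Nodes on the planted causal pathways score high: the relay nodes")
print("exceed mean + SD on two or three normalized measures (hub score")
print(">= 2) and are flagged as hubs.  The pure source (node 0) has high")
print("out-degree and clustering but zero betweenness - no shortest path")
print("passes *through* a source - while the unconnected noise nodes")
print("score zero throughout.")
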