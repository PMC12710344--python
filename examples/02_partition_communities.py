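"""Partition a co-occurrence network into communities with random walks.

Short random walks tend to stay inside densely connected groups, so nodes
with similar 4-step walk profiles are merged agglomeratively; the dendrogram
is cut at the level of maximum weighted modularity.
"""

import networkx as nx

from mnetclass import CorrelationNetwork, walktrap_partition

# two 5-cliques joined by a single bridge edge — an obvious two-community
# structure with mixed-sign correlations
g = nx.Graph()
for base, sign in ((0, 1), (5, -1)):
    for i in range(5):
        for j in range(i + 1, 5):
            g.add_edge(base + i, base + j, rho=sign * 0.9)
g.add_edge(0, 5, rho=0.85)
net = CorrelationNetwork(graph=g, threshold=0.0, alpha=1.0)

part = walktrap_partition(net, t=4)
print(f"{part.n_communities} communities "
      f"(weighted modularity {part.modularity:.3f}):")
for k, comm in enumerate(part.communities, 1):
    print(f"  community {k}: {sorted(comm)}")
# Negative correlations enter as absolute weights, so the all-negative clique
# is recovered exactly like the positive one; the modularity (~0.45) says the
# split is far denser within communities than a degree-matched random graph.
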