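"""Random-walk (Walktrap) community detection on the co-occurrence network.

A t-step random walk started at a node tends to stay inside the node's
community, so the probability profile ``P^t_i.`` characterizes where the node
sits in the mesoscale structure.  Nodes (and communities) are compared through
the degree-weighted Euclidean distance between their t-step profiles:

    r_ij^2     = sum_k (P^t_ik - P^t_jk)^2 / d(k)
    r_C1C2^2   = sum_k (P^t_C1k - P^t_C2k)^2 / d(k),   P^t_Ck = mean over i in C

Starting from singletons, communities are merged agglomeratively.  At each
step the pair of *adjacent* communities whose merge least increases the mean
squared distance between nodes and their community profile (the Ward-like
criterion of Pons & Latapy) is fused; the flat partition returned is the
dendrogram level of maximum weighted modularity.

Negative correlations enter as absolute values: the walk needs non-negative
weights, and strong negative co-occurrence is still strong association.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyNetworkError, IsolatedNode
from .netbuild import CorrelationNetwork

__all__ = [
    "RandomWalkModel",
    "Partition",
    "transition_matrix",
    "walk_distance",
    "community_distance",
    "walktrap_partition",
    "weighted_modularity",
    "write_membership",
    "write_dendrogram",
]


@dataclass
class RandomWalkModel:
    """Transition structure of the t-step random walk on |weights|.

    ``nodes`` lists the non-isolated nodes (walk support); ``isolated`` the
    degree-zero nodes, which bypass the walk and become singleton
    communities.  ``P`` is the one-step row-stochastic transition matrix
    D^-1 A over ``nodes``; ``Pt`` its t-th power.
    """

    nodes: list
    isolated: list
    A_abs: np.ndarray
    degrees: np.ndarray
    P: np.ndarray
    Pt: np.ndarray
    t: int

    def index(self, node) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            if node in self.isolated:
                raise IsolatedNode(f"node {node!r} is isolated") from None
            raise KeyError(node) from None


@dataclass
class Partition:
    """Flat community assignment plus the agglomerative merge history.

    ``dendrogram`` rows are (left, right, merged, height): internal integer
    community labels (initial singletons are 0..n-1 in ``walk_nodes`` order)
    and the Ward-like merge cost.  ``modularity_trace[l]`` is the weighted
    modularity of the partition after ``l`` merges; the returned flat
    ``communities`` correspond to the trace argmax, with isolated nodes
    appended as singletons.
    """

    membership: dict
    communities: list[frozenset]
    dendrogram: list[tuple[int, int, int, float]]
    modularity_trace: list[float]
    cut_level: int
    modularity: float
    walk_nodes: list

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def community_of(self, node):
        return self.membership[node]


def _abs_adjacency(network: CorrelationNetwork) -> tuple[list, np.ndarray]:
    nodes = list(network.graph.nodes)
    a = nx.to_numpy_array(network.graph, nodelist=nodes, weight="rho")
    return nodes, np.abs(a)


def transition_matrix(network: CorrelationNetwork, t: int = 4) -> RandomWalkModel:
    """Build the t-step random-walk model on absolute edge weights."""
    if network.n_nodes == 0:
        raise EmptyNetworkError("network has no nodes")
    all_nodes, a = _abs_adjacency(network)
    deg = a.sum(axis=1)
    noniso = deg > 0
    nodes = [n for n, keep in zip(all_nodes, noniso) if keep]
    isolated = [n for n, keep in zip(all_nodes, noniso) if not keep]
    a = a[np.ix_(noniso, noniso)]
    d = deg[noniso]
    if len(nodes) == 0:
        P = np.zeros((0, 0))
        return RandomWalkModel(nodes, isolated, a, d, P, P.copy(), t)
    P = a / d[:, None]
    Pt = np.linalg.matrix_power(P, t)
    return RandomWalkModel(nodes, isolated, a, d, P, Pt, t)


def walk_distance(model: RandomWalkModel, i, j) -> float:
    """Degree-weighted Euclidean distance between t-step profiles of two nodes."""
    ii, jj = model.index(i), model.index(j)
    diff = model.Pt[ii] - model.Pt[jj]
    return float(np.sqrt(np.sum(diff**2 / model.degrees)))


def community_distance(model: RandomWalkModel, C1: Iterable, C2: Iterable) -> float:
    """Distance between two disjoint communities via averaged walk profiles."""
    idx1 = [model.index(n) for n in C1]
    idx2 = [model.index(n) for n in C2]
    if not idx1 or not idx2:
        raise ValueError("communities must be nonempty")
    if set(idx1) & set(idx2):
        raise ValueError("communities must be disjoint")
    p1 = model.Pt[idx1].mean(axis=0)
    p2 = model.Pt[idx2].mean(axis=0)
    return float(np.sqrt(np.sum((p1 - p2) ** 2 / model.degrees)))


def weighted_modularity(network: CorrelationNetwork,
                        communities: Sequence[Iterable]) -> float:
    """Newman modularity with absolute edge weights.

    Q = sum_c [ w_in_c / (2m) - (d_c / (2m))^2 ] where w_in_c counts internal
    weight twice (both edge directions), d_c is the total absolute strength
    of the community, and 2m the total strength of the graph.
    """
    nodes, a = _abs_adjacency(network)
    idx = {n: k for k, n in enumerate(nodes)}
    deg = a.sum(axis=1)
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        ids = [idx[n] for n in comm]
        sub = a[np.ix_(ids, ids)]
        w_in = sub.sum()  # counts each internal edge twice
        d_c = deg[ids].sum()
        q += w_in / two_m - (d_c / two_m) ** 2
    return float(q)


def _pair_key(c1: int, c2: int) -> tuple[int, int]:
    return (c1, c2) if c1 < c2 else (c2, c1)


def walktrap_partition(network: CorrelationNetwork, t: int = 4) -> Partition:
    """Agglomerative random-walk partition of the network.

    Merges only adjacent (edge-connected) community pairs, at each step the
    pair minimizing the Ward-like cost

        delta_sigma(C1, C2) = |C1| |C2| / (|C1| + |C2|) * r_C1C2^2 / n,

    ties broken by the smallest community-id pair.  The flat partition is the
    merge level with maximum weighted modularity (ties resolved toward the
    more merged level); isolated nodes are appended as singletons.
    """
    if network.n_edges == 0:
        if network.n_nodes == 0:
            raise EmptyNetworkError("network has no nodes")
        comms = [frozenset([n]) for n in network.graph.nodes]
        membership = {n: k for k, c in enumerate(comms) for n in c}
        return Partition(membership, comms, [], [0.0], 0, 0.0,
                         walk_nodes=[])
    model = transition_matrix(network, t=t)
    n = len(model.nodes)
    deg = model.degrees

    # community state: id -> (member indices, size-weighted profile sum, size)
    members: dict[int, set[int]] = {k: {k} for k in range(n)}
    prof_sum: dict[int, np.ndarray] = {k: model.Pt[k].copy() for k in range(n)}
    size: dict[int, int] = {k: 1 for k in range(n)}
    neighbors: dict[int, set[int]] = {k: set() for k in range(n)}
    for u, v in network.graph.edges:
        if u in model.isolated or v in model.isolated:
            continue
        iu, iv = model.index(u), model.index(v)
        if iu != iv:
            neighbors[iu].add(iv)
            neighbors[iv].add(iu)

    def delta_sigma(c1: int, c2: int) -> float:
        p1 = prof_sum[c1] / size[c1]
        p2 = prof_sum[c2] / size[c2]
        r2 = float(np.sum((p1 - p2) ** 2 / deg))
        s1, s2 = size[c1], size[c2]
        return s1 * s2 / (s1 + s2) * r2 / n

    # incremental modularity bookkeeping on absolute weights
    two_m = deg.sum()
    strength: dict[int, float] = {k: float(deg[k]) for k in range(n)}
    w_in: dict[int, float] = {k: 0.0 for k in range(n)}
    w_between: dict[tuple[int, int], float] = {}
    for u, v, d_attr in network.graph.edges(data=True):
        if u in model.isolated or v in model.isolated:
            continue
        iu, iv = model.index(u), model.index(v)
        key = _pair_key(iu, iv)
        w_between[key] = w_between.get(key, 0.0) + abs(d_attr["rho"])

    q = -float(np.sum((deg / two_m) ** 2))
    trace = [q]
    dendrogram: list[tuple[int, int, int, float]] = []
    active = set(range(n))
    next_id = n

    # candidate costs, refreshed lazily per step (n is small in practice)
    while True:
        best: tuple[float, int, int] | None = None
        for c1 in sorted(active):
            for c2 in sorted(neighbors[c1]):
                if c2 <= c1:
                    continue
                ds = delta_sigma(c1, c2)
                cand = (ds, c1, c2)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        ds, c1, c2 = best
        new = next_id
        next_id += 1
        members[new] = members.pop(c1) | members.pop(c2)
        prof_sum[new] = prof_sum.pop(c1) + prof_sum.pop(c2)
        size[new] = size.pop(c1) + size.pop(c2)
        strength[new] = strength.pop(c1) + strength.pop(c2)
        between = w_between.pop(_pair_key(c1, c2), 0.0)
        w_in[new] = w_in.pop(c1) + w_in.pop(c2) + between
        nbrs = (neighbors.pop(c1) | neighbors.pop(c2)) - {c1, c2}
        neighbors[new] = nbrs
        for other in nbrs:
            neighbors[other].discard(c1)
            neighbors[other].discard(c2)
            neighbors[other].add(new)
            w = (w_between.pop(_pair_key(c1, other), 0.0)
                 + w_between.pop(_pair_key(c2, other), 0.0))
            if w:
                w_between[_pair_key(new, other)] = w
        active -= {c1, c2}
        active.add(new)
        q = (sum(2 * w_in[c] for c in active) / two_m
             - sum((strength[c] / two_m) ** 2 for c in active))
        trace.append(q)
        dendrogram.append((c1, c2, new, ds))

    # cut at the max-modularity level; among ties keep the most merged one
    best_q = max(round(x, 12) for x in trace)
    best_level = next(
        lvl for lvl in range(len(trace) - 1, -1, -1)
        if round(trace[lvl], 12) == best_q
    )

    comm_ids: dict[int, set[int]] = {k: {k} for k in range(n)}
    for c1, c2, new, _ in dendrogram[:best_level]:
        comm_ids[new] = comm_ids.pop(c1) | comm_ids.pop(c2)
    comms = [frozenset(model.nodes[i] for i in s) for s in comm_ids.values()]
    comms.extend(frozenset([node]) for node in model.isolated)
    # deterministic community order: by size desc, then smallest member id
    comms.sort(key=lambda c: (-len(c), sorted(map(str, c))[0]))
    membership = {node: k for k, c in enumerate(comms) for node in c}
    q_final = weighted_modularity(network, comms)
    return Partition(membership, comms, dendrogram, trace, best_level,
                     q_final, walk_nodes=list(model.nodes))


def write_membership(partition: Partition, path: str | Path) -> None:
    """Write (taxon, community_id) as TSV, community ids 1-based."""
    rows = [(str(node), cid + 1) for node, cid in partition.membership.items()]
    rows.sort(key=lambda r: (r[1], r[0]))
    pd.DataFrame(rows, columns=["taxon", "community_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_dendrogram(partition: Partition, path: str | Path) -> None:
    """Write the merge history as a nested, Newick-like string with heights."""

    labels: dict[int, str] = {
        k: str(node) for k, node in enumerate(partition.walk_nodes)
    }
    heights: dict[int, float] = {k: 0.0 for k in labels}
    for c1, c2, new, h in partition.dendrogram:
        labels[new] = f"({labels.pop(c1)},{labels.pop(c2)}):{h:.6g}"
        heights[new] = h
    trees = [labels[k] for k in sorted(labels)]
    text = ";\n".join(trees) + ";\n" if trees else ""
    Path(path).write_text(text)
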