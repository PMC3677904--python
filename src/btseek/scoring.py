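"""Partition-quality scores: block-image error E, NMI, and modularity Q.

The error function E treats a partition as a block image of the
adjacency matrix: each block (diagonal or off-diagonal) is idealized as
either completely full or completely empty, whichever is cheaper, where
an edge sitting in an "empty" block costs (1 - rho) and a missing edge
in a "full" block costs rho, with rho the global edge density.  E is the
total mismatch cost; it is 0 exactly when every block is completely full
or completely empty, so both assortative (dense diagonal) and
disassortative (dense off-diagonal, i.e. sparse-module) structure can
reach a perfect score.  Lower is better.
"""

from __future__ import annotations

from sklearn.metrics import normalized_mutual_info_score

from .metrics import ModuleStats, module_stats
from .netio import Network, Partition

__all__ = ["error_E", "error_E_from_stats", "nmi", "modularity"]


def error_E_from_stats(stats: ModuleStats) -> float:
    """Block-image error from precomputed block statistics."""
    rho = stats.rho
    mods = stats.modules()
    total = 0.0
    # blocks with zero edges cost min((1-rho)*0, rho*L) = 0, so only
    # blocks that actually contain edges can contribute
    for k in mods:
        l = stats.internal_edges[k]
        if l:
            cap = stats.block_capacity(k, k)
            total += min((1.0 - rho) * l, rho * (cap - l))
    for (r, s), l in stats.inter_edges.items():
        cap = stats.block_capacity(r, s)
        total += min((1.0 - rho) * l, rho * (cap - l))
    return total


def error_E(network: Network, partition: Partition) -> float:
    """Block-image mismatch cost of ``partition`` on ``network`` (>= 0).

    E = sum over module pairs r <= s of min((1-rho) l_rs, rho (L_rs - l_rs)).
    Bounded above by (1 - rho) * m, the cost of the all-empty image.
    """
    if network.n == 0:
        raise ValueError("empty network")
    return error_E_from_stats(module_stats(network, partition))


def nmi(p: Partition, q: Partition) -> float:
    """Normalized mutual information 2 I(P;Q) / (H(P) + H(Q)) in [0, 1].

    Symmetric; 1 for identical groupings.  Degenerate conventions: 1 when
    both partitions are single-module (both entropies 0), 0 when exactly
    one is.
    """
    if p.nodes != q.nodes:
        diff = sorted(p.nodes ^ q.nodes)
        raise ValueError(f"partitions cover different nodes, e.g. {diff[:5]}")
    order = sorted(p.nodes)
    a = [p[v] for v in order]
    b = [q[v] for v in order]
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def modularity(network: Network, partition: Partition) -> float:
    """Newman-Girvan modularity Q = sum_k [l_k/m - (d_k/2m)^2], in [-1, 1].

    High for assortative (cohesive) structure; planted disassortative
    (sparse-module) structure scores near or below zero, which is why a
    modularity maximizer cannot see it.
    """
    if network.m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    stats = module_stats(network, partition)
    m = stats.m
    q = 0.0
    for k in stats.modules():
        q += stats.internal_edges[k] / m - (stats.degree_sum[k] / (2.0 * m)) ** 2
    return q
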