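"""Comparison protocol against greedy-modularity (fast agglomerative) partitions.

A cohesive-only detector splits a network into modules that maximize
modularity Q; modules smaller than a size cutoff (default 10) tend to
lack clear modular significance, and the interesting question is how
their nodes redistribute over the sparse/cohesive labeling the tree
search produces.  :func:`overlap_report` tabulates exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import LabeledPartition
from .netio import Network, Partition

__all__ = ["OverlapReport", "greedy_modularity_partition", "overlap_report"]


def greedy_modularity_partition(
    network: Network, return_trace: bool = False
):
    """Fast agglomerative modularity maximization (CNM-style).

    Starts from singleton modules (numbered 1..n in sorted label order)
    and repeatedly merges the connected module pair with the largest
    modularity gain dQ = l_rs/m - d_r d_s / (2 m^2), ties broken by the
    smallest (r, s) label pair, stopping at the first non-positive gain.
    Accepted gains are all positive, so the final state is the Q maximum
    along the merge path.

    With ``return_trace=True`` also returns the list of accepted merges
    as ``(r, s, dQ)`` triples for oracle checking.
    """
    if network.m == 0:
        raise ValueError("greedy modularity needs at least one edge")
    m = float(network.m)
    nodes = sorted(network.nodes)
    label_of = {v: i + 1 for i, v in enumerate(nodes)}
    members: dict[int, set[str]] = {label_of[v]: {v} for v in nodes}
    deg_sum = {label_of[v]: float(network.degree(v)) for v in nodes}
    inter: dict[tuple[int, int], float] = {}
    for u, v in network.edges():
        r, s = label_of[u], label_of[v]
        key = (min(r, s), max(r, s))
        inter[key] = inter.get(key, 0.0) + 1.0
    trace: list[tuple[int, int, float]] = []
    while True:
        best: tuple[float, int, int] | None = None
        for (r, s), l_rs in inter.items():
            dq = l_rs / m - deg_sum[r] * deg_sum[s] / (2.0 * m * m)
            if best is None or dq > best[0] + 1e-12 or (
                abs(dq - best[0]) <= 1e-12 and (r, s) < (best[1], best[2])
            ):
                best = (dq, r, s)
        if best is None or best[0] <= 1e-12:
            break
        dq, r, s = best
        trace.append((r, s, dq))
        members[r] |= members.pop(s)
        deg_sum[r] += deg_sum.pop(s)
        # fold s's inter-module counts into r
        new_inter: dict[tuple[int, int], float] = {}
        for (a, b), l in inter.items():
            a = r if a == s else a
            b = r if b == s else b
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            new_inter[key] = new_inter.get(key, 0.0) + l
        inter = new_inter
    part = Partition.from_groups(
        [members[k] for k in sorted(members)]
    )
    return (part, trace) if return_trace else part


@dataclass
class OverlapReport:
    """2x3 node-overlap table between a size-split comparison partition
    (small vs large modules) and a sparse/cohesive/ambiguous labeling."""

    table: pd.DataFrame  # rows: small, large; cols: sparse, cohesive, ambiguous
    size_cutoff: int

    @property
    def small_nodes(self) -> int:
        return int(self.table.loc["small"].sum())

    @property
    def large_nodes(self) -> int:
        return int(self.table.loc["large"].sum())

    @property
    def sparse_nodes(self) -> int:
        return int(self.table["sparse"].sum())

    @property
    def cohesive_nodes(self) -> int:
        return int(self.table["cohesive"].sum())

    @property
    def ambiguous_nodes(self) -> int:
        return int(self.table["ambiguous"].sum())

    @property
    def small_sparse(self) -> int:
        return int(self.table.loc["small", "sparse"])

    @property
    def large_cohesive(self) -> int:
        return int(self.table.loc["large", "cohesive"])

    @property
    def n(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            fh.write(f"# size_cutoff={self.size_cutoff} (small: size < cutoff)\n")
            self.table.to_csv(fh, sep="\t")


def overlap_report(
    labeled: LabeledPartition, comparison: Partition, size_cutoff: int = 10
) -> OverlapReport:
    """Cross-tabulate comparison-module size class against module labels.

    A comparison module is *small* when its size is strictly below
    ``size_cutoff``.  Row and column sums both equal the node count.
    """
    bts_nodes = labeled.partition.nodes
    if bts_nodes != comparison.nodes:
        diff = sorted(bts_nodes ^ comparison.nodes)
        raise ValueError(f"partitions cover different nodes, e.g. {diff[:5]}")
    comp_sizes: dict[int, int] = {}
    for mod in comparison.assignment.values():
        comp_sizes[mod] = comp_sizes.get(mod, 0) + 1
    table = pd.DataFrame(
        0, index=["small", "large"], columns=["sparse", "cohesive", "ambiguous"]
    )
    for node in bts_nodes:
        size_class = "small" if comp_sizes[comparison[node]] < size_cutoff else "large"
        lab = labeled.label[labeled.partition[node]]
        table.loc[size_class, lab] += 1
    return OverlapReport(table=table, size_cutoff=size_cutoff)
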