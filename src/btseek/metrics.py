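"""Block statistics of a partitioned network and the three-threshold
module classification into cohesive, sparse, and ambiguous.

The classification thresholds are a triple (a1, a2, a3):

* ``a1`` — lower limit on the internal stub fraction ``f_in`` of a
  cohesive module (fraction of the module's edge endpoints that stay
  inside it, dimensionless in [0, 1]);
* ``a2`` — upper limit on the mean internal degree ``a_int`` of a sparse
  module (internal edges per node, >= 0);
* ``a3`` — lower limit on the bridge density ``b(r, s)`` between two
  modules (inter-module edges per node on the smaller side) required for
  a bridge to count.

A module is *cohesive* if ``f_in >= a1``; otherwise it is *sparse* if
``a_int <= a2`` and it participates in at least one bridge; anything
else is *ambiguous* (and remains splittable for the tree search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .netio import Network, Partition

__all__ = [
    "ThresholdTriple",
    "CLASSICAL",
    "PRESETS",
    "ModuleStats",
    "LabeledPartition",
    "module_stats",
    "classify_modules",
    "summarize",
    "write_summary",
]


@dataclass(frozen=True)
class ThresholdTriple:
    """Classification thresholds (a1, a2, a3); see module docstring."""

    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a1 <= 1.0:
            raise ValueError("a1 must lie in [0, 1]")
        if self.a2 < 0 or self.a3 < 0:
            raise ValueError("a2 and a3 must be non-negative")

    def __iter__(self):
        yield from (self.a1, self.a2, self.a3)

    def __str__(self) -> str:
        return f"({self.a1:g}, {self.a2:g}, {self.a3:g})"


#: The classical triple, the recommended default.
CLASSICAL = ThresholdTriple(0.7, 1.5, 1.0)

#: The six standard presets (classical first).
PRESETS: tuple[ThresholdTriple, ...] = (
    CLASSICAL,
    ThresholdTriple(0.5, 1.3, 1.0),
    ThresholdTriple(0.5, 1.7, 1.0),
    ThresholdTriple(0.85, 1.3, 1.0),
    ThresholdTriple(0.8, 1.4, 1.0),
    ThresholdTriple(0.5, 1.5, 1.0),
)


@dataclass
class ModuleStats:
    """Edge/density bookkeeping of a partitioned network.

    All per-module densities of singleton modules are defined as 0.
    Edge conservation holds exactly:
    ``sum(internal_edges) + sum(inter_edges) == m``.
    """

    network: Network
    partition: Partition
    module_size: dict[int, int] = field(default_factory=dict)
    internal_edges: dict[int, int] = field(default_factory=dict)
    degree_sum: dict[int, int] = field(default_factory=dict)
    inter_edges: dict[tuple[int, int], int] = field(default_factory=dict)

    # -- global -----------------------------------------------------------
    @property
    def n(self) -> int:
        return self.network.n

    @property
    def m(self) -> int:
        return self.network.m

    @property
    def rho(self) -> float:
        """Global edge density 2m / n(n-1); 0 for n < 2."""
        n = self.n
        return 2.0 * self.m / (n * (n - 1)) if n >= 2 else 0.0

    # -- per module -------------------------------------------------------
    def internal_density(self, k: int) -> float:
        """d_in(k) = 2 l_k / n_k(n_k - 1)."""
        n_k = self.module_size[k]
        if n_k < 2:
            return 0.0
        return 2.0 * self.internal_edges[k] / (n_k * (n_k - 1))

    def stub_fraction(self, k: int) -> float:
        """f_in(k) = 2 l_k / sum of degrees in k (0 if degree sum is 0)."""
        d = self.degree_sum[k]
        return 2.0 * self.internal_edges[k] / d if d > 0 else 0.0

    def mean_internal_degree(self, k: int) -> float:
        """a_int(k) = 2 l_k / n_k."""
        return 2.0 * self.internal_edges[k] / self.module_size[k]

    # -- per pair ---------------------------------------------------------
    def pair_edges(self, r: int, s: int) -> int:
        return self.inter_edges.get((min(r, s), max(r, s)), 0)

    def bridge_density(self, r: int, s: int) -> float:
        """b(r, s) = l_rs / min(n_r, n_s)."""
        return self.pair_edges(r, s) / min(self.module_size[r], self.module_size[s])

    def block_capacity(self, r: int, s: int) -> int:
        """Maximum possible edges of block (r, s): n_r n_s off the diagonal,
        n_k(n_k - 1)/2 on it."""
        if r == s:
            n_k = self.module_size[r]
            return n_k * (n_k - 1) // 2
        return self.module_size[r] * self.module_size[s]

    def modules(self) -> list[int]:
        return sorted(self.module_size)


def module_stats(network: Network, partition: Partition) -> ModuleStats:
    """Compute block statistics in a single pass over the edges."""
    partition.validate_over(network)
    stats = ModuleStats(network=network, partition=partition)
    for node, k in partition.assignment.items():
        stats.module_size[k] = stats.module_size.get(k, 0) + 1
        stats.degree_sum[k] = stats.degree_sum.get(k, 0) + network.degree(node)
        stats.internal_edges.setdefault(k, 0)
    for u, v in network.edges():
        r, s = partition[u], partition[v]
        if r == s:
            stats.internal_edges[r] += 1
        else:
            key = (min(r, s), max(r, s))
            stats.inter_edges[key] = stats.inter_edges.get(key, 0) + 1
    return stats


@dataclass
class LabeledPartition:
    """A partition with per-module type labels and the bridges found."""

    partition: Partition
    label: dict[int, str]
    bridges: set[tuple[int, int]]
    thresholds: ThresholdTriple
    error: float | None = None
    stats: ModuleStats | None = None

    def nodes_by_label(self) -> dict[str, int]:
        counts = {"cohesive": 0, "sparse": 0, "ambiguous": 0}
        sizes = self.stats.module_size if self.stats else None
        for k, lab in self.label.items():
            size = sizes[k] if sizes else sum(
                1 for m in self.partition.assignment.values() if m == k
            )
            counts[lab] += size
        return counts

    @property
    def n_modules(self) -> int:
        return len(self.label)


def classify_modules(
    stats: ModuleStats, thresholds: ThresholdTriple
) -> LabeledPartition:
    """Label every module cohesive / sparse / ambiguous.

    Cohesive: ``f_in >= a1``.  Sparse: not cohesive, ``a_int <= a2`` and at
    least one bridge with density ``>= a3``.  Everything else: ambiguous.
    """
    a1, a2, a3 = thresholds
    mods = stats.modules()
    bridges = {
        (r, s)
        for r, s in combinations(mods, 2)
        if stats.bridge_density(r, s) >= a3
    }
    bridged = {k for pair in bridges for k in pair}
    label: dict[int, str] = {}
    for k in mods:
        if stats.stub_fraction(k) >= a1:
            label[k] = "cohesive"
        elif stats.mean_internal_degree(k) <= a2 and k in bridged:
            label[k] = "sparse"
        else:
            label[k] = "ambiguous"
    return LabeledPartition(
        partition=stats.partition,
        label=label,
        bridges=bridges,
        thresholds=thresholds,
        stats=stats,
    )


def summarize(labeled: LabeledPartition) -> pd.DataFrame:
    """Per-label-class summary: node counts/fractions and mean module size.

    One row per class in {cohesive, sparse, ambiguous}; node fractions sum
    to 1 over the three rows; ``mean_size`` is NaN for unoccupied classes.
    """
    n = len(labeled.partition)
    stats = labeled.stats
    rows = []
    for cls in ("cohesive", "sparse", "ambiguous"):
        mods = [k for k, lab in labeled.label.items() if lab == cls]
        if stats is not None:
            sizes = [stats.module_size[k] for k in mods]
        else:
            counts: dict[int, int] = {}
            for mod in labeled.partition.assignment.values():
                counts[mod] = counts.get(mod, 0) + 1
            sizes = [counts[k] for k in mods]
        node_count = sum(sizes)
        rows.append(
            {
                "label": cls,
                "node_count": node_count,
                "node_fraction": node_count / n if n else 0.0,
                "module_count": len(mods),
                "mean_size": sum(sizes) / len(sizes) if sizes else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("label")


def write_summary(path, labeled: LabeledPartition, header: str | None = None) -> None:
    """Write the :func:`summarize` table as TSV."""
    df = summarize(labeled)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")
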