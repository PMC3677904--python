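"""Model/results front end for the tree search.

:class:`BinTreeSeeker` is built from a network (plus search settings);
``fit`` runs the search and returns a :class:`BTSResults` carrying the
selected partition, per-module labels and statistics, the achieved error
E, and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import __version__ as _version
from .btsearch import SearchConfig, bts_detect
from .metrics import (
    CLASSICAL,
    LabeledPartition,
    ThresholdTriple,
    module_stats,
    summarize,
)
from .netio import Network, Partition, read_network, write_partition
from .scoring import nmi as _nmi

__all__ = ["BinTreeSeeker", "BTSResults"]


class BinTreeSeeker:
    """Cohesive + sparse module detector for an undirected network.

    Parameters
    ----------
    network : Network
        The graph to divide.
    thresholds : ThresholdTriple or sequence of triples
        Classification thresholds (a1, a2, a3); with several triples the
        search keeps the division with the lowest error E over all of
        them.  Default: the classical (0.7, 1.5, 1).
    sweep_a3 : (start, stop, step), optional
        Vary a3 over a range with a1/a2 fixed — the recommended setting
        for bipartite-style networks.
    merge_pass : bool
        Append a greedy E-decreasing module-merge pass to the selected
        division.
    """

    def __init__(
        self,
        network: Network,
        thresholds: ThresholdTriple | Sequence[ThresholdTriple] = CLASSICAL,
        *,
        min_split_size: int = 4,
        max_depth: int | None = None,
        n_restarts: int = 8,
        sweep_a3: tuple[float, float, float] | None = None,
        merge_pass: bool = False,
    ) -> None:
        self.network = network
        self._base = SearchConfig(
            thresholds=thresholds,
            min_split_size=min_split_size,
            max_depth=max_depth,
            n_restarts=n_restarts,
            sweep_a3=sweep_a3,
            merge_pass=merge_pass,
        )

    @classmethod
    def from_edgelist(cls, path, **kwargs) -> "BinTreeSeeker":
        return cls(read_network(path, format="edgelist"), **kwargs)

    @classmethod
    def from_pajek(cls, path, **kwargs) -> "BinTreeSeeker":
        return cls(read_network(path, format="pajek"), **kwargs)

    def fit(self, seed: int | None = None) -> "BTSResults":
        """Run the search; deterministic given ``seed``."""
        from dataclasses import replace

        config = replace(self._base, seed=seed)
        labeled = bts_detect(self.network, config)
        return BTSResults(self, labeled, seed=seed)


class BTSResults:
    """Outcome of a fitted :class:`BinTreeSeeker`."""

    def __init__(
        self, model: BinTreeSeeker, labeled: LabeledPartition, seed: int | None
    ) -> None:
        self.model = model
        self.labeled = labeled
        self.seed = seed

    # -- primary estimates -----------------------------------------------
    @property
    def partition(self) -> Partition:
        return self.labeled.partition

    @property
    def labels(self) -> dict[int, str]:
        return dict(self.labeled.label)

    @property
    def bridges(self) -> set[tuple[int, int]]:
        return set(self.labeled.bridges)

    @property
    def error(self) -> float:
        """Block-image error E of the selected division (lower is better)."""
        return float(self.labeled.error)

    @property
    def thresholds(self) -> ThresholdTriple:
        return self.labeled.thresholds

    @property
    def n_modules(self) -> int:
        return self.labeled.n_modules

    # -- diagnostics ------------------------------------------------------
    def module_table(self) -> pd.DataFrame:
        """Per-module size, label, and density diagnostics."""
        stats = self.labeled.stats or module_stats(
            self.model.network, self.partition
        )
        rows = []
        for k in stats.modules():
            bridged_with = sorted(
                s for pair in self.labeled.bridges for s in pair if k in pair and s != k
            )
            rows.append(
                {
                    "module": k,
                    "label": self.labeled.label[k],
                    "size": stats.module_size[k],
                    "internal_edges": stats.internal_edges[k],
                    "stub_fraction": stats.stub_fraction(k),
                    "mean_internal_degree": stats.mean_internal_degree(k),
                    "internal_density": stats.internal_density(k),
                    "bridges_with": ",".join(map(str, bridged_with)),
                }
            )
        return pd.DataFrame(rows).set_index("module")

    def label_summary(self) -> pd.DataFrame:
        """Node counts/fractions and mean module size per label class."""
        return summarize(self.labeled)

    def nmi(self, reference: Partition) -> float:
        """Normalized mutual information against a reference partition."""
        return _nmi(self.partition, reference)

    def summary(self) -> str:
        """Plain-text report of the fitted division."""
        net = self.model.network
        head = [
            "BinTree Seeking results",
            "=" * 55,
            f"nodes: {net.n}    edges: {net.m}",
            f"thresholds (a1, a2, a3): {self.thresholds}    seed: {self.seed}",
            f"selected error E: {self.error:.4f}    modules: {self.n_modules}",
            "",
        ]
        table = self.module_table()
        body = table.to_string(
            float_format=lambda x: f"{x:.3f}", max_colwidth=20
        )
        counts = self.labeled.nodes_by_label()
        tail = [
            "",
            "nodes per label: "
            + ", ".join(f"{lab}={cnt}" for lab, cnt in counts.items()),
        ]
        return "\n".join(head) + body + "\n".join(tail)

    def to_tsv(self, partition_path, report_path=None) -> None:
        """Write the partition (and optionally the module report) as TSV."""
        header = (
            f"btseek {_version}; seed={self.seed}; "
            f"thresholds={self.thresholds}; error={self.error:.6f}"
        )
        write_partition(partition_path, self.partition, header=header)
        if report_path is not None:
            with open(report_path, "w") as fh:
                fh.write(f"# {header}\n")
                self.module_table().to_csv(fh, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<BTSResults modules={self.n_modules} "
            f"E={self.error:.3f} thresholds={self.thresholds}>"
        )
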