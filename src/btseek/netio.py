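"""Network and partition containers, file I/O, and network builders.

Networks are undirected simple graphs with opaque string node labels.
Supported on-disk formats: whitespace-separated edge lists ('#' comments),
Pajek ``.net`` files, and two-column TSV partitions.  Builders construct
networks from gene-expression matrices (Pearson-correlation thresholding)
and from rank-preference tables (top-k nomination union).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "Partition",
    "NetworkFormatError",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
    "build_pcc_network",
    "build_topk_network",
]


class NetworkFormatError(ValueError):
    """Raised for malformed network or partition files."""


class Network:
    """Undirected simple graph with stable string node labels.

    Self-loops and duplicate edges are dropped on construction and counted
    in :attr:`n_dropped`.  ``bipartite_class`` optionally annotates each
    node with a side in {0, 1}; it is a bookkeeping flag only and edges are
    never required to respect it.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        bipartite_class: Mapping[str, int] | None = None,
    ) -> None:
        g = nx.Graph()
        for v in nodes:
            g.add_node(str(v))
        dropped = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v or g.has_edge(u, v):
                dropped += 1
                continue
            g.add_edge(u, v)
        self._graph = g
        self.n_dropped = dropped
        if dropped:
            logger.info("dropped %d duplicate/self-loop records", dropped)
        if bipartite_class is not None:
            bc = {str(k): int(v) for k, v in bipartite_class.items()}
            missing = set(g.nodes) - set(bc)
            if missing:
                raise ValueError(
                    f"bipartite_class missing for nodes: {sorted(missing)[:5]}"
                )
            if not set(bc.values()) <= {0, 1}:
                raise ValueError("bipartite classes must be 0 or 1")
            self.bipartite_class: dict[str, int] | None = bc
        else:
            self.bipartite_class = None

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (treat as read-only)."""
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._graph.nodes)

    @property
    def n(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self._graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples with u < v."""
        return [tuple(sorted(e)) for e in self._graph.edges]

    def degree(self, v: str) -> int:
        return self._graph.degree[v]

    def drop_isolated(self) -> "Network":
        """Copy without degree-0 nodes (reported, since some analyses drop them)."""
        keep = [v for v in self.nodes if self._graph.degree[v] > 0]
        n_iso = self.n - len(keep)
        if n_iso:
            logger.info("dropping %d isolated nodes", n_iso)
        bc = (
            {v: self.bipartite_class[v] for v in keep}
            if self.bipartite_class is not None
            else None
        )
        return Network(keep, self.edges(), bipartite_class=bc)

    def adjacency_matrix(self, nodelist: Sequence[str] | None = None) -> np.ndarray:
        """Dense 0/1 adjacency over ``nodelist`` (default: all nodes)."""
        nodelist = list(nodelist) if nodelist is not None else list(self.nodes)
        return nx.to_numpy_array(self._graph, nodelist=nodelist, dtype=np.int8)

    def __contains__(self, v: str) -> bool:
        return v in self._graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n={self.n}, m={self.m})"


class Partition:
    """Total, non-overlapping assignment of node labels to module ids.

    Module identifiers are canonicalized to contiguous integers starting
    at 1, ordered by first appearance when nodes are scanned in sorted
    label order; grouping-level equality is therefore label-free.
    """

    def __init__(self, assignment: Mapping[str, int | str]) -> None:
        raw = {str(k): v for k, v in assignment.items()}
        relabel: dict = {}
        canon: dict[str, int] = {}
        # scan in sorted label order so numbering and storage order are
        # reproducible regardless of the caller's container (set hash
        # order varies across processes)
        for node in sorted(raw):
            mod = raw[node]
            if mod not in relabel:
                relabel[mod] = len(relabel) + 1
            canon[node] = relabel[mod]
        self._assignment = canon

    @property
    def assignment(self) -> dict[str, int]:
        return dict(self._assignment)

    @property
    def nodes(self) -> set[str]:
        return set(self._assignment)

    @property
    def n_modules(self) -> int:
        return max(self._assignment.values(), default=0)

    def __getitem__(self, node: str) -> int:
        return self._assignment[node]

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for v, k in self._assignment.items():
            out.setdefault(k, set()).add(v)
        return out

    def groups(self) -> list[frozenset[str]]:
        return [frozenset(g) for _, g in sorted(self.modules().items())]

    def same_grouping(self, other: "Partition") -> bool:
        return set(self.groups()) == set(other.groups())

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Partition":
        assignment = {}
        for i, g in enumerate(groups, start=1):
            for v in g:
                if v in assignment:
                    raise ValueError(f"node {v!r} appears in two groups")
                assignment[v] = i
        return cls(assignment)

    def validate_over(self, network: Network) -> None:
        """Raise unless this partition is total over ``network``."""
        missing = set(network.nodes) - self.nodes
        if missing:
            raise ValueError(f"partition missing nodes: {sorted(missing)[:5]}")
        extra = self.nodes - set(network.nodes)
        if extra:
            raise ValueError(f"partition has unknown nodes: {sorted(extra)[:5]}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and self._assignment == other._assignment

    def __len__(self) -> int:
        return len(self._assignment)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(n={len(self)}, modules={self.n_modules})"


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_edgelist(path: Path) -> Network:
    edges: list[tuple[str, str]] = []
    warned_weights = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected two labels, got {line!r}"
                )
            if len(tokens) > 2 and not warned_weights:
                warnings.warn(
                    f"{path}: extra columns (weights?) ignored from line {lineno}",
                    stacklevel=3,
                )
                warned_weights = True
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise NetworkFormatError(f"{path}: no edges found")
    return Network(edges=edges)


def _read_pajek(path: Path) -> Network:
    try:
        g = nx.read_pajek(path)
    except Exception as exc:  # networkx raises assorted types here
        raise NetworkFormatError(f"{path}: not a readable Pajek file: {exc}") from exc
    if g.number_of_nodes() == 0:
        raise NetworkFormatError(f"{path}: empty Pajek file")
    if g.is_directed():
        g = g.to_undirected()
    nodes = [str(v) for v in g.nodes]
    edges = [(str(u), str(v)) for u, v in g.edges()]
    if any(d.get("weight", 1) not in (1, 1.0) for *_, d in g.edges(data=True)):
        warnings.warn(f"{path}: edge weights ignored", stacklevel=3)
    net = Network(nodes, edges)
    n_iso = sum(1 for v in net.nodes if net.degree(v) == 0)
    if n_iso:
        logger.info("%s: %d isolated nodes retained", path, n_iso)
    return net


def read_network(
    path: str | Path, format: str = "edgelist", drop_isolated: bool = False
) -> Network:
    """Read a network from ``path`` in the given format.

    Parameters
    ----------
    format : {"edgelist", "pajek"}
        Edge list: two whitespace-separated labels per line, '#' comments.
        Pajek: ``*Vertices`` with optional quoted names, ``*Edges``/``*Arcs``
        sections; arcs are symmetrized.
    drop_isolated : bool
        Drop degree-0 nodes after reading (kept by default).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        net = _read_edgelist(path)
    elif format == "pajek":
        net = _read_pajek(path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return net.drop_isolated() if drop_isolated else net


def write_network(path: str | Path, network: Network, header: str | None = None) -> None:
    """Write ``network`` as an edge list (isolated nodes in a '#' comment)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        isolated = [v for v in network.nodes if network.degree(v) == 0]
        if isolated:
            fh.write("# isolated: " + " ".join(isolated) + "\n")
        for u, v in network.edges():
            fh.write(f"{u} {v}\n")


def read_partition(path: str | Path, network: Network | None = None) -> Partition:
    """Read a two-column TSV ``node<TAB>module`` partition (header optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    assignment: dict[str, str] = {}
    first_data_row = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected 'node<TAB>module'"
                )
            node, mod = parts[0].strip(), parts[1].strip()
            if first_data_row:
                first_data_row = False
                if (node.lower(), mod.lower()) == ("node", "module"):
                    continue  # header row
            if node in assignment:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: node {node!r} assigned twice"
                )
            assignment[node] = mod
    if not assignment:
        raise NetworkFormatError(f"{path}: empty partition file")
    part = Partition(assignment)
    if network is not None:
        part.validate_over(network)
    return part


def write_partition(
    path: str | Path, partition: Partition, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("node\tmodule\n")
        for node, mod in partition.assignment.items():
            fh.write(f"{node}\t{mod}\n")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_pcc_network(
    expression: pd.DataFrame, threshold: float = 0.6
) -> Network:
    """Gene co-expression network by Pearson-correlation thresholding.

    ``expression`` is genes x samples.  An edge (g, h) is placed iff the
    signed Pearson correlation of the two sample vectors is strictly
    greater than ``threshold``.  Zero-variance genes get no edges.
    """
    if not -1 < threshold < 1:
        raise ValueError("threshold must lie in (-1, 1)")
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    values = expression.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i, gene in enumerate(expression.index):
            for j, sample in enumerate(expression.columns):
                try:
                    float(expression.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value at gene {gene!r}, sample {sample!r}"
                    ) from None
        values = expression.astype(float).to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric value at gene {expression.index[i]!r}, "
            f"sample {expression.columns[j]!r}"
        )
    genes = [str(g) for g in expression.index]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            c = corr[i, j]
            if np.isfinite(c) and c > threshold:
                edges.append((genes[i], genes[j]))
    return Network(genes, edges)


def build_topk_network(
    rankings: Mapping[str, Sequence[str]], k: int
) -> Network:
    """Social network from rank-preference lists (top-``k`` nomination union).

    Each actor nominates the first ``k`` names on its preference list; an
    undirected edge (u, v) exists iff u nominated v or v nominated u.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    actors = [str(a) for a in rankings]
    edges: set[frozenset[str]] = set()
    for actor, prefs in rankings.items():
        actor = str(actor)
        prefs = [str(p) for p in prefs]
        if len(prefs) < k:
            raise ValueError(f"actor {actor!r} ranks only {len(prefs)} < k={k}")
        for choice in prefs[:k]:
            if choice == actor:
                raise ValueError(f"actor {actor!r} ranks itself")
            edges.add(frozenset((actor, choice)))
    return Network(actors, [tuple(sorted(e)) for e in edges])
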