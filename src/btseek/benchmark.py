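"""Planted-partition benchmark generator with exact block counts.

The default specification is a 72-node, 448-edge network with three
planted modules of 16, 32 and 24 nodes and per-node degrees fixed to
16, 8 and 16.  Modules 1 and 2 are internally empty (every one of their
edges crosses to another module): each module-1 node sends 12 of its 16
edges to module 2 and 4 to module 3, each module-2 node sends 6 edges
to module 1 and 2 to module 3, and module 3 absorbs the remaining stubs
internally (128 internal edges).  Modules 1 and 2 are therefore planted
sparse modules and module 3 a (moderately) cohesive one.  All block
edge counts and all node degrees are exact for every seed; only the
placement of edges within blocks is randomized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import Network, Partition

__all__ = ["BenchmarkSpec", "BenchmarkError", "default_spec", "generate_planted"]


class BenchmarkError(RuntimeError):
    """Raised when a specification cannot be realized as a simple graph."""


@dataclass(frozen=True)
class BenchmarkSpec:
    """Block-level design of a planted-partition network.

    ``inter_edges[r][s]`` is the exact number of edges between modules r
    and s (symmetric, zero diagonal); ``intra_edges[k]`` the exact number
    inside module k.  When ``degree_targets`` is set, every node of
    module k ends with total degree exactly ``degree_targets[k]``, which
    requires the stub-accounting identity
    ``2 intra[k] + sum_s inter[k][s] == sizes[k] * degree_targets[k]``.
    """

    sizes: tuple[int, ...]
    inter_edges: tuple[tuple[int, ...], ...]
    intra_edges: tuple[int, ...]
    degree_targets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        k = len(self.sizes)
        if len(self.intra_edges) != k or len(self.inter_edges) != k:
            raise ValueError("sizes, intra_edges, inter_edges length mismatch")
        for r in range(k):
            if len(self.inter_edges[r]) != k:
                raise ValueError("inter_edges must be a square matrix")
            if self.inter_edges[r][r] != 0:
                raise ValueError("inter_edges diagonal must be zero")
            n_r = self.sizes[r]
            if self.intra_edges[r] > n_r * (n_r - 1) // 2:
                raise ValueError(f"intra_edges[{r}] exceeds block capacity")
            for s in range(k):
                if self.inter_edges[r][s] != self.inter_edges[s][r]:
                    raise ValueError("inter_edges must be symmetric")
                if r != s and self.inter_edges[r][s] > n_r * self.sizes[s]:
                    raise ValueError(f"inter_edges[{r}][{s}] exceeds block capacity")
        if self.degree_targets is not None:
            if len(self.degree_targets) != k:
                raise ValueError("degree_targets length mismatch")
            for r in range(k):
                stubs = 2 * self.intra_edges[r] + sum(self.inter_edges[r])
                if stubs != self.sizes[r] * self.degree_targets[r]:
                    raise ValueError(
                        f"module {r}: stub count {stubs} != "
                        f"{self.sizes[r]} * {self.degree_targets[r]}"
                    )

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    @property
    def n_nodes(self) -> int:
        return sum(self.sizes)

    @property
    def n_edges(self) -> int:
        k = self.n_modules
        inter = sum(self.inter_edges[r][s] for r in range(k) for s in range(r + 1, k))
        return inter + sum(self.intra_edges)


def default_spec() -> BenchmarkSpec:
    """The standard three-module design (72 nodes, 448 edges)."""
    return BenchmarkSpec(
        sizes=(16, 32, 24),
        inter_edges=((0, 192, 64), (192, 0, 64), (64, 64, 0)),
        intra_edges=(0, 0, 128),
        degree_targets=(16, 8, 16),
    )


# ---------------------------------------------------------------------------
# degree-sequence realization helpers
# ---------------------------------------------------------------------------

def _block_degree_sequence(
    n_nodes: int, n_stubs: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-node stub quotas for one side of a block: the integer part goes
    to everyone, the remainder +1s land on uniformly chosen nodes."""
    base, rem = divmod(n_stubs, n_nodes)
    seq = np.full(n_nodes, base, dtype=int)
    if rem:
        seq[rng.choice(n_nodes, size=rem, replace=False)] += 1
    return seq


def _realize_bipartite(
    left_deg: np.ndarray, right_deg: np.ndarray
) -> set[tuple[int, int]]:
    """Gale-Ryser-style greedy bipartite realization of two degree sequences."""
    if left_deg.sum() != right_deg.sum():
        raise BenchmarkError("bipartite stub counts do not balance")
    residual = right_deg.astype(int).copy()
    edges: set[tuple[int, int]] = set()
    order = np.argsort(-left_deg, kind="stable")
    for i in order:
        d = int(left_deg[i])
        if d == 0:
            continue
        targets = np.argsort(-residual, kind="stable")[:d]
        if residual[targets[-1]] <= 0:
            raise BenchmarkError("bipartite degree sequence not realizable")
        for j in targets:
            edges.add((int(i), int(j)))
            residual[j] -= 1
    return edges


def _realize_simple(deg: np.ndarray) -> set[tuple[int, int]]:
    """Havel-Hakimi realization of a graphical degree sequence on 0..n-1."""
    residual = [(int(d), i) for i, d in enumerate(deg)]
    edges: set[tuple[int, int]] = set()
    while True:
        residual.sort(key=lambda t: (-t[0], t[1]))
        d, v = residual[0]
        if d == 0:
            return edges
        if d > len(residual) - 1:
            raise BenchmarkError("degree sequence not graphical")
        residual[0] = (0, v)
        for idx in range(1, d + 1):
            du, u = residual[idx]
            if du <= 0:
                raise BenchmarkError("degree sequence not graphical")
            residual[idx] = (du - 1, u)
            edges.add((min(u, v), max(u, v)))


def _swap_bipartite(
    edges: set[tuple[int, int]], rng: np.random.Generator, n_attempts: int
) -> None:
    """Degree-preserving double-edge swaps within a bipartite block."""
    for _ in range(n_attempts):
        elist = sorted(edges)
        if len(elist) < 2:
            return
        i1, i2 = rng.integers(0, len(elist), size=2)
        (a, b), (c, d) = elist[i1], elist[i2]
        if a == c or b == d:
            continue
        if (a, d) in edges or (c, b) in edges:
            continue
        edges -= {(a, b), (c, d)}
        edges |= {(a, d), (c, b)}


def _swap_simple(
    edges: set[tuple[int, int]], rng: np.random.Generator, n_attempts: int
) -> None:
    """Degree-preserving double-edge swaps keeping the graph simple."""
    for _ in range(n_attempts):
        elist = sorted(edges)
        if len(elist) < 2:
            return
        i1, i2 = rng.integers(0, len(elist), size=2)
        old1, old2 = elist[i1], elist[i2]
        a, b = old1
        c, d = old2
        if rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if e1 in edges or e2 in edges:
            continue
        edges -= {old1, old2}
        edges |= {e1, e2}


def generate_planted(
    spec: BenchmarkSpec, seed: int | None = None
) -> tuple[Network, Partition]:
    """Realize ``spec`` as a simple network plus its ground-truth partition.

    Block edge counts are exact for every seed; with degree targets set,
    every node's total degree is exact as well.  Within each block the
    edge placement is randomized by seeded degree-preserving swaps, so
    different seeds differ in wiring but never in count-level observables.
    """
    rng = np.random.default_rng(seed)
    k = spec.n_modules
    offsets = np.concatenate(([0], np.cumsum(spec.sizes)))
    width = len(str(spec.n_nodes - 1))
    labels = [f"n{idx:0{width}d}" for idx in range(spec.n_nodes)]
    truth = Partition(
        {
            labels[offsets[r] + i]: r + 1
            for r in range(k)
            for i in range(spec.sizes[r])
        }
    )
    all_edges: list[tuple[str, str]] = []
    inter_degree = [np.zeros(spec.sizes[r], dtype=int) for r in range(k)]
    # off-diagonal blocks
    for r in range(k):
        for s in range(r + 1, k):
            l_rs = spec.inter_edges[r][s]
            if l_rs == 0:
                continue
            ldeg = _block_degree_sequence(spec.sizes[r], l_rs, rng)
            rdeg = _block_degree_sequence(spec.sizes[s], l_rs, rng)
            block = _realize_bipartite(ldeg, rdeg)
            _swap_bipartite(block, rng, 4 * l_rs)
            inter_degree[r] += ldeg
            inter_degree[s] += rdeg
            all_edges.extend(
                (labels[offsets[r] + i], labels[offsets[s] + j]) for i, j in block
            )
    # diagonal blocks
    for r in range(k):
        l_r = spec.intra_edges[r]
        if l_r == 0:
            continue
        if spec.degree_targets is not None:
            deg = spec.degree_targets[r] - inter_degree[r]
            if deg.min() < 0 or deg.sum() != 2 * l_r:
                raise BenchmarkError(f"module {r}: internal stubs infeasible")
        else:
            deg = _block_degree_sequence(spec.sizes[r], 2 * l_r, rng)
        block = _realize_simple(deg)
        _swap_simple(block, rng, 4 * l_r)
        all_edges.extend(
            (labels[offsets[r] + i], labels[offsets[r] + j]) for i, j in block
        )
    net = Network(labels, all_edges)
    if net.m != spec.n_edges:
        raise BenchmarkError("edge placement collided; spec not realized")
    return net, truth
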