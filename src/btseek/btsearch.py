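"""BinTree Seeking: recursive bisection search for cohesive and sparse modules.

The search grows a binary tree of group splits.  Each split is a
swap-based local search over the group's adjacency sub-matrix (the
Kernighan-Lin move set: single-node moves and pairwise swaps, the
matrix-level "primary transpositions"), run in two modes — a cohesive
mode that minimizes the cut and a sparse mode that maximizes it — so
that both diagonal-dense and off-diagonal-dense block structure can
emerge; the mode whose converged split has the lower local block-image
error wins.  Every division state reached while the tree grows is
recorded as a candidate partition, and the candidate with the lowest
global error E is selected, so the number of modules is an output of
the search, never an input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import (
    CLASSICAL,
    LabeledPartition,
    ThresholdTriple,
    classify_modules,
    module_stats,
)
from .netio import Network, Partition
from .scoring import error_E, error_E_from_stats

__all__ = ["SearchConfig", "BinTree", "split_group", "grow_tree", "bts_detect",
           "a3_profile", "greedy_merge"]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the tree search.

    thresholds may be a single triple or a list; with a list (or with an
    ``sweep_a3`` range) one tree is grown per triple and the E-minimal
    candidate over all trees is selected.
    """

    thresholds: ThresholdTriple | Sequence[ThresholdTriple] = CLASSICAL
    min_split_size: int = 4
    max_depth: int | None = None  # default: ceil(log2 n) + 5
    n_restarts: int = 8
    seed: int | None = None
    sweep_a3: tuple[float, float, float] | None = None  # (start, stop, step)
    record_intermediate: bool = True
    merge_pass: bool = False

    def __post_init__(self) -> None:
        if self.min_split_size < 2:
            raise ValueError("min_split_size must be >= 2")
        if self.sweep_a3 is not None and self.sweep_a3[2] <= 0:
            raise ValueError("sweep step must be positive")

    def triples(self) -> list[ThresholdTriple]:
        if self.sweep_a3 is not None:
            base = (
                self.thresholds
                if isinstance(self.thresholds, ThresholdTriple)
                else self.thresholds[0]
            )
            start, stop, step = self.sweep_a3
            n_steps = int(round((stop - start) / step))
            return [
                replace(base, a3=round(start + i * step, 10))
                for i in range(n_steps + 1)
            ]
        if isinstance(self.thresholds, ThresholdTriple):
            return [self.thresholds]
        return list(self.thresholds)


@dataclass
class TreeNode:
    members: frozenset[str]
    depth: int
    children: tuple["TreeNode", "TreeNode"] | None = None


@dataclass
class BinTree:
    """The grown split tree plus every recorded division state."""

    root: TreeNode
    leaf_states: list[Partition] = field(default_factory=list)

    def n_nodes(self) -> int:
        def count(node: TreeNode) -> int:
            if node.children is None:
                return 1
            return 1 + count(node.children[0]) + count(node.children[1])

        return count(self.root)


# ---------------------------------------------------------------------------
# the split operator
# ---------------------------------------------------------------------------

def _hill_climb(adj: np.ndarray, side: np.ndarray, maximize: bool) -> np.ndarray:
    """Local search on the cut objective with single flips and pair swaps.

    ``side`` is a 0/1 vector; flips that would empty a side are barred.
    The cut strictly improves at every accepted move, so this terminates.
    """
    sign = 1.0 if maximize else -1.0
    n = len(side)
    while True:
        deg = adj.sum(axis=1)
        to_one = adj @ side  # neighbours currently on side 1
        same = np.where(side == 1, to_one, deg - to_one)
        other = deg - same
        delta = same - other  # cut change if the node flips alone
        gain = sign * delta
        n1 = int(side.sum())
        feasible = np.ones(n, dtype=bool)
        if n1 == 1:
            feasible &= side == 0
        if n1 == n - 1:
            feasible &= side == 1
        best_move: tuple[float, int, int] | None = None  # (gain, i, j or -1)
        if feasible.any():
            i = int(np.flatnonzero(feasible)[np.argmax(gain[feasible])])
            if gain[i] > 1e-9:
                best_move = (float(gain[i]), i, -1)
        # pair swaps across the sides; correction +2 A_ij because the
        # mutual edge stays in the cut when both endpoints flip
        zeros = np.flatnonzero(side == 0)
        ones = np.flatnonzero(side == 1)
        if len(zeros) and len(ones):
            pair_delta = delta[zeros, None] + delta[None, ones] + 2 * adj[np.ix_(zeros, ones)]
            pair_gain = sign * pair_delta
            a, b = np.unravel_index(np.argmax(pair_gain), pair_gain.shape)
            g = float(pair_gain[a, b])
            if g > 1e-9 and (best_move is None or g > best_move[0]):
                best_move = (g, int(zeros[a]), int(ones[b]))
        if best_move is None:
            return side
        _, i, j = best_move
        side = side.copy()
        side[i] = 1 - side[i]
        if j >= 0:
            side[j] = 1 - side[j]


def _block_cost(l00, l11, l01, n0, n1, rho):
    """Vectorized block-image cost of a bisection's three blocks."""
    c = np.minimum((1.0 - rho) * l00, rho * (n0 * (n0 - 1) / 2.0 - l00))
    c = c + np.minimum((1.0 - rho) * l11, rho * (n1 * (n1 - 1) / 2.0 - l11))
    c = c + np.minimum((1.0 - rho) * l01, rho * (n0 * n1 - l01))
    return c


def _climb_local_error(adj: np.ndarray, side: np.ndarray, rho: float) -> np.ndarray:
    """Refine a bisection by hill-climbing the local block-image error.

    Same move set as the cut climbs (single flips, cross-side swaps); the
    objective is the quantity the mode comparison selects by, so the cut
    optima only serve as starting points.  Strict improvement per step
    guarantees termination.
    """
    n = len(side)
    side = side.copy()
    while True:
        s1 = adj @ side
        deg = adj.sum(axis=1)
        s0 = deg - s1
        ones = side == 1
        n1 = int(ones.sum())
        n0 = n - n1
        l11 = float(side @ s1) / 2.0
        l01 = float((1.0 - side) @ s1)
        l00 = float((1.0 - side) @ s0) / 2.0
        cur = float(_block_cost(l00, l11, l01, n0, n1, rho))
        # single flips (vectorized over the flipping node)
        f_l00 = np.where(ones, l00 + s0, l00 - s0)
        f_l11 = np.where(ones, l11 - s1, l11 + s1)
        f_l01 = np.where(ones, l01 + s1 - s0, l01 + s0 - s1)
        f_n0 = np.where(ones, n0 + 1, n0 - 1)
        f_n1 = np.where(ones, n1 - 1, n1 + 1)
        fc = _block_cost(f_l00, f_l11, f_l01, f_n0, f_n1, rho)
        feasible = np.ones(n, dtype=bool)
        if n1 == 1:
            feasible &= ~ones
        if n0 == 1:
            feasible &= ones
        best: tuple[float, int, int] | None = None
        if feasible.any():
            i = int(np.flatnonzero(feasible)[np.argmin(fc[feasible])])
            if fc[i] < cur - 1e-9:
                best = (float(fc[i]), i, -1)
        # cross-side swaps; the +/- adj terms correct for the mutual edge
        zeros_idx = np.flatnonzero(~ones)
        ones_idx = np.flatnonzero(ones)
        if len(zeros_idx) and len(ones_idx):
            a_blk = adj[np.ix_(zeros_idx, ones_idx)]
            sw_l00 = l00 - s0[zeros_idx][:, None] + (s0[ones_idx][None, :] - a_blk)
            sw_l11 = l11 + s1[zeros_idx][:, None] - (s1[ones_idx][None, :] + a_blk)
            sw_l01 = (
                l01
                + (s0[zeros_idx] - s1[zeros_idx])[:, None]
                + (s1[ones_idx] - s0[ones_idx])[None, :]
                + 2.0 * a_blk
            )
            sc = _block_cost(sw_l00, sw_l11, sw_l01, n0, n1, rho)
            a, b = np.unravel_index(np.argmin(sc), sc.shape)
            g = float(sc[a, b])
            if g < cur - 1e-9 and (best is None or g < best[0]):
                best = (g, int(zeros_idx[a]), int(ones_idx[b]))
        if best is None:
            return side
        _, i, j = best
        side[i] = 1.0 - side[i]
        if j >= 0:
            side[j] = 1.0 - side[j]


def _local_error(adj: np.ndarray, side: np.ndarray, rho: float) -> float:
    """Block-image error of the three blocks a bisection induces."""
    n = len(side)
    ones = side == 1
    n1, n0 = int(ones.sum()), n - int(ones.sum())
    l11 = int(adj[np.ix_(ones, ones)].sum()) // 2
    l00 = int(adj[np.ix_(~ones, ~ones)].sum()) // 2
    l01 = int(adj[np.ix_(~ones, ones)].sum())
    total = 0.0
    for l, cap in (
        (l11, n1 * (n1 - 1) // 2),
        (l00, n0 * (n0 - 1) // 2),
        (l01, n0 * n1),
    ):
        total += min((1.0 - rho) * l, rho * (cap - l))
    return total


def split_group(
    network: Network,
    group: frozenset[str] | set[str],
    seed_seq: np.random.SeedSequence | int | None = None,
    *,
    n_restarts: int = 8,
    min_split_size: int = 4,
    rho: float | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Bisect ``group`` by dual-objective local search.

    For each seeded random balanced start, a cut-minimizing (cohesive)
    and a cut-maximizing (sparse) hill climb both run; over all restarts
    and both modes the converged bisection with the lowest local
    block-image error is returned, normalized so the half holding the
    smallest node label comes first.  Deterministic given the seed.
    """
    members = sorted(group)
    if len(members) < min_split_size:
        raise ValueError(
            f"group of {len(members)} nodes is below min_split_size={min_split_size}"
        )
    if rho is None:
        n = network.n
        rho = 2.0 * network.m / (n * (n - 1)) if n >= 2 else 0.0
    adj = network.adjacency_matrix(members).astype(np.float64)
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    restart_seeds = seed_seq.spawn(n_restarts)
    k = len(members)
    best: tuple[float, tuple[str, ...], frozenset[str], frozenset[str]] | None = None
    for rs in restart_seeds:
        rng = np.random.default_rng(rs)
        side0 = np.zeros(k, dtype=np.float64)
        side0[rng.permutation(k)[: k // 2]] = 1.0
        for maximize in (False, True):
            side = _hill_climb(adj, side0, maximize)
            side = _climb_local_error(adj, side, rho)
            e_loc = _local_error(adj, side, rho)
            half1 = frozenset(m for m, s in zip(members, side) if s == 1)
            half0 = frozenset(group) - half1
            # normalize: the half containing the smallest label is first
            if min(half1) < min(half0):
                half0, half1 = half1, half0
            key = tuple(sorted(half0))
            if best is None or e_loc < best[0] - 1e-12 or (
                abs(e_loc - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (e_loc, key, half0, half1)
    assert best is not None
    return best[2], best[3]


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------

def grow_tree(network: Network, config: SearchConfig,
              thresholds: ThresholdTriple | None = None,
              seed_seq: np.random.SeedSequence | None = None) -> BinTree:
    """Grow the binary split tree for one threshold triple.

    The root group (all nodes) is split unconditionally when it is large
    enough; after that, only leaves classified ambiguous under the triple
    are split, and cohesive or sparse leaves are frozen.  Every state of
    the leaf set reached along the way is recorded as a candidate
    partition.  Terminates: the depth cap bounds growth.
    """
    if network.n == 0:
        raise ValueError("empty network")
    triple = thresholds if thresholds is not None else config.triples()[0]
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    max_depth = (
        config.max_depth
        if config.max_depth is not None
        else math.ceil(math.log2(max(network.n, 2))) + 5
    )
    root = TreeNode(members=frozenset(network.nodes), depth=0)
    leaves: list[TreeNode] = [root]
    tree = BinTree(root=root)

    def record() -> None:
        tree.leaf_states.append(
            Partition.from_groups([leaf.members for leaf in leaves])
        )

    record()
    first = True
    while True:
        part = Partition.from_groups([leaf.members for leaf in leaves])
        stats = module_stats(network, part)
        labeled = classify_modules(stats, triple)
        module_of = {leaf.members: part[next(iter(leaf.members))] for leaf in leaves}
        candidates = []
        for idx, leaf in enumerate(leaves):
            if len(leaf.members) < config.min_split_size or leaf.depth >= max_depth:
                continue
            lab = labeled.label[module_of[leaf.members]]
            if lab == "ambiguous" or (first and leaf is root):
                candidates.append(idx)
        if not candidates:
            break
        idx = candidates[0]
        leaf = leaves[idx]
        rho = (
            2.0 * network.m / (network.n * (network.n - 1))
            if network.n >= 2
            else 0.0
        )
        half0, half1 = split_group(
            network,
            leaf.members,
            seed_seq.spawn(1)[0],
            n_restarts=config.n_restarts,
            min_split_size=config.min_split_size,
            rho=rho,
        )
        child0 = TreeNode(members=half0, depth=leaf.depth + 1)
        child1 = TreeNode(members=half1, depth=leaf.depth + 1)
        leaf.children = (child0, child1)
        leaves[idx: idx + 1] = [child0, child1]
        first = False
        if config.record_intermediate:
            record()
    if not config.record_intermediate and len(tree.leaf_states) == 1 and len(leaves) > 1:
        record()
    return tree


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def greedy_merge(network: Network, partition: Partition) -> Partition:
    """Greedily merge the module pair that most decreases E, while E drops."""
    current = partition
    e_cur = error_E(network, current)
    while current.n_modules > 1:
        groups = current.groups()
        best: tuple[float, int, int] | None = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                merged = [g for k, g in enumerate(groups) if k not in (i, j)]
                merged.append(groups[i] | groups[j])
                e_new = error_E(network, Partition.from_groups(merged))
                if e_new < e_cur - 1e-12 and (best is None or e_new < best[0]):
                    best = (e_new, i, j)
        if best is None:
            break
        e_cur, i, j = best
        groups_new = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups_new.append(groups[i] | groups[j])
        current = Partition.from_groups(groups_new)
    return current


def bts_detect(network: Network, config: SearchConfig | None = None) -> LabeledPartition:
    """Run the full search and return the E-minimal labeled division.

    For every threshold triple (and every a3 of a sweep, if configured) a
    tree is grown and all its recorded candidate states are scored with
    the global error E; the overall minimum wins.  The selected partition
    is classified under its own triple; the error and the triple are
    recorded on the result.  The module count is an output of the E
    minimization.
    """
    if network.n == 0:
        raise ValueError("empty network")
    config = config or SearchConfig()
    master = np.random.SeedSequence(config.seed)
    best: tuple[float, Partition, ThresholdTriple] | None = None
    for triple, child in zip(config.triples(), master.spawn(len(config.triples()))):
        tree = grow_tree(network, config, thresholds=triple, seed_seq=child)
        for state in tree.leaf_states:
            e = error_E(network, state)
            if best is None or e < best[0] - 1e-12:
                best = (e, state, triple)
    assert best is not None
    e_best, part, triple = best
    if config.merge_pass:
        part = greedy_merge(network, part)
        e_best = error_E(network, part)
    stats = module_stats(network, part)
    labeled = classify_modules(stats, triple)
    labeled.error = e_best
    return labeled


def a3_profile(network: Network, config: SearchConfig) -> pd.DataFrame:
    """Selected E as a function of a3 over the configured sweep.

    Intended for bipartite-style networks, where a1 and a2 stay fixed at
    their classical values and only the bridge threshold is varied; the
    returned frame (columns a3, error, n_modules) is the E-vs-a3 curve.
    """
    if config.sweep_a3 is None:
        raise ValueError("config.sweep_a3 is not set")
    rows = []
    master = np.random.SeedSequence(config.seed)
    for triple, child in zip(config.triples(), master.spawn(len(config.triples()))):
        sub = replace(config, thresholds=triple, sweep_a3=None)
        tree = grow_tree(network, sub, thresholds=triple, seed_seq=child)
        scored = [(error_E(network, s), s) for s in tree.leaf_states]
        e, state = min(scored, key=lambda t: t[0])
        rows.append({"a3": triple.a3, "error": e, "n_modules": state.n_modules})
    return pd.DataFrame(rows)
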