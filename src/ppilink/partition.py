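"""Train/test edge partitioning: random, BFS and DFS schemes, plus test stratification.

The traversal schemes emulate inductive link-prediction splits: a random
root protein is chosen and the protein graph is traversed breadth-first
(resp. depth-first); every edge with at least one endpoint in the visited
node set goes to the test partition, and traversal stops as soon as the
test set reaches the target fraction of all edges (it may overshoot by the
incident edges of the last visited node). If a connected component is
exhausted first, traversal restarts from a new random unvisited root.

A test edge is "homologous" when both of its endpoints occur in at least
one training edge, and "unknown" otherwise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import EdgeRecord


@dataclass
class SplitResult:
    scheme: str
    seed: int
    train_edges: list
    test_edges: list
    test_homologous: list = field(default_factory=list)
    test_unknown: list = field(default_factory=list)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SplitResult):
            return NotImplemented
        return (
            self.scheme == other.scheme
            and self.seed == other.seed
            and set(self.train_edges) == set(other.train_edges)
            and set(self.test_edges) == set(other.test_edges)
        )


def stratify_test(train_edges: list, test_edges: list) -> tuple[list, list]:
    """Partition test edges into (homologous, unknown) by train-node membership."""
    train_nodes = {p for e in train_edges for p in (e.protein_a, e.protein_b)}
    homologous = [
        e for e in test_edges if e.protein_a in train_nodes and e.protein_b in train_nodes
    ]
    unknown = [
        e
        for e in test_edges
        if not (e.protein_a in train_nodes and e.protein_b in train_nodes)
    ]
    return homologous, unknown


def random_split(edges: list, ratio: float = 0.2, seed: int = 0) -> SplitResult:
    """Uniformly sample round(ratio * |edges|) test edges."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"test ratio must be in (0, 1), got {ratio}")
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to split")
    rng = np.random.default_rng(seed)
    n_test = int(np.rint(ratio * len(edges)))
    test_idx = set(rng.choice(len(edges), size=n_test, replace=False).tolist())
    train = [e for i, e in enumerate(edges) if i not in test_idx]
    test = [e for i, e in enumerate(edges) if i in test_idx]
    homologous, unknown = stratify_test(train, test)
    return SplitResult("random", seed, train, test, homologous, unknown)


def traversal_split(
    edges: list,
    scheme: str,
    ratio: float = 0.2,
    seed: int = 0,
    root: str | None = None,
) -> SplitResult:
    """BFS or DFS split: test edges accumulate around traversal-visited proteins.

    ``root`` overrides the seeded random choice of the first traversal root
    (useful for reproducing hand-worked examples).
    """
    if scheme not in ("bfs", "dfs"):
        raise ValueError(f"scheme must be 'bfs' or 'dfs', got {scheme!r}")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"test ratio must be in (0, 1), got {ratio}")
    if not edges:
        raise ValueError("need at least one edge to split")

    G = nx.Graph()
    incident: dict[str, list[int]] = {}
    for i, e in enumerate(edges):
        G.add_edge(e.protein_a, e.protein_b)
        incident.setdefault(e.protein_a, []).append(i)
        incident.setdefault(e.protein_b, []).append(i)

    rng = np.random.default_rng(seed)
    target = ratio * len(edges)
    nodes = sorted(G.nodes)
    visited: set[str] = set()
    test_idx: set[int] = set()

    def visit(node: str) -> None:
        visited.add(node)
        test_idx.update(incident[node])

    while len(test_idx) < target:
        if root is not None and not visited:
            start = root
        else:
            candidates = [p for p in nodes if p not in visited]
            if not candidates:
                raise ValueError(
                    f"cannot reach test ratio {ratio}: traversal exhausted the graph"
                )
            start = candidates[rng.integers(len(candidates))]
        frontier = deque([start])
        while frontier and len(test_idx) < target:
            node = frontier.popleft() if scheme == "bfs" else frontier.pop()
            if node in visited:
                continue
            visit(node)
            neighbors = sorted(n for n in G.neighbors(node) if n not in visited)
            if scheme == "dfs":
                neighbors = reversed(neighbors)
            frontier.extend(neighbors)

    train = [e for i, e in enumerate(edges) if i not in test_idx]
    test = [e for i, e in enumerate(edges) if i in test_idx]
    homologous, unknown = stratify_test(train, test)
    return SplitResult(scheme, seed, train, test, homologous, unknown)


def make_split(
    edges: list, scheme: str, ratio: float = 0.2, seed: int = 0
) -> SplitResult:
    """Dispatch on scheme name ('random', 'bfs' or 'dfs')."""
    if scheme == "random":
        return random_split(edges, ratio=ratio, seed=seed)
    return traversal_split(edges, scheme, ratio=ratio, seed=seed)
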