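"""Lightweight rooted-tree container for local genealogies.

Genealogies are stored as flat parent/time arrays rather than node objects:
the sequence-evolution stage traverses tens of thousands of local trees per
chromosome and object graphs are too slow for that.  Node ids 0..n_leaves-1
are the sampled haplotypes (in sample order); internal nodes follow.  Times
are in generations before present; a branch's length is
``time[parent] - time[child]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tree", "GenealogySegment"]


@dataclass
class Tree:
    parent: np.ndarray  # int64, -1 at the root
    time: np.ndarray  # float64, generations before present
    n_leaves: int
    leaf_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.parent.shape != self.time.shape:
            raise ValueError("parent and time arrays must have equal length")
        lengths = self.branch_lengths()
        if np.any(lengths < 0):
            raise ValueError("negative branch length in tree")

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError(f"tree has {roots.size} roots, expected 1")
        return int(roots[0])

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length in generations (0 at the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                kids[par].append(node)
        return kids

    def preorder(self) -> list[int]:
        """Node ids with every parent before its children."""
        kids = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(kids[node])
        return order

    def height(self) -> float:
        return float(self.time[self.root])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self, i: int, j: int) -> float:
        """Time of the most recent common ancestor of leaves i and j."""
        anc_i = set()
        node = i
        while node != -1:
            anc_i.add(node)
            node = int(self.parent[node])
        node = j
        while node not in anc_i:
            node = int(self.parent[node])
        return float(self.time[node])

    def to_newick(self, precision: int = 6) -> str:
        kids = self.children()
        labels = self.leaf_labels or [f"n{i}" for i in range(self.n_leaves)]
        lengths = self.branch_lengths()

        def rec(node: int) -> str:
            if not kids[node]:
                name = labels[node]
            else:
                name = "(" + ",".join(rec(c) for c in kids[node]) + ")"
            if self.parent[node] == -1:
                return name
            return f"{name}:{lengths[node]:.{precision}f}"

        return rec(self.root) + ";"


@dataclass
class GenealogySegment:
    """A local genealogy valid over a half-open base-pair interval."""

    interval_bp: tuple[int, int]
    tree: Tree

    def __post_init__(self) -> None:
        start, end = self.interval_bp
        if not 0 <= start < end:
            raise ValueError(f"bad interval {self.interval_bp}")

    @property
    def length_bp(self) -> int:
        return self.interval_bp[1] - self.interval_bp[0]

    @property
    def pop_labels(self) -> list[str]:
        """Population of each leaf, parsed from 'species|index' labels."""
        return [lab.split("|")[0] for lab in self.tree.leaf_labels]


def check_partition(segments: list[GenealogySegment], seq_length_bp: int) -> None:
    """Raise unless the segments tile [0, seq_length_bp) without overlap."""
    if not segments:
        raise ValueError("no segments")
    expected = 0
    for seg in segments:
        start, end = seg.interval_bp
        if start != expected:
            raise ValueError(f"gap or overlap at {start} (expected {expected})")
        expected = end
    if expected != seq_length_bp:
        raise ValueError(f"segments end at {expected}, not {seq_length_bp}")
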