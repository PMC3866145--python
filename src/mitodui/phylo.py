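"""Distance-matrix neighbor joining, monophyly checks, newick I/O.

This is deliberately lightweight machinery: it exists to exercise
topology-level properties — above all the reciprocal monophyly of the
female- and male-transmitted genome clades expected under doubly
uniparental inheritance — on p-distance matrices, not to replace
likelihood or Bayesian inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "Tree", "Node", "nj_tree", "is_monophyletic",
           "read_newick", "write_newick"]

log = logging.getLogger(__name__)


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored from an arbitrary root node."""

    root: Node

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets cut off by each edge (the smaller/lexical side kept
        canonical by storing the child-side set)."""
        parts: set[frozenset[str]] = set()

        def walk(node: Node) -> list[str]:
            if node.is_leaf():
                parts.add(frozenset([node.name]))
                return [node.name]
            below = []
            for child, _ in node.children:
                below.extend(walk(child))
            parts.add(frozenset(below))
            return below

        walk(self.root)
        return parts


class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labelled taxa."""

    def __init__(self, labels: list[str], matrix):
        self.labels = list(labels)
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        self.matrix = m

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.matrix[i, j]


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The minimal-Q pair with the lowest (i, j) index order is joined at each
    step; negative branch lengths are clamped to zero (logged).
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes = [Node(name=l) for l in d.labels]
    D = d.matrix.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li), _clamp(lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances to the new node (standard NJ reduction)
        D = np.pad(D, ((0, 1), (0, 1)))
        k_new = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]
    i, j, k = active
    li = _clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = _clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = _clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root = Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return Tree(root)


def _clamp(x: float) -> float:
    if x < 0:
        if x < -1e-9:
            log.info("negative NJ branch length %.4g clamped to 0", x)
        return 0.0
    return float(x)


def is_monophyletic(tree: Tree, taxa_subset) -> bool:
    """True iff some edge bipartitions the leaves into subset vs complement.

    On an unrooted tree this is symmetric in the subset and its complement.
    """
    subset = frozenset(taxa_subset)
    leaves = tree.leaf_names
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if not subset or subset == leaves:
        raise ValueError("subset must be a non-empty proper subset of leaves")
    parts = tree.bipartitions()
    return subset in parts or (leaves - subset) in parts


# ---------------------------------------------------------------------------
# newick

def write_newick(tree: Tree) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf():
            return _quote(node.name)
        inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
        return f"({inner})"
    return fmt(tree.root) + ";"


def _quote(name: str) -> str:
    if any(ch in name for ch in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_newick(text: str) -> Tree:
    """Minimal newick parser (names, branch lengths, nesting)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            while True:
                child = parse_node()
                length = 0.0
                if pos < len(s) and s[pos] == ":":
                    pos += 1
                    start = pos
                    while pos < len(s) and s[pos] not in ",()":
                        pos += 1
                    length = float(s[start:pos])
                node.children.append((child, length))
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                if pos < len(s) and s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"malformed newick near position {pos}")
        start = pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            name_chars = []
            while pos < len(s):
                if s[pos] == "'" and pos + 1 < len(s) and s[pos + 1] == "'":
                    name_chars.append("'")
                    pos += 2
                elif s[pos] == "'":
                    pos += 1
                    break
                else:
                    name_chars.append(s[pos])
                    pos += 1
            node.name = "".join(name_chars)
        else:
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            if pos > start:
                node.name = s[start:pos]
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick")
    return Tree(root)
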