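"""Phylogenetic trees: neighbor joining, Newick I/O, splits and congruence.

The tree structure here is deliberately small — labeled nodes with parent
links and branch lengths — because the pipeline needs exactly three things
from it: NJ construction from a distance matrix, bipartition-based
comparison between a network tree and the species tree, and root-to-tip
path lengths for the branch-length correlation. Newick parsing is delegated
to dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .network_distance import DistanceMatrix

__all__ = [
    "TreeNode",
    "PhyloTree",
    "SplitComparison",
    "neighbor_join",
    "read_newick",
    "write_newick",
    "parse_newick",
    "splits",
    "shared_split_fraction",
    "robinson_foulds",
    "root_to_tip_lengths",
    "resolve_polytomies",
]


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


@dataclass
class PhyloTree:
    root: TreeNode
    rooted: bool = True

    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def is_binary(self) -> bool:
        for node in self.postorder():
            if node.is_tip:
                continue
            limit = 2 if (self.rooted or node is not self.root) else 3
            if len(node.children) != limit:
                return False
        return True

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_tip:
                return f"{node.label}:{node.length:.10g}"
            inner = ",".join(render(c) for c in node.children)
            if node is self.root:
                return f"({inner})"
            return f"({inner}):{node.length:.10g}"

        return render(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(label=node.label, length=node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return PhyloTree(root=clone(self.root), rooted=self.rooted)


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    warned = False

    def convert(dnode) -> TreeNode:
        nonlocal warned
        label = dnode.taxon.label if dnode.taxon else dnode.label
        length = dnode.edge.length
        if length is None:
            length = 0.0
            if dnode.parent_node is not None and not warned:
                warnings.warn("missing branch lengths default to 0", stacklevel=4)
                warned = True
        node = TreeNode(label=label, length=float(length))
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    # trifurcating (or higher) root is the Newick convention for unrooted
    return PhyloTree(root=root, rooted=len(root.children) < 3)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; malformed input raises ValueError with position."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(tree.to_newick() + "\n")
    return path


def neighbor_join(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Iteratively joins the pair minimizing Q(i,j) = (n-2)d(i,j) - r_i - r_j;
    ties are broken by the lexicographically smallest pair of representative
    labels (smallest tip under each cluster), so the result is deterministic.
    Negative branch lengths are clamped to zero with a warning.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = matrix.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in matrix.labels]
    reps: list[str] = list(matrix.labels)  # tie-break representative per cluster
    active = list(range(n))
    clamped = False

    def set_length(node: TreeNode, value: float) -> None:
        nonlocal clamped
        if value < 0:
            clamped = True
            value = 0.0
        node.length = value

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new cluster to the others
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        u = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u] = new_row
        D[: u, u] = new_row
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    root = TreeNode()
    set_length(nodes[a], 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    set_length(nodes[b], 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    set_length(nodes[c], 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    for k in (a, b, c):
        root.add_child(nodes[k])
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0", stacklevel=2)
    return PhyloTree(root=root, rooted=False)


def splits(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial bipartitions of the tip set, unrooted interpretation.

    Each split is stored canonically as the side not containing the
    lexicographically smallest tip label.
    """
    all_tips = frozenset(tree.tip_labels)
    if len(all_tips) != tree.n_tips:
        raise ValueError("tip labels must be unique")
    ref = min(all_tips) if all_tips else None
    clades: dict[int, frozenset] = {}
    out: set[frozenset] = set()
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(clades[id(c)] for c in node.children))
        clades[id(node)] = clade
        if node is tree.root:
            continue
        if len(clade) < 2 or len(clade) > len(all_tips) - 2:
            continue  # trivial split
        out.add(clade if ref not in clade else all_tips - clade)
    return out


@dataclass
class SplitComparison:
    shared_pct: float
    rf_distance: int
    n_shared: int
    n_splits_query: int
    n_splits_reference: int


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    s1, s2 = splits(t1), splits(t2)
    return len(s1 ^ s2)


def shared_split_fraction(
    query: PhyloTree, reference: PhyloTree, denominator: str = "reference"
) -> SplitComparison:
    """Percentage of nontrivial splits shared between two trees on one tip set.

    The denominator defaults to the reference (second) tree's split count;
    ``union`` and ``average`` are available alternatives.
    """
    if set(query.tip_labels) != set(reference.tip_labels):
        raise ValueError("trees must share an identical tip set")
    sq, sr = splits(query), splits(reference)
    shared = len(sq & sr)
    if denominator == "reference":
        denom = len(sr)
    elif denominator == "union":
        denom = len(sq | sr)
    elif denominator == "average":
        denom = 0.5 * (len(sq) + len(sr))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct = 100.0 * shared / denom if denom else 0.0
    return SplitComparison(
        shared_pct=pct,
        rf_distance=len(sq ^ sr),
        n_shared=shared,
        n_splits_query=len(sq),
        n_splits_reference=len(sr),
    )


def root_to_tip_lengths(tree: PhyloTree) -> dict[str, float]:
    """Branch-length sum from the root (ancestor of all species) to each tip."""
    if not tree.rooted:
        raise ValueError("root-to-tip lengths require a rooted tree")
    out: dict[str, float] = {}

    def walk(node: TreeNode, depth: float) -> None:
        depth += node.length if node is not tree.root else 0.0
        if node.is_tip:
            out[node.label] = depth
        for c in node.children:
            walk(c, depth)

    walk(tree.root, 0.0)
    return out


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Resolve multifurcations arbitrarily with zero-length internal branches."""
    tree = tree.copy()
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            joint = TreeNode(length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    return tree
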