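"""Rooted/unrooted phylogenetic tree container.

Trees are stored as mutable node hierarchies.  An *unrooted* tree is
represented with a designated trifurcating root; rooted (outgroup-oriented)
trees have a bifurcating root.  Branch lengths are expected substitutions
per site; internal nodes may carry a bootstrap support in [0, 100].
"""
from __future__ import annotations

from typing import Iterable, Iterator, Optional


class Node:
    """A single tree node. Leaves carry a taxon name."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal/{len(self.children)}"
        return f"<Node {kind}>"


class PhyloTree:
    """Tree with unique leaf labels and non-negative branch lengths."""

    def __init__(self, root: Node) -> None:
        self.root = root
        names = root.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in root.postorder():
            if node is not root and node.length is not None and node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} on edge above "
                    f"{node.name or 'internal node'}"
                )

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves:
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    # -- copying -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- topology queries --------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the canonical side not containing
        the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) < 4:
            return set()
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            canon = side if ref not in side else all_leaves - side
            if 1 < len(canon) < len(all_leaves) - 1:
                splits.add(canon)
        return splits

    def rf_distance(self, other: "PhyloTree") -> int:
        """Robinson-Foulds distance (symmetric difference of split sets)."""
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    def clades(self) -> set[frozenset[str]]:
        """All leaf sets subtended by internal edges (uncanonicalized)."""
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            out.add(frozenset(node.leaf_names()))
        return out

    # -- surgery -----------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Collapse internal nodes with a single child, summing lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.parent is None:
                    # root with one child: promote the child
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                    child.parent = parent
                    parent.children[idx] = child
                    node.parent = None
                changed = True
                break

    def unroot(self) -> None:
        """Ensure the root is trifurcating (merge a bifurcating root)."""
        root = self.root
        if len(root.children) != 2:
            return
        left, right = root.children
        keep, fold = (left, right) if not left.is_leaf else (right, left)
        if keep.is_leaf:
            return  # two-leaf tree cannot be unrooted
        root.children = list(keep.children)
        for c in root.children:
            c.parent = root
        fold.length = (fold.length or 0.0) + (keep.length or 0.0)
        root.add_child(fold)
        root.support = None

    def prune_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restriction of the tree to a subset of leaves (copy)."""
        keep = set(taxa)
        missing = keep - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        tree = self.copy()
        changed = True
        while changed:
            changed = False
            for node in list(tree.postorder()):
                if node.is_leaf and node.name not in keep and node.parent is not None:
                    node.parent.remove_child(node)
                    changed = True
                    break
                if not node.is_leaf and not node.children and node.parent is not None:
                    node.parent.remove_child(node)
                    changed = True
                    break
        tree.suppress_unifurcations()
        return tree
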