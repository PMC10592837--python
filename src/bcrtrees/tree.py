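"""Rooted phylogenetic tree structure used throughout the package.

Trees are rooted on (or adjacent to) the clonal germline tip, allow
polytomies and zero-length branches, and store branch lengths in expected
substitutions per site. Newick parsing is delegated to dendropy at the I/O
boundary (:mod:`bcrtrees.io`); this module only knows how to serialize.
"""

from __future__ import annotations

from typing import Iterator, Optional

__all__ = ["Node", "PhyloTree", "GERMLINE_LABEL"]

GERMLINE_LABEL = "Germline"


class Node:
    """A tree node. ``length`` is the branch above the node (None at root)."""

    __slots__ = ("label", "length", "children", "parent", "index")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.index: int = -1  # assigned by PhyloTree._reindex

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def tip_set(self) -> frozenset[str]:
        return frozenset(n.label for n in self.postorder() if n.is_tip)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class PhyloTree:
    """Rooted tree with labelled tips; polytomies and length-0 branches legal."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        for i, node in enumerate(self.root.postorder()):
            node.index = i

    # -- traversal helpers -------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    @property
    def nodes(self) -> list[Node]:
        return list(self.postorder())

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> set[str]:
        return {n.label for n in self.tips}

    def find_tip(self, label: str) -> Node:
        for node in self.postorder():
            if node.is_tip and node.label == label:
                return node
        raise KeyError(f"no tip labelled {label!r}")

    # -- editing -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def suppress_unifurcations(self) -> None:
        """Merge nodes with a single child into their parent edge."""
        changed = True
        while changed:
            changed = False
            for node in list(self.root.postorder()):
                if node.is_tip or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.parent is None:
                    # root unifurcation: child becomes the root
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    parent.remove_child(node)
                    parent.add_child(child)
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                changed = True
        self._reindex()

    def prune_to(self, keep: set[str]) -> None:
        """Remove tips not in ``keep``; collapse resulting unifurcations."""
        missing = keep - self.tip_labels
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        for tip in list(self.tips):
            if tip.label in keep:
                continue
            parent = tip.parent
            parent.remove_child(tip)
            while parent is not None and parent.parent is not None and not parent.children:
                grand = parent.parent
                grand.remove_child(parent)
                parent = grand
        self.suppress_unifurcations()

    def root_on(self, label: str = GERMLINE_LABEL) -> "PhyloTree":
        """Return a copy rooted at the internal node adjacent to tip ``label``.

        The designated tip becomes a child of the new root, so rooted
        clades are always read relative to the germline.
        """
        tree = self.copy()
        tip = tree.find_tip(label)
        new_root = tip.parent
        if new_root is None:  # tree is just the tip
            return tree
        # path from the new root up to the old root; edge i connects
        # path[i] (child side, holds the length) to path[i+1]
        path = []
        node = new_root
        while node is not None:
            path.append(node)
            node = node.parent
        edge_lengths = [p.length for p in path[:-1]]
        for lower, upper in zip(path[:-1], path[1:]):
            upper.children.remove(lower)
        for i, (lower, upper) in enumerate(zip(path[:-1], path[1:])):
            lower.children.append(upper)
            upper.parent = lower
            upper.length = edge_lengths[i]
        new_root.parent = None
        new_root.length = None
        out = PhyloTree(new_root)
        out.suppress_unifurcations()
        return out

    # -- serialization -----------------------------------------------------
    def to_newick(self, include_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = _quote(node.label or "")
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += _quote(node.label)
            if include_lengths and node.length is not None:
                core += f":{node.length:.12g}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {len(self.tips)} tips>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def star_tree(labels: list[str], length: float = 0.0) -> PhyloTree:
    root = Node()
    for lab in labels:
        root.add_child(Node(lab, length))
    return PhyloTree(root)
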