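"""Lightweight rooted-tree structure shared by all pipeline stages.

A :class:`Node` is a mutable n-ary tree node.  Most algorithms in this
package require binary trees; neighbor joining produces a trifurcating
"unrooted" tree whose root degree is 3.  Newick text is parsed with
dendropy and converted into this structure, so the full newick grammar
(quoted labels, comments, exotic whitespace) is supported.

Internal node labels of the form ``"<support>#<class>"`` are split into a
numeric support value and a branch-class label; either part may be absent.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Leaf name, or an arbitrary internal-node label.
    length : float or None
        Length of the edge above this node.
    support : float or None
        Bootstrap support (percentage) of the edge above this node.
    clade_class : str or None
        Branch-class label used by the selection stage (e.g. ``FLC_sstr``).
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("label", "length", "support", "clade_class", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        clade_class: Optional[str] = None,
        children: Optional[list["Node"]] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.clade_class = clade_class
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        for c in children or []:
            self.add_child(c)

    # -- construction -------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    # -- predicates & traversal ---------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def postorder(self) -> Iterator["Node"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Optional["Node"]:
        for n in self.postorder():
            if n.label == label:
                return n
        return None

    # -- editing ------------------------------------------------------
    def copy(self) -> "Node":
        n = Node(self.label, self.length, self.support, self.clade_class)
        for c in self.children:
            n.add_child(c.copy())
        return n

    def suppress_unary(self) -> "Node":
        """Remove unary internal nodes, summing edge lengths.

        Returns the (possibly new) root of the modified tree.
        """
        root = self
        for node in list(root.postorder()):
            if node.is_leaf or len(node.children) != 1:
                continue
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if node.parent is None:
                child.parent = None
                root = child
            else:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        return root

    # -- rendering ----------------------------------------------------
    def _node_token(self, with_support: bool, with_classes: bool) -> str:
        parts = ""
        if self.is_leaf:
            parts = self.label or ""
        else:
            if with_support and self.support is not None:
                parts = format(self.support, "g")
            elif self.label:
                parts = self.label
        if with_classes and self.clade_class:
            parts += f"#{self.clade_class}"
        return parts

    def to_newick(self, with_support: bool = True, with_classes: bool = False) -> str:
        def render(n: Node) -> str:
            tok = n._node_token(with_support, with_classes)
            if not n.is_leaf:
                tok = "(" + ",".join(render(c) for c in n.children) + ")" + tok
            if n.length is not None:
                tok += f":{n.length:.10g}"
            return tok

        return render(self) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.to_newick()})"


def _split_label(raw: Optional[str]) -> tuple[Optional[str], Optional[float], Optional[str]]:
    """Split ``"<label-or-support>#<class>"`` into (label, support, class)."""
    if raw is None or raw == "":
        return None, None, None
    clade = None
    if "#" in raw:
        raw, clade = raw.split("#", 1)
        clade = clade or None
    if raw == "":
        return None, None, clade
    try:
        return None, float(raw), clade
    except ValueError:
        return raw, None, clade


def parse_newick(text: str) -> Node:
    """Parse a newick string into a :class:`Node` tree.

    Raises
    ------
    ValueError
        On malformed newick (message includes the parser's position
        information) or duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.taxon is not None:
            label, support, clade = _split_label(dnode.taxon.label)
            if label is None and support is not None:
                # purely numeric leaf name: keep as label
                label, support = dnode.taxon.label, None
        else:
            label, support, clade = _split_label(dnode.label)
        node = Node(label=label, length=dnode.edge.length, support=support, clade_class=clade)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    seen: set[str] = set()
    for leaf in root.leaves():
        if leaf.label is None:
            raise ValueError("newick parse error: unlabeled leaf")
        if leaf.label in seen:
            raise ValueError(f"duplicate leaf label: {leaf.label!r}")
        seen.add(leaf.label)
    return root
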