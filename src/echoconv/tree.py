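"""Phylogenetic tree structure with labeled foreground edges.

Newick text is parsed with dendropy and converted to a light node structure
that the numerical modules traverse directly.  Foreground edges (the
echolocator lineages, conventionally labeled ``b``, ``d`` and ``g``) are
written PAML-style as a ``#label`` suffix on the node at the child end of
the edge, e.g. ``(Rhinolophus,Hipposideros)#b`` or ``Tursiops#g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy


@dataclass(eq=False)
class Node:
    name: str | None = None
    length: float | None = None
    label: str | None = None          # foreground tag for the edge above
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree; edges are identified with their child node.

    ``edge_id`` of a node: the leaf name for leaves, the foreground label if
    present, else a stable postorder id ``node<i>``.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()

    def _index(self):
        self.postorder: list[Node] = []

        def walk(n: Node):
            for c in n.children:
                c.parent = n
                walk(c)
            self.postorder.append(n)
        self.root.parent = None
        walk(self.root)
        self.nodes = self.postorder
        self.leaves = [n for n in self.postorder if n.is_leaf]
        self.internal = [n for n in self.postorder if not n.is_leaf]
        names = [n.name for n in self.leaves]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names in tree")
        self._edge_ids: dict[Node, str] = {}
        i = 0
        for n in self.postorder:
            if n.label:
                self._edge_ids[n] = n.label
            elif n.is_leaf:
                self._edge_ids[n] = n.name
            else:
                self._edge_ids[n] = f"node{i}"
                i += 1

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def edge_id(self, node: Node) -> str:
        return self._edge_ids[node]

    def node_by_edge_id(self, edge_id: str) -> Node:
        for n, eid in self._edge_ids.items():
            if eid == edge_id:
                return n
        raise KeyError(f"no edge labeled {edge_id!r}")

    @property
    def foreground_edges(self) -> dict[str, Node]:
        return {n.label: n for n in self.postorder if n.label}

    def subtree_leaves(self, node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return out

    def is_ancestor(self, a: Node, b: Node) -> bool:
        n = b.parent
        while n is not None:
            if n is a:
                return True
            n = n.parent
        return False

    def copy(self) -> "PhyloTree":
        def dup(n: Node) -> Node:
            return Node(n.name, n.length, n.label, [dup(c) for c in n.children])
        return PhyloTree(dup(self.root))

    # -- topology comparison (unrooted) ------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each as its smaller-or-canonical side."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)          # canonical side excludes `ref`
        splits = set()
        for n in self.postorder:
            if n is self.root or n.is_leaf:
                continue
            side = frozenset(self.subtree_leaves(n))
            if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
                continue
            if ref in side:
                side = all_leaves - side
            splits.add(side)
        return splits

    def same_unrooted_topology(self, other: "PhyloTree") -> bool:
        if set(self.leaf_names) != set(other.leaf_names):
            return False
        return self.bipartitions() == other.bipartitions()

    def has_clade(self, taxa: set[str]) -> bool:
        """Whether ``taxa`` form a clade in the unrooted sense (a split)."""
        taxa = frozenset(taxa)
        all_leaves = frozenset(self.leaf_names)
        if not taxa <= all_leaves:
            return False
        if len(taxa) <= 1 or taxa == all_leaves:
            return True
        ref = min(all_leaves)
        canon = (all_leaves - taxa) if ref in taxa else taxa
        comp = all_leaves - canon
        if len(canon) == 1 or len(comp) == 1:
            return True
        return canon in self.bipartitions()


def _convert(dnode: dendropy.Node) -> Node:
    raw = dnode.taxon.label if dnode.taxon else dnode.label
    name, tag = None, None
    if raw:
        raw = raw.replace(" ", "_")
        if "#" in raw:
            name, _, tag = raw.partition("#")
            name = name or None
            tag = tag or None
        else:
            name = raw
    length = dnode.edge.length
    node = Node(name=name, length=length, label=tag)
    node.children = [_convert(c) for c in dnode.child_nodes()]
    return node


def read_newick(text: str) -> PhyloTree:
    """Parse newick text (one tree).  Raises ValueError on malformed input."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:                         # dendropy error types vary
        raise ValueError(f"malformed newick: {exc}") from exc
    root = _convert(dtree.seed_node)
    tree = PhyloTree(root)
    for leaf in tree.leaves:
        if leaf.name is None:
            raise ValueError("malformed newick: unnamed leaf")
    return tree


def read_newick_file(path: str | Path) -> PhyloTree:
    return read_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, decimals: int = 6) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.name:
                s += n.name
        if n.label:
            s += f"#{n.label}"
        if n.length is not None and n.parent is not None:
            s += f":{n.length:.{decimals}f}"
        return s
    return fmt(tree.root) + ";"


def write_newick_file(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")
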