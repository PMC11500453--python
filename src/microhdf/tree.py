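"""Rooted taxonomy tree used to linearize abundance profiles.

The tree is the "least-pruned" hierarchy spanning the profile's taxa:
every leaf is a profile taxon and internal nodes are shared taxonomic
ancestors.  Newick exchange goes through dendropy; the in-memory class
is deliberately small because the rest of the package only needs
deterministic traversals and descendant-leaf bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["TreeNode", "TaxonomyTree"]


@dataclass
class TreeNode:
    id: str
    name: str
    rank: str | None = None
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "TreeNode") -> "TreeNode":
        self.children.append(node)
        return node


class TaxonomyTree:
    """A rooted tree with deterministic traversal orders.

    Child order is whatever the construction produced (file order for
    Newick input, lexicographic for lineage-built trees); traversals
    never reorder it, so templates are reproducible for a given tree.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names in tree: {sorted(dupes)}")

    # -- traversals ---------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def level_order(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        queue = [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            queue.extend(node.children)
        return out

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            for child in node.children:
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def node_by_id(self, node_id: str) -> TreeNode:
        for node in self.preorder():
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def descendant_leaves(self, node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        out: list[TreeNode] = []
        stack = list(node.children)
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- editing ------------------------------------------------------

    def prune_leaves(self, keep: set[str]) -> None:
        """Drop leaves whose name is not in `keep`, then empty internals."""

        def walk(node: TreeNode) -> bool:
            node.children = [c for c in node.children if walk(c)]
            if node.is_leaf:
                return node.name in keep or node is self.root
            return True

        # repeat until stable: removing leaves can empty their parents
        before = -1
        while before != self.n_leaves():
            before = self.n_leaves()
            walk(self.root)

    # -- Newick exchange ----------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TaxonomyTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"invalid Newick: {exc}") from exc

        counter = [0]

        def convert(dnode: dendropy.Node) -> TreeNode:
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            else:
                counter[0] += 1
                name = f"_node{counter[0]}"
            node = TreeNode(id=name, name=name, branch_length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            label = node.name
            if any(ch in label for ch in "(),:; "):
                label = f"'{label}'"
            bl = f":{node.branch_length:g}" if node.branch_length is not None else ""
            if node.is_leaf:
                return label + bl
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}){label}{bl}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonomyTree(n_leaves={self.n_leaves()})"
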