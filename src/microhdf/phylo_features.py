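"""Phylogeny-derived feature matrices.

The taxonomy tree spanning the profile's lineage strings is linearized
by two traversal templates:

* **level template** — breadth-first over *all* nodes (root first, each
  level left to right).  Internal-node positions carry the summed
  abundance of their descendant leaves, so each column is a clade
  abundance and the root column equals the sample's total abundance.
* **post-order template** — the depth-first left-to-right *leaf*
  sequence, which places taxa sharing recent ancestry next to each
  other.

Populating the templates with per-sample abundances yields the two
phylogeny-based feature matrices that feed the cascade's second channel;
`assemble_views` concatenates any combination of the raw (O), level (L)
and post-order (P) views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_profiles import AbundanceProfile, parse_lineage
from .tree import TaxonomyTree, TreeNode

__all__ = [
    "TraversalTemplate",
    "PhyloFeatureMatrix",
    "build_taxonomy_tree",
    "reconcile_tree",
    "level_template",
    "postorder_template",
    "populate_template",
    "assemble_views",
]


@dataclass
class TraversalTemplate:
    strategy: str  # "level" | "postorder"
    node_ids: list[str]
    include_internal: bool

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("template node ids are not unique")

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass
class PhyloFeatureMatrix:
    sample_ids: list[str]
    template: TraversalTemplate
    values: np.ndarray
    column_features: list[str]  # original feature id each column reports under

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_taxonomy_tree(profile: AbundanceProfile) -> TaxonomyTree:
    """Build the least-pruned taxonomy tree from the profile's lineage strings.

    Each lineage is a root-to-leaf path; shared rank prefixes share nodes.
    Single-child internal nodes are kept so rank levels stay aligned.
    Children are sorted lexicographically by name at every node, which makes
    the traversal templates reproducible regardless of taxon input order.
    """
    if not profile.taxon_ids:
        raise ValueError("empty profile")
    root = TreeNode(id="root", name="root")
    index: dict[str, TreeNode] = {}
    leaf_paths: dict[str, str] = {}
    terminal_paths: set[str] = set()
    for taxon in profile.taxon_ids:
        lineage = parse_lineage(taxon)
        tokens = lineage.prefixed_tokens()
        node = root
        for depth, token in enumerate(tokens):
            path = "|".join(tokens[: depth + 1])
            is_last = depth == len(tokens) - 1
            if is_last:
                name = lineage.entries[depth][1]
                if name in leaf_paths and leaf_paths[name] != path:
                    raise ValueError(
                        f"conflicting lineages for leaf {name!r}: "
                        f"{leaf_paths[name]} vs {path}"
                    )
                if path in index:
                    raise ValueError(
                        f"taxon {taxon!r} clashes with an existing node; mixed-rank "
                        "profiles (a taxon that is an ancestor of another) are not "
                        "supported — filter the table to a single rank"
                    )
                # leaf id is the full profile taxon id for direct lookup
                child = TreeNode(
                    id=taxon, name=token, rank=lineage.entries[depth][0]
                )
                node.add_child(child)
                index[path] = child
                leaf_paths[name] = path
                terminal_paths.add(path)
            else:
                if path in terminal_paths:
                    raise ValueError(
                        f"taxon at {path!r} is an ancestor of {taxon!r}; mixed-rank "
                        "profiles are not supported — filter the table to a single rank"
                    )
                if path not in index:
                    child = TreeNode(id=path, name=token, rank=tokens[depth][0])
                    node.add_child(child)
                    index[path] = child
                node = index[path]
    _sort_children(root)
    return TaxonomyTree(root)


def _sort_children(node: TreeNode) -> None:
    node.children.sort(key=lambda c: c.name)
    for child in node.children:
        _sort_children(child)


def reconcile_tree(tree: TaxonomyTree, profile: AbundanceProfile) -> TaxonomyTree:
    """Adapt a user-supplied tree to the profile (least-pruned semantics).

    Tree leaves are matched to profile taxa by the terminal rank token
    (e.g. the ``s__`` name) or the full lineage string.  Leaves absent
    from the profile are pruned; profile taxa absent from the tree are
    appended as direct children of the root with a warning.  Matched
    leaves are re-identified by their profile taxon id.
    """
    terminal = {}
    for taxon in profile.taxon_ids:
        lin = parse_lineage(taxon)
        rank, name = lin.terminal
        for key in (taxon, f"{rank}__{name}", name):
            terminal.setdefault(key, taxon)
    matched: dict[str, str] = {}
    for leaf in tree.leaves():
        if leaf.name in terminal:
            matched[leaf.name] = terminal[leaf.name]
    tree.prune_leaves(set(matched))
    for leaf in tree.leaves():
        if leaf.name in matched:
            leaf.id = matched[leaf.name]
    covered = set(matched.values())
    orphans = [t for t in profile.taxon_ids if t not in covered]
    if orphans:
        warnings.warn(
            f"{len(orphans)} profile taxa absent from the supplied tree; "
            "appended as children of the root",
            stacklevel=2,
        )
        for taxon in orphans:
            rank, name = parse_lineage(taxon).terminal
            tree.root.add_child(TreeNode(id=taxon, name=f"{rank}__{name}", rank=rank))
    return TaxonomyTree(tree.root)


def level_template(tree: TaxonomyTree, include_internal: bool = True) -> TraversalTemplate:
    """Breadth-first order over the tree, root first, each level left to right."""
    nodes = tree.level_order()
    if not include_internal:
        nodes = [n for n in nodes if n.is_leaf]
    return TraversalTemplate("level", [n.id for n in nodes], include_internal)


def postorder_template(
    tree: TaxonomyTree, include_internal: bool = False
) -> TraversalTemplate:
    """Depth-first post-order; by default the left-to-right leaf sequence."""
    nodes = tree.postorder()
    if not include_internal:
        nodes = [n for n in nodes if n.is_leaf]
    return TraversalTemplate("postorder", [n.id for n in nodes], include_internal)


def populate_template(
    profile: AbundanceProfile, tree: TaxonomyTree, template: TraversalTemplate
) -> PhyloFeatureMatrix:
    """Fill template positions with per-sample abundances.

    Leaf positions carry the taxon's abundance; internal positions carry
    the sum over descendant leaves, so the hierarchy is additive.
    """
    col = {t: j for j, t in enumerate(profile.taxon_ids)}
    nodes = {n.id: n for n in tree.preorder()}
    out = np.zeros((len(profile.sample_ids), len(template)))
    column_features: list[str] = []
    for j, node_id in enumerate(template.node_ids):
        if node_id not in nodes:
            raise ValueError(f"template node {node_id!r} not in tree")
        node = nodes[node_id]
        if node.is_leaf:
            if node.id not in col:
                raise ValueError(f"template leaf {node.id!r} not in profile")
            out[:, j] = profile.values[:, col[node.id]]
            column_features.append(node.id)
        else:
            leaf_cols = [col[l.id] for l in tree.descendant_leaves(node) if l.id in col]
            if leaf_cols:
                out[:, j] = profile.values[:, leaf_cols].sum(axis=1)
            column_features.append(node.name if node.name else node.id)
    return PhyloFeatureMatrix(list(profile.sample_ids), template, out, column_features)


_VIEW_PREFIX = {"O": "raw", "L": "lvl", "P": "post"}


def assemble_views(
    profile: AbundanceProfile,
    matrix_level: PhyloFeatureMatrix | None,
    matrix_post: PhyloFeatureMatrix | None,
    mode: str,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Concatenate the selected views column-wise.

    Returns (matrix, column names with view-provenance prefixes, original
    feature id per column).  `mode` is one of O, O+L, O+P, O+L+P, L, P, L+P.
    """
    parts = mode.split("+")
    if not parts or any(p not in ("O", "L", "P") for p in parts):
        raise ValueError(f"unknown view mode {mode!r}")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    feats: list[str] = []
    for part in parts:
        if part == "O":
            blocks.append(profile.values)
            names.extend(f"raw:{t}" for t in profile.taxon_ids)
            feats.extend(profile.taxon_ids)
        else:
            m = matrix_level if part == "L" else matrix_post
            if m is None:
                raise ValueError(f"view {part} requested but matrix not supplied")
            if m.sample_ids != profile.sample_ids:
                raise ValueError(f"sample-id mismatch between profile and {part} view")
            blocks.append(m.values)
            names.extend(f"{_VIEW_PREFIX[part]}:{c}" for c in m.column_features)
            feats.extend(m.column_features)
    return np.hstack(blocks), names, feats
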