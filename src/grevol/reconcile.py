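"""Duplication–loss reconciliation of a gene tree with a species tree.

Standard parsimony LCA reconciliation: each gene-tree node is mapped to the
lowest common ancestor of its children's species; a node whose mapping
equals a child's mapping is a duplication; losses are implied wherever a
gene lineage skips speciation nodes on its way down the species tree.  The
duplication+loss count of the LCA mapping is provably minimal over all
reconciliations, so the per-branch gains and losses and the ancestral
repertoire sizes derived from it form the most parsimonious history.

Gains on a species branch are the duplications mapped to the branch's child
node; duplications mapped to the species root are reported on a stem branch
(key ``"__stem__"``) above the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .seqio import species_from_leaf

STEM = "__stem__"


def _check_binary(tree: dendropy.Tree, name: str) -> None:
    for node in tree.preorder_node_iter():
        n = len(node.child_nodes())
        if n not in (0, 2):
            raise ValueError(f"{name} has a non-binary node with {n} children")


def _species_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{id(node)}"


def _index_species_tree(species_tree: dendropy.Tree):
    """Assign stable labels, parent pointers and depths."""
    labels: dict[dendropy.Node, str] = {}
    depth: dict[dendropy.Node, int] = {}
    counter = 0
    for node in species_tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"anc{counter}"
            counter += 1
        labels[node] = _species_label(node)
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
    return labels, depth


def _lca(a: dendropy.Node, b: dendropy.Node, depth) -> dendropy.Node:
    while depth[a] > depth[b]:
        a = a.parent_node
    while depth[b] > depth[a]:
        b = b.parent_node
    while a is not b:
        a, b = a.parent_node, b.parent_node
    return a


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    prefix_map: Mapping[str, str],
) -> dict[dendropy.Node, dendropy.Node]:
    """Map every gene-tree node to its species node.

    Leaves map to the species named by the prefix map; internal nodes map to
    the LCA of their children's mappings.  Both trees must be rooted and
    binary, and every gene leaf must resolve to a species leaf.
    """
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")
    _, depth = _index_species_tree(species_tree)
    species_leaves = {
        leaf.taxon.label: leaf for leaf in species_tree.leaf_node_iter()
    }
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            species = species_from_leaf(label, prefix_map)
            if species not in species_leaves:
                raise KeyError(f"species {species!r} not in the species tree")
            mapping[node] = species_leaves[species]
        else:
            left, right = node.child_nodes()
            mapping[node] = _lca(mapping[left], mapping[right], depth)
    return mapping


@dataclass
class ReconciliationResult:
    """Parsimony DL reconciliation: events per species branch.

    ``gains``/``losses`` are keyed by the species-branch child label (the
    branch leading into that node); duplications mapped to the species root
    are keyed by the stem branch above it.  ``ancestral_count`` gives the
    number of gene lineages present at each species node; within the
    ``origin`` subtree it satisfies
    ``count(child) = count(parent) + gains(child) - losses(child)``, the
    origin itself carrying the founding lineage
    (``count(origin) = 1 + gains(origin branch)``), and every node outside
    that subtree counting zero.
    """

    node_map: dict = field(repr=False)
    duplications: list = field(repr=False)
    gains: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    ancestral_count: dict[str, int] = field(default_factory=dict)
    dl_cost: int = 0
    #: species node where the family originates: the mapping of the gene
    #: root.  Counts above/outside this node's subtree are zero, and its own
    #: count is 1 (the founding lineage) + duplications on its branch.
    origin: str = ""

    @property
    def n_duplications(self) -> int:
        return len(self.duplications)

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    prefix_map: Mapping[str, str],
) -> ReconciliationResult:
    """Full parsimony duplication–loss reconciliation."""
    mapping = lca_map(gene_tree, species_tree, prefix_map)
    labels, depth = _index_species_tree(species_tree)

    gains: dict[str, int] = {STEM: 0}
    losses: dict[str, int] = {STEM: 0}
    for node in species_tree.preorder_node_iter():
        gains.setdefault(labels[node], 0)
        losses.setdefault(labels[node], 0)

    duplications = []
    is_dup: dict[dendropy.Node, bool] = {}
    for g in gene_tree.postorder_node_iter():
        if g.is_leaf():
            is_dup[g] = False
            continue
        children = g.child_nodes()
        dup = any(mapping[c] is mapping[g] for c in children)
        is_dup[g] = dup
        if dup:
            duplications.append(g)
            s = mapping[g]
            key = STEM if s.parent_node is None else labels[s]
            gains[key] += 1

    # losses: for each gene edge, count species nodes whose speciation the
    # lineage passes without leaving a descendant in the sibling subtree
    for g in gene_tree.preorder_node_iter():
        if g.parent_node is None:
            continue
        u, v = g.parent_node, g
        su, sv = mapping[u], mapping[v]
        path = []
        node = sv
        while node is not su:
            path.append(node)
            node = node.parent_node
            if node is None:
                raise RuntimeError("mapping inconsistency: child maps above parent")
        # path = nodes from sv up to (exclusive) su, child-first
        skipped = [n.parent_node for n in path]  # nodes strictly between, plus su
        if not is_dup[u] and skipped:
            skipped = skipped[:-1]  # speciation at su consumes su itself
        for idx, w in enumerate(skipped):
            # the on-path child of w is the previous node on the path
            on_path = path[idx] if idx < len(path) else sv
            sibling = next(c for c in w.child_nodes() if c is not on_path)
            losses[labels[sibling]] += 1

    # ancestral counts, top-down by the conservation identity, seeded by the
    # founding lineage at the gene root's mapping
    origin = mapping[gene_tree.seed_node]
    in_origin_subtree = set()
    stack = [origin]
    while stack:
        n = stack.pop()
        in_origin_subtree.add(id(n))
        stack.extend(n.child_nodes())
    counts: dict[str, int] = {}
    for node in species_tree.preorder_node_iter():
        lab = labels[node]
        if id(node) not in in_origin_subtree:
            counts[lab] = 0
        elif node is origin:
            origin_gain_key = STEM if node.parent_node is None else lab
            counts[lab] = 1 + gains[origin_gain_key] - losses[lab]
        else:
            counts[lab] = counts[labels[node.parent_node]] + gains[lab] - losses[lab]

    return ReconciliationResult(
        node_map=mapping,
        duplications=duplications,
        gains=gains,
        losses=losses,
        ancestral_count=counts,
        dl_cost=len(duplications) + sum(losses.values()),
        origin=labels[origin],
    )


def ancestral_counts(
    result: ReconciliationResult, species_tree: dendropy.Tree
) -> dict[str, int]:
    """Ancestral repertoire size at every species node (from ``result``)."""
    del species_tree  # counts are already keyed by species-node label
    return dict(result.ancestral_count)
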