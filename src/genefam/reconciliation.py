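"""Gene-tree / species-tree reconciliation by LCA mapping.

Maps each gene-tree node to the species-tree most recent common ancestor
of its descendant species, flags duplication nodes, counts parsimony
losses per species-tree edge, and reconstructs ancestral copy numbers.
Both trees must be rooted and binary; polytomies are rejected rather
than silently resolved, since resolution changes the event counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .tree import Node


def species_of_label(label: str) -> str:
    """Leaf labels are ``species|gene_id``; a label without ``|`` is taken
    to be the species itself (single-copy shorthand)."""
    return label.split("|", 1)[0]


def gene_id_of_label(label: str) -> str:
    parts = label.split("|", 1)
    return parts[1] if len(parts) > 1 else parts[0]


@dataclass
class Loss:
    """A single inferred loss, attached to the species-tree edge entering
    ``edge_child`` and caused by the gene lineage below ``gene_node``."""

    edge_child: str
    gene_node: Node


@dataclass
class ReconciliationResult:
    mapping: dict[int, Node]            # id(gene node) -> species node
    duplication_nodes: set[int]         # ids of duplication gene nodes
    losses: list[Loss]
    ancestral_counts: dict[str, int]    # species node label -> copy number
    gene_tree: Node
    species_tree: Node

    def species(self, gene_node: Node) -> Node:
        return self.mapping[id(gene_node)]

    def is_duplication(self, gene_node: Node) -> bool:
        return id(gene_node) in self.duplication_nodes

    def losses_per_edge(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for loss in self.losses:
            out[loss.edge_child] = out.get(loss.edge_child, 0) + 1
        return out

    def duplication_count(self) -> int:
        return len(self.duplication_nodes)


def _check_binary(tree: Node, what: str) -> None:
    for node in tree.postorder():
        if node.children and len(node.children) != 2:
            raise ValueError(
                f"{what} has a polytomy at node {node.label!r}; resolve it first"
            )


def _species_index(species_tree: Node) -> tuple[dict[str, Node], dict[int, int], dict[int, Node]]:
    by_label: dict[str, Node] = {}
    depth: dict[int, int] = {}
    parent: dict[int, Node] = {}
    for node in species_tree.preorder():
        if node.label:
            if node.label in by_label:
                raise ValueError(f"duplicate species-tree label {node.label!r}")
            by_label[node.label] = node
        depth[id(node)] = 0 if node.is_root else depth[id(node.parent)] + 1
        if not node.is_root:
            parent[id(node)] = node.parent
    return by_label, depth, parent


def _lca(a: Node, b: Node, depth: dict[int, int]) -> Node:
    while a is not b:
        if depth[id(a)] < depth[id(b)]:
            b = b.parent
        elif depth[id(a)] > depth[id(b)]:
            a = a.parent
        else:
            a, b = a.parent, b.parent
    return a


def lca_map(
    gene_tree: Node,
    species_tree: Node,
    species_of: Callable[[str], str] = species_of_label,
) -> dict[int, Node]:
    """LCA mapping of gene-tree nodes into the species tree."""
    _check_binary(gene_tree, "gene tree")
    _check_binary(species_tree, "species tree")
    by_label, depth, _ = _species_index(species_tree)
    leaf_species = {n.label for n in species_tree.leaves()}
    mapping: dict[int, Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = species_of(node.label)
            if sp not in leaf_species:
                raise ValueError(f"species {sp!r} (gene {node.label!r}) not in species tree")
            mapping[id(node)] = by_label[sp]
        else:
            m = mapping[id(node.children[0])]
            for c in node.children[1:]:
                m = _lca(m, mapping[id(c)], depth)
            mapping[id(node)] = m
    return mapping


def infer_duplications(gene_tree: Node, mapping: dict[int, Node]) -> set[int]:
    """A node is a duplication iff it maps to the same species-tree node
    as at least one of its children."""
    dups: set[int] = set()
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        if any(mapping[id(c)] is mapping[id(node)] for c in node.children):
            dups.add(id(node))
    return dups


def _path_down(top: Node, bottom: Node) -> list[Node]:
    """Species-tree path from ``top`` down to ``bottom``, inclusive."""
    path = [bottom]
    while path[-1] is not top:
        path.append(path[-1].parent)
    path.reverse()
    return path


def count_losses(
    gene_tree: Node, mapping: dict[int, Node], duplication_nodes: set[int]
) -> list[Loss]:
    """Parsimony losses implied by the mapping, each attached to the
    species-tree edge on which the copy disappeared."""
    losses: list[Loss] = []
    for node in gene_tree.postorder():
        if node.is_leaf:
            continue
        top = mapping[id(node)]
        is_dup = id(node) in duplication_nodes
        for child in node.children:
            bottom = mapping[id(child)]
            if bottom is top:
                continue
            path = _path_down(top, bottom)
            # a copy must be lost in the off-path subtree at each node the
            # lineage passes through; a speciation already accounts for the
            # split at its own mapping
            start = 0 if is_dup else 1
            for k in range(start, len(path) - 1):
                here, next_on_path = path[k], path[k + 1]
                for sp_child in here.children:
                    if sp_child is not next_on_path:
                        losses.append(Loss(edge_child=sp_child.label, gene_node=child))
    return losses


def ancestral_counts(
    gene_tree: Node,
    mapping: dict[int, Node],
    duplication_nodes: set[int],
    species_tree: Node,
) -> dict[str, int]:
    """Gene copy number at each species-tree node: the number of gene
    lineages whose reconciled existence interval covers that node's
    speciation point."""
    counts = {n.label: 0 for n in species_tree.preorder()}

    def is_dup(n: Node) -> bool:
        return id(n) in duplication_nodes

    root = gene_tree
    if not is_dup(root) or root.is_leaf:
        counts[mapping[id(root)].label] += 1
    for node in gene_tree.postorder():
        if node.is_root:
            continue
        u, v = node.parent, node
        top, bottom = mapping[id(u)], mapping[id(v)]
        path = _path_down(top, bottom)
        covered = path if is_dup(u) else path[1:]
        if not is_dup(v) or v.is_leaf:
            pass  # bottom endpoint counts
        else:
            covered = covered[:-1]  # duplication at bottom precedes its speciation
        for sp in covered:
            counts[sp.label] += 1
    return counts


def _validate_flow(result: ReconciliationResult) -> None:
    """count(child) = count(parent) + duplications mapped to child - losses
    on the edge into child, for every species-tree edge."""
    dup_at: dict[str, int] = {}
    for node in result.gene_tree.postorder():
        if result.is_duplication(node):
            label = result.species(node).label
            dup_at[label] = dup_at.get(label, 0) + 1
    loss_at = result.losses_per_edge()
    counts = result.ancestral_counts
    family_root = result.species(result.gene_tree)
    for sp in family_root.preorder():
        for child in sp.children:
            expected = counts[sp.label] + dup_at.get(child.label, 0) - loss_at.get(child.label, 0)
            if counts[child.label] != expected:
                raise AssertionError(
                    f"flow conservation violated on edge into {child.label!r}: "
                    f"{counts[child.label]} != {expected}"
                )


def reconcile(
    gene_tree: Node,
    species_tree: Node,
    species_of: Callable[[str], str] = species_of_label,
) -> ReconciliationResult:
    """Full LCA reconciliation with internal consistency checking."""
    ensure_labels(species_tree)
    mapping = lca_map(gene_tree, species_tree, species_of)
    dups = infer_duplications(gene_tree, mapping)
    losses = count_losses(gene_tree, mapping, dups)
    counts = ancestral_counts(gene_tree, mapping, dups, species_tree)
    result = ReconciliationResult(
        mapping=mapping,
        duplication_nodes=dups,
        losses=losses,
        ancestral_counts=counts,
        gene_tree=gene_tree,
        species_tree=species_tree,
    )
    _validate_flow(result)
    return result


def ensure_labels(tree: Node, prefix: str = "N") -> Node:
    """Assign deterministic labels to unlabeled internal nodes, in
    preorder (``N1``, ``N2``, ...)."""
    existing = {n.label for n in tree.preorder() if n.label}
    counter = 0
    for node in tree.preorder():
        if node.label:
            continue
        counter += 1
        while f"{prefix}{counter}" in existing:
            counter += 1
        node.label = f"{prefix}{counter}"
    return tree


# ----------------------------------------------------------------------
# Tabular export

def reconciliation_tables(result: ReconciliationResult):
    """(duplications, losses, ancestral counts) as pandas DataFrames."""
    import pandas as pd

    dup_rows = []
    for node in result.gene_tree.postorder():
        if result.is_duplication(node):
            dup_rows.append(
                {
                    "gene_node": node.label or "|".join(sorted(node.leaf_labels())[:2]),
                    "species_branch": result.species(node).label,
                    "n_descendants": len(node.leaves()),
                }
            )
    loss_rows = [
        {"species_edge": edge, "losses": n}
        for edge, n in sorted(result.losses_per_edge().items())
    ]
    count_rows = [
        {"species_node": label, "copies": n}
        for label, n in result.ancestral_counts.items()
    ]
    return (
        pd.DataFrame(dup_rows, columns=["gene_node", "species_branch", "n_descendants"]),
        pd.DataFrame(loss_rows, columns=["species_edge", "losses"]),
        pd.DataFrame(count_rows, columns=["species_node", "copies"]),
    )
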