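"""Mechanism classification of inferred duplications from genomic
coordinates.

Every duplication node from reconciliation is assigned a mechanism by
examining the two closest extant descendant copies (one from each child
clade) in a shared species: same-scaffold neighbours within the tandem
window are tandem (or inverted, if on opposite strands), distant
same-scaffold pairs are segmental, and duplications with no same-scaffold
witness in any shared species are transpositions.  Nested same-branch
tandem pairs collapse into triplications, and duplications on annotated
polyploidy branches with cross-scaffold witnesses become WGD/WGT
retentions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import GeneLocus
from .reconciliation import ReconciliationResult
from .synthetic import Polyploidy
from .tree import Node


@dataclass
class Thresholds:
    tandem_max: int = 100_000
    segmental_min: int = 500_000


@dataclass
class EventCall:
    event_id: str
    type: str
    branch: str
    gene_ids: tuple[str, ...]
    scaffold_match: Optional[bool] = None
    distance: Optional[int] = None
    strands: Optional[tuple[str, ...]] = None
    low_confidence: bool = False
    flags: list[str] = field(default_factory=list)
    note: str = ""
    nodes: tuple[int, ...] = ()  # ids of the gene-tree duplication nodes


def locus_gap(a: GeneLocus, b: GeneLocus) -> int:
    """Distance between nearest gene boundaries; 0 if the loci overlap."""
    if a.scaffold != b.scaffold:
        raise ValueError("gap is undefined across scaffolds")
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end)


def _modal_strand(clade_loci: list[GeneLocus], witness: GeneLocus) -> Optional[str]:
    votes = [
        l.strand
        for l in clade_loci
        if l.species == witness.species and l.scaffold == witness.scaffold
    ]
    if not votes:
        return None
    plus = votes.count("+")
    return "+" if plus * 2 > len(votes) else "-" if plus * 2 < len(votes) else None


def _descendant_loci(node: Node, loci_by_id: dict[str, GeneLocus]) -> list[GeneLocus]:
    out = []
    for leaf in node.leaves():
        locus = loci_by_id.get(leaf.label)
        if locus is None:
            raise ValueError(f"no locus for gene-tree leaf {leaf.label!r}")
        out.append(locus)
    return out


def classify_duplication(
    dup_node: Node,
    gene_tree: Node,
    loci_by_id: dict[str, GeneLocus],
    thresholds: Thresholds = Thresholds(),
    branch: str = "",
    event_id: str = "",
) -> EventCall:
    """Classify one duplication node from its witness pair."""
    if len(dup_node.children) != 2:
        raise ValueError("duplication node must be binary")
    left = _descendant_loci(dup_node.children[0], loci_by_id)
    right = _descendant_loci(dup_node.children[1], loci_by_id)

    pairs = [
        (a, b)
        for a in left
        for b in right
        if a.species == b.species
    ]
    if not pairs:
        return EventCall(
            event_id=event_id,
            type="unresolved",
            branch=branch,
            gene_ids=(),
            note="child clades survive in disjoint species; no witness pair",
            nodes=(id(dup_node),),
        )
    same_scaffold = [(a, b) for a, b in pairs if a.scaffold == b.scaffold]
    if not same_scaffold:
        a, b = min(pairs, key=lambda p: (p[0].gene_id, p[1].gene_id))
        return EventCall(
            event_id=event_id,
            type="transposed_duplication",
            branch=branch,
            gene_ids=(a.gene_id, b.gene_id),
            scaffold_match=False,
            strands=(a.strand, b.strand),
            nodes=(id(dup_node),),
        )
    a, b = min(
        same_scaffold,
        key=lambda p: (locus_gap(p[0], p[1]), p[0].gene_id, p[1].gene_id),
    )
    gap = locus_gap(a, b)
    # strand configuration: modal strand of each child clade in the witness
    # species/scaffold is more robust than the single witness pair when
    # later duplications flipped individual copies
    strand_a = _modal_strand(left, a) or a.strand
    strand_b = _modal_strand(right, a) or b.strand
    call = EventCall(
        event_id=event_id,
        type="",
        branch=branch,
        gene_ids=(a.gene_id, b.gene_id),
        scaffold_match=True,
        distance=gap,
        strands=(strand_a, strand_b),
        nodes=(id(dup_node),),
    )
    if gap <= thresholds.tandem_max:
        call.type = (
            "tandem_duplication" if strand_a == strand_b else "inverted_duplication"
        )
    else:
        call.type = "segmental_duplication"
        if gap <= thresholds.segmental_min:
            call.low_confidence = True
            call.note = "distance in the gray zone between tandem and segmental"
    return call


def classify_all(
    reconciliation: ReconciliationResult,
    loci: list[GeneLocus],
    thresholds: Thresholds = Thresholds(),
) -> list[EventCall]:
    """One call per duplication node, ordered root-to-leaf (oldest first)."""
    loci_by_id = {loc.gene_id: loc for loc in loci}
    calls = []
    k = 0
    for node in reconciliation.gene_tree.preorder():
        if not reconciliation.is_duplication(node):
            continue
        k += 1
        calls.append(
            classify_duplication(
                node,
                reconciliation.gene_tree,
                loci_by_id,
                thresholds,
                branch=reconciliation.species(node).label,
                event_id=f"D{k}",
            )
        )
    return calls


_TANDEM_TYPES = ("tandem_duplication", "inverted_duplication")


def collapse_triplications(
    calls: list[EventCall],
    gene_tree: Node,
    loci: list[GeneLocus],
    thresholds: Thresholds = Thresholds(),
) -> list[EventCall]:
    """Merge nested same-branch tandem pairs whose three copies sit
    mutually within the tandem window on one scaffold into a single
    triplication call.  Greedy, oldest pair first."""
    loci_by_id = {loc.gene_id: loc for loc in loci}
    nodes_by_id = {id(n): n for n in gene_tree.preorder()}

    def is_ancestor(a: Node, b: Node) -> bool:
        p = b.parent
        while p is not None:
            if p is a:
                return True
            p = p.parent
        return False

    merged: set[int] = set()
    out: list[EventCall] = []
    order = list(calls)  # classify_all already yields oldest first
    for i, outer in enumerate(order):
        if i in merged or outer.type not in _TANDEM_TYPES:
            continue
        for j in range(i + 1, len(order)):
            inner = order[j]
            if j in merged or inner.type not in _TANDEM_TYPES:
                continue
            if inner.branch != outer.branch:
                continue
            na, nb = nodes_by_id[outer.nodes[0]], nodes_by_id[inner.nodes[0]]
            if not (is_ancestor(na, nb) or is_ancestor(nb, na)):
                continue
            copies = {g: loci_by_id[g] for g in set(outer.gene_ids) | set(inner.gene_ids)}
            if len(copies) < 3:
                continue
            three = sorted(copies.values(), key=lambda l: l.gene_id)[:3]
            scaffolds = {l.scaffold for l in three}
            species = {l.species for l in three}
            if len(scaffolds) != 1 or len(species) != 1:
                continue
            gaps = [
                locus_gap(x, y)
                for xi, x in enumerate(three)
                for y in three[xi + 1 :]
            ]
            if max(gaps) > thresholds.tandem_max:
                continue
            merged.add(i)
            merged.add(j)
            out.append(
                EventCall(
                    event_id=outer.event_id,
                    type="tandem_triplication",
                    branch=outer.branch,
                    gene_ids=tuple(l.gene_id for l in three),
                    scaffold_match=True,
                    distance=max(gaps),
                    strands=tuple(l.strand for l in three),
                    nodes=outer.nodes + inner.nodes,
                )
            )
            break
    for i, call in enumerate(order):
        if i not in merged:
            out.append(call)
    out.sort(key=lambda c: c.event_id)
    return out


def assign_polyploidy(
    calls: list[EventCall],
    polyploidy: dict[str, Polyploidy],
    flag_unannotated: bool = True,
) -> list[EventCall]:
    """Relabel cross-scaffold duplications on annotated WGD/WGT branches
    as polyploidy retentions; flag suspicious unannotated branches."""
    by_branch: dict[str, list[EventCall]] = {}
    for call in calls:
        by_branch.setdefault(call.branch, []).append(call)
    out = []
    for call in calls:
        ann = polyploidy.get(call.branch)
        cross = call.scaffold_match is False
        if ann is not None and cross:
            call.type = "wgd_retention" if ann.kind == "WGD" else "wgt_retention"
            cluster = sum(
                1 for c in by_branch[call.branch] if c.scaffold_match is False
            )
            if cluster >= 2:
                call.flags.append("cluster_support")
        elif ann is None and cross and flag_unannotated:
            cluster = sum(
                1 for c in by_branch[call.branch] if c.scaffold_match is False
            )
            if cluster >= 2:
                call.flags.append("possible_unannotated_WGD")
        out.append(call)
    return out


# ----------------------------------------------------------------------
# Summaries

CLADE_CLASSES = ("FLC_sstr", "MAF123", "MAF45", "background")


def leaf_classes(gene_tree: Node) -> dict[str, str]:
    """Effective clade class per gene leaf: its own class or the nearest
    labelled ancestor's, defaulting to background."""
    out = {}
    for leaf in gene_tree.leaves():
        node: Optional[Node] = leaf
        cls = None
        while node is not None and cls is None:
            cls = node.clade_class
            node = node.parent
        out[leaf.label] = cls or "background"
    return out


def summarize_events(
    calls: list[EventCall],
    losses_per_edge: dict[str, int],
    species_tree: Node,
    gene_tree: Optional[Node] = None,
    loci: Optional[list[GeneLocus]] = None,
):
    """Per-branch event-count table and per-species copy-number table."""
    import pandas as pd

    branches = [n.label for n in species_tree.preorder()]
    types = sorted({c.type for c in calls} | {"loss"} | set(_TANDEM_TYPES))
    per_branch = pd.DataFrame(0, index=branches, columns=types)
    for call in calls:
        per_branch.loc[call.branch, call.type] += 1
    for edge, n in losses_per_edge.items():
        per_branch.loc[edge, "loss"] += n
    per_branch.loc["total"] = per_branch.sum()
    per_branch.index.name = "branch"

    per_species = None
    if gene_tree is not None and loci is not None:
        classes = leaf_classes(gene_tree)
        species = [n.label for n in species_tree.leaves()]
        per_species = pd.DataFrame(0, index=species, columns=list(CLADE_CLASSES))
        for loc in loci:
            cls = classes.get(loc.gene_id, "background")
            if loc.species in per_species.index:
                per_species.loc[loc.species, cls] += 1
        per_species.loc["total"] = per_species.sum()
        per_species.index.name = "species"
    return per_branch, per_species


def calls_table(calls: list[EventCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "type": c.type,
                "branch": c.branch,
                "witnesses": ",".join(c.gene_ids),
                "scaffold_match": c.scaffold_match,
                "distance_bp": c.distance,
                "strands": "/".join(c.strands) if c.strands else "",
                "low_confidence": c.low_confidence,
                "flags": ";".join(c.flags),
                "note": c.note,
            }
            for c in calls
        ],
        columns=[
            "event_id", "type", "branch", "witnesses", "scaffold_match",
            "distance_bp", "strands", "low_confidence", "flags", "note",
        ],
    )
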