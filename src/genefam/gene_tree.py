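"""Gene-tree construction from aligned sequences.

Deterministic alignment trimming, Kimura-corrected protein distances,
Saitou–Nei neighbor joining, column-bootstrap support values, and
outgroup rooting.  The alignment itself is an input (or simulator
truth); no aligner is bundled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .tree import Node

GAP = "-"
SATURATION_CAP = 5.0


@dataclass
class MultipleAlignment:
    """Rows of equal-length aligned sequences.

    ``alphabet`` is ``"protein"`` or ``"codon"``; codon alignments must
    have length divisible by 3 with gaps in whole-codon units.
    """

    records: list[tuple[str, str]]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.alphabet == "codon":
            (length,) = lengths
            if length % 3 != 0:
                raise ValueError("codon alignment length must be divisible by 3")
            for rid, seq in self.records:
                for k in range(0, length, 3):
                    codon = seq[k : k + 3]
                    if GAP in codon and codon != GAP * 3:
                        raise ValueError(
                            f"row {rid!r}: gap not in whole-codon units at position {k}"
                        )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def unit_size(self) -> int:
        return 3 if self.alphabet == "codon" else 1

    def n_units(self) -> int:
        return self.length // self.unit_size()

    def unit(self, row: int, k: int) -> str:
        u = self.unit_size()
        return self.records[row][1][u * k : u * (k + 1)]

    def take_units(self, indices: Sequence[int]) -> "MultipleAlignment":
        u = self.unit_size()
        recs = [
            (rid, "".join(seq[u * k : u * (k + 1)] for k in indices))
            for rid, seq in self.records
        ]
        return MultipleAlignment(recs, self.alphabet)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.isfinite(self.matrix).all():
            raise ValueError("distances must be finite")


# ----------------------------------------------------------------------
# Trimming

def trim_alignment(
    aln: MultipleAlignment,
    max_gap_fraction: float = 0.5,
    min_identity: float = 0.1,
) -> tuple[MultipleAlignment, list[int]]:
    """Keep columns with gap fraction <= ``max_gap_fraction`` whose modal
    non-gap residue frequency (among non-gap rows) is >= ``min_identity``.

    Returns the trimmed alignment and the kept column (unit) indices.
    """
    if not 0 <= max_gap_fraction <= 1 or not 0 <= min_identity <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    n_rows = len(aln.records)
    gap_unit = GAP * aln.unit_size()
    kept: list[int] = []
    for k in range(aln.n_units()):
        column = [aln.unit(r, k) for r in range(n_rows)]
        residues = [c for c in column if c != gap_unit]
        gap_fraction = 1.0 - len(residues) / n_rows
        if gap_fraction > max_gap_fraction:
            continue
        if residues:
            top = max(residues.count(c) for c in set(residues))
            if top / len(residues) < min_identity:
                continue
        kept.append(k)
    if not kept:
        raise ValueError(
            "trimming removed every column; relax max_gap_fraction/min_identity"
        )
    return aln.take_units(kept), kept


def trim_report(aln: MultipleAlignment, kept: Sequence[int]) -> list[tuple[int, float, bool]]:
    """(column index, gap fraction, kept flag) per column, for provenance."""
    n_rows = len(aln.records)
    gap_unit = GAP * aln.unit_size()
    kept_set = set(kept)
    report = []
    for k in range(aln.n_units()):
        gaps = sum(1 for r in range(n_rows) if aln.unit(r, k) == gap_unit)
        report.append((k, gaps / n_rows, k in kept_set))
    return report


# ----------------------------------------------------------------------
# Distances

def protein_distance(
    aln: MultipleAlignment, saturation_cap: float = SATURATION_CAP
) -> DistanceMatrix:
    """Kimura-corrected pairwise protein distances
    ``d = -ln(1 - p - 0.2 p^2)`` over mutually ungapped columns."""
    n = len(aln.records)
    seqs = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in aln.records]
    gap = np.frombuffer(GAP.encode(), dtype="S1")[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            n_ok = int(ok.sum())
            if n_ok == 0:
                raise ValueError(
                    f"sequences {aln.records[i][0]!r} and {aln.records[j][0]!r} "
                    "share no ungapped columns"
                )
            p = float((seqs[i][ok] != seqs[j][ok]).sum()) / n_ok
            arg = 1.0 - p - 0.2 * p * p
            if arg <= 0:
                warnings.warn(
                    f"saturated pair ({aln.records[i][0]}, {aln.records[j][0]}): "
                    f"p={p:.3f}; capping distance at {saturation_cap}"
                )
                d = saturation_cap
            else:
                d = min(-np.log(arg), saturation_cap)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(aln.ids, mat)


# ----------------------------------------------------------------------
# Neighbor joining

def nj_tree(dm: DistanceMatrix) -> Node:
    """Saitou–Nei neighbor joining; returns an unrooted tree represented
    with a trifurcating root.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  Ties in the Q-matrix minimisation are broken by
    the lexicographically lowest pair of cluster labels (a cluster is
    labelled by its smallest leaf label) for determinism.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes = [Node(label) for label in dm.labels]
    reps = list(dm.labels)  # representative (minimum) leaf label per cluster
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-12 * max(1.0, abs(qmin))
        candidates = np.argwhere(q <= qmin + tol)
        best = min(
            (tuple(sorted((reps[active[a]], reps[active[b]]))), a, b)
            for a, b in candidates
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        vi = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new cluster
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    root = Node()
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, v in ((nodes[i], a), (nodes[j], b), (nodes[k], c)):
        node.length = max(v, 0.0)
        root.add_child(node)
    return root


# ----------------------------------------------------------------------
# Splits and bootstrap

def _splits(tree: Node) -> dict[frozenset[str], Node]:
    """Non-trivial bipartitions of an (un)rooted tree, canonicalised to the
    side not containing the lexicographically smallest leaf."""
    universe = frozenset(tree.leaf_labels())
    anchor = min(universe)
    out: dict[frozenset[str], Node] = {}
    for node in tree.postorder():
        if node.is_leaf or node.is_root:
            continue
        below = frozenset(node.leaf_labels())
        if len(below) < 2 or len(universe - below) < 2:
            continue
        side = universe - below if anchor in below else below
        out[side] = node
    return out


def bootstrap_support(
    aln: MultipleAlignment, n_replicates: int = 1000, seed: Optional[int] = None
) -> Node:
    """NJ tree on the full alignment with per-split bootstrap support (%)
    from column resampling."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(aln.records) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    canonical = sort_rows(aln)
    full_tree = nj_tree(protein_distance(canonical))
    target = _splits(full_tree)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    n_units = aln.n_units()
    for _ in range(n_replicates):
        idx = rng.integers(0, n_units, size=n_units)
        rep = canonical.take_units(idx)
        rep_splits = _splits(nj_tree(protein_distance(rep)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in target.items():
        node.support = 100.0 * counts[split] / n_replicates
    return full_tree


def sort_rows(aln: MultipleAlignment) -> MultipleAlignment:
    """Row order canonicalisation so supports are order-invariant."""
    return MultipleAlignment(sorted(aln.records), aln.alphabet)


# ----------------------------------------------------------------------
# Rooting

def _invert_upward(node: Node) -> Node:
    """Re-hang ``node``'s parent side below ``node`` (edge attributes move
    with their edges); returns ``node`` as root of its side."""
    parent = node.parent
    if parent is not None:
        parent.remove_child(node)
        inverted = _invert_upward(parent)
        edge_len, edge_sup, edge_cls = node.length, node.support, node.clade_class
        node.add_child(inverted)
        inverted.length = edge_len
        inverted.support = edge_sup
        inverted.clade_class = edge_cls
    return node


def root_by_outgroup(tree: Node, outgroup_labels: Iterable[str]) -> Node:
    """Root on the edge separating the outgroup from the ingroup, placing
    the root at that edge's midpoint."""
    og = frozenset(outgroup_labels)
    work = tree.copy()
    universe = frozenset(work.leaf_labels())
    unknown = og - universe
    if unknown:
        raise ValueError(f"outgroup labels not in tree: {sorted(unknown)}")
    if og == universe:
        raise ValueError("outgroup cannot contain every leaf")

    edge_child = None
    for node in work.postorder():
        if node.is_root:
            continue
        below = frozenset(node.leaf_labels())
        if below == og or (universe - below) == og:
            edge_child = node
            break
    if edge_child is None:
        raise ValueError(
            f"outgroup is not monophyletic on any rooting: {sorted(og)}"
        )

    below = frozenset(edge_child.leaf_labels())
    old_len = edge_child.length if edge_child.length is not None else 0.0
    support = edge_child.support
    parent = edge_child.parent
    parent.remove_child(edge_child)
    upper = _invert_upward(parent).suppress_unary()
    new_root = Node()
    edge_child.length = old_len / 2
    upper.length = old_len / 2
    upper.support = support
    new_root.add_child(edge_child)
    new_root.add_child(upper)
    # outgroup goes first for presentation stability
    if og != below:
        new_root.children.reverse()
    return new_root
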