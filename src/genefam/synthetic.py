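"""Forward simulation of gene families along a species tree.

Generates gene families with a fully known history — duplication events
of five mechanisms, losses, and whole-genome duplication/triplication
with partial retention — together with genomic coordinates for every
surviving copy, the true gene tree, and codon sequences evolved under a
branch-class-specific dN/dS model.  Every downstream stage of the
pipeline can therefore be tested against logged truth without any
external data.

Events arise from independent Poisson processes per gene lineage; all
randomness flows through a single ``numpy`` generator, so identical
seeds give identical output.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import io as gio
from .gene_tree import MultipleAlignment
from .reconciliation import ensure_labels
from .selection import N_CODONS, SpectralGenerator, build_rate_matrix, uniform_pi
from .tree import Node

DUPLICATION_TYPES = (
    "tandem_duplication",
    "tandem_triplication",
    "inverted_duplication",
    "segmental_duplication",
    "transposed_duplication",
)
EVENT_TYPES = DUPLICATION_TYPES + ("loss", "wgd_retention", "wgt_retention")

# Table-style default branch-class selection strengths
DEFAULT_KAPPA = 1.99
DEFAULT_OMEGA = {
    "background": 0.33,
    "MAF45": 0.41,
    "MAF123": 0.35,
    "FLC_sstr": 0.21,
}


@dataclass
class Polyploidy:
    """WGD/WGT annotation of a species-tree branch.

    ``retention`` holds one probability per extra sub-genome (1 entry for
    WGD, 2 for WGT).
    """

    kind: str
    retention: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"WGD": 1, "WGT": 2}.get(self.kind)
        if expected is None:
            raise ValueError(f"polyploidy kind must be WGD or WGT, got {self.kind!r}")
        if len(self.retention) != expected:
            raise ValueError(f"{self.kind} needs {expected} retention probabilities")
        if any(not 0 <= r <= 1 for r in self.retention):
            raise ValueError("retention probabilities must lie in [0, 1]")


@dataclass
class SpeciesTree:
    """Rooted binary species phylogeny with optional polyploidy branches
    (keyed by the label of the node below the branch)."""

    tree: Node
    polyploidy: dict[str, Polyploidy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ensure_labels(self.tree)
        seen: set[str] = set()
        for node in self.tree.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError(f"species tree must be binary (node {node.label!r})")
            if node.length is not None and node.length < 0:
                raise ValueError("species-tree branch lengths must be >= 0")
            if node.is_leaf:
                if node.label in seen:
                    raise ValueError(f"duplicate species name {node.label!r}")
                seen.add(node.label)
        labels = {n.label for n in self.tree.preorder()}
        for key in self.polyploidy:
            if key not in labels:
                raise ValueError(f"polyploidy annotation on unknown branch {key!r}")


@dataclass
class ScheduledEvent:
    """A deterministic event injected at a fixed point, used by presets to
    pin clade-defining duplications (e.g. the MAF1/2/3–MAF4/5 split)."""

    branch: str
    time: float
    event_type: str
    parent_gene: str
    child_classes: Optional[tuple[Optional[str], ...]] = None


@dataclass
class Event:
    type: str
    branch: str
    time: float
    parent_gene: str
    child_genes: tuple[str, ...]


class EventLog:
    """Ordered record of simulated events plus per-node truth."""

    def __init__(self) -> None:
        self.events: list[Event] = []
        self.true_counts: dict[str, int] = {}
        self.extinct: bool = False

    def add(self, event: Event) -> None:
        self.events.append(event)

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.type] = out.get(ev.type, 0) + 1
        return out

    def duplication_events(self) -> list[Event]:
        return [ev for ev in self.events if ev.type != "loss"]

    def n_duplication_nodes(self) -> int:
        """Number of binary gene-tree duplication nodes implied by the log
        (a triplication contributes two)."""
        n = 0
        for ev in self.events:
            if ev.type != "loss":
                n += len(ev.child_genes)
        return n

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "type": ev.type,
                    "branch": ev.branch,
                    "time": ev.time,
                    "parent_gene": ev.parent_gene,
                    "child_genes": ",".join(ev.child_genes),
                }
                for ev in self.events
            ],
            columns=["type", "branch", "time", "parent_gene", "child_genes"],
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class SimulationConfig:
    """Rates are per gene lineage per unit branch length."""

    rates: dict[str, float] = field(default_factory=dict)
    tandem_offset_bp: tuple[int, int] = (2_000, 50_000)
    segmental_min_bp: int = 500_000
    transposed_scaffold_prefix: str = "scf_t"
    root_genes: tuple[tuple[str, Optional[str]], ...] = (
        ("FLC", "FLC_sstr"),
        ("MAF", None),
    )
    kappa: float = DEFAULT_KAPPA
    omega_by_class: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    pi: Optional[np.ndarray] = None
    n_codons: int = 200
    n_exons: int = 7
    intron_bp: int = 300
    scheduled: tuple[ScheduledEvent, ...] = ()

    def __post_init__(self) -> None:
        for etype, rate in self.rates.items():
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event type {etype!r}")
            if rate < 0:
                raise ValueError(f"rate for {etype} must be >= 0")
        for cls, w in self.omega_by_class.items():
            if w <= 0:
                raise ValueError(f"omega for class {cls!r} must be > 0")
        if not self.root_genes:
            raise ValueError("root gene count must be >= 1")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (N_CODONS,) or not np.isclose(self.pi.sum(), 1.0):
                raise ValueError("pi must hold 61 sense-codon frequencies summing to 1")

    def rate(self, etype: str) -> float:
        return self.rates.get(etype, 0.0)

    def gene_span(self) -> int:
        return 3 * self.n_codons + (self.n_exons - 1) * self.intron_bp

    def exon_layout(self, start: int) -> list[tuple[int, int]]:
        total = 3 * self.n_codons
        base = total // self.n_exons
        sizes = [base] * (self.n_exons - 1) + [total - base * (self.n_exons - 1)]
        exons = []
        pos = start
        for size in sizes:
            exons.append((pos, pos + size))
            pos += size + self.intron_bp
        return exons


# ----------------------------------------------------------------------
# Simulation machinery

@dataclass
class _Lineage:
    node: Node
    opened: float  # absolute time at which this gene-tree edge started
    gene: str
    scaffold: str
    start: int
    strand: str
    clade: Optional[str]


class _Simulator:
    def __init__(self, species_tree: SpeciesTree, config: SimulationConfig, seed) -> None:
        self.st = species_tree
        self.cfg = config
        self.rng = np.random.default_rng(seed)
        self.log = EventLog()
        self.counter = itertools.count(1)
        self.t_counter = itertools.count(1)
        self.loci: list[gio.GeneLocus] = []
        self.span = config.gene_span()
        self._dup_rates = [(t, config.rate(t)) for t in DUPLICATION_TYPES]
        self._total_rate = sum(r for _, r in self._dup_rates) + config.rate("loss")

    # -- helpers -------------------------------------------------------
    def _new_gene_name(self) -> str:
        return f"g{next(self.counter)}"

    def _close(self, lin: _Lineage, t_abs: float) -> None:
        lin.node.length = max(t_abs - lin.opened, 0.0)

    def _child_node(self, lin: _Lineage, t_abs: float, clade: Optional[str]) -> Node:
        node = Node(clade_class=clade)
        lin.node.add_child(node)
        return node

    def _place_copy(self, lin: _Lineage, etype: str) -> tuple[str, int, str]:
        lo, hi = self.cfg.tandem_offset_bp
        if etype in ("tandem_duplication", "tandem_triplication"):
            offset = int(self.rng.integers(lo, hi + 1))
            return lin.scaffold, lin.start + self.span + offset, lin.strand
        if etype == "inverted_duplication":
            offset = int(self.rng.integers(lo, hi + 1))
            strand = "-" if lin.strand == "+" else "+"
            return lin.scaffold, lin.start + self.span + offset, strand
        if etype == "segmental_duplication":
            offset = self.cfg.segmental_min_bp + int(self.rng.integers(0, 500_001))
            return lin.scaffold, lin.start + self.span + offset, lin.strand
        if etype == "transposed_duplication":
            scaffold = f"{self.cfg.transposed_scaffold_prefix}{next(self.t_counter)}"
            return scaffold, 10_000, lin.strand
        raise ValueError(f"unknown duplication type {etype!r}")

    def _apply_duplication(
        self,
        lineages: list[_Lineage],
        lin: _Lineage,
        etype: str,
        branch: str,
        t_branch: float,
        t_abs: float,
        child_classes: Optional[tuple[Optional[str], ...]] = None,
    ) -> None:
        n_new = 2 if etype == "tandem_triplication" else 1
        classes = child_classes or (lin.clade,) * (n_new + 1)
        self._close(lin, t_abs)
        cont_node = self._child_node(lin, t_abs, classes[0])
        new_names = []
        new_lineages = []
        if etype == "tandem_triplication":
            inner = self._child_node(lin, t_abs, lin.clade)
            inner.length = 0.0
            holder = _Lineage(inner, t_abs, lin.gene, lin.scaffold, lin.start, lin.strand, lin.clade)
            for k in range(2):
                name = self._new_gene_name()
                scaffold, start, strand = self._place_copy(lin, etype)
                node = self._child_node(holder, t_abs, classes[k + 1])
                new_lineages.append(
                    _Lineage(node, t_abs, name, scaffold, start, strand, classes[k + 1])
                )
                new_names.append(name)
        else:
            name = self._new_gene_name()
            scaffold, start, strand = self._place_copy(lin, etype)
            node = self._child_node(lin, t_abs, classes[1])
            new_lineages.append(_Lineage(node, t_abs, name, scaffold, start, strand, classes[1]))
            new_names.append(name)
        # continuing copy keeps the parent's name and coordinates
        idx = lineages.index(lin)
        lineages[idx] = _Lineage(
            cont_node, t_abs, lin.gene, lin.scaffold, lin.start, lin.strand, classes[0]
        )
        lineages.extend(new_lineages)
        self.log.add(Event(etype, branch, t_branch, lin.gene, tuple(new_names)))

    def _apply_loss(
        self, lineages: list[_Lineage], lin: _Lineage, branch: str, t_branch: float, t_abs: float
    ) -> None:
        self._close(lin, t_abs)
        lineages.remove(lin)
        self.log.add(Event("loss", branch, t_branch, lin.gene, ()))

    def _apply_polyploidy(
        self, lineages: list[_Lineage], ann: Polyploidy, branch: str, t_abs: float
    ) -> None:
        etype = "wgd_retention" if ann.kind == "WGD" else "wgt_retention"
        for lin in list(lineages):
            current = lin
            for sub, keep_p in enumerate(ann.retention, start=2):
                if self.rng.random() >= keep_p:
                    continue
                name = self._new_gene_name()
                self._close(current, t_abs)
                cont = self._child_node(current, t_abs, current.clade)
                copy_node = self._child_node(current, t_abs, current.clade)
                scaffold = f"{current.scaffold}_sg{sub}"
                new_lin = _Lineage(
                    copy_node, t_abs, name, scaffold, current.start, current.strand, current.clade
                )
                idx = lineages.index(current if current in lineages else lin)
                cont_lin = _Lineage(
                    cont, t_abs, current.gene, current.scaffold, current.start,
                    current.strand, current.clade,
                )
                lineages[idx] = cont_lin
                lineages.append(new_lin)
                self.log.add(Event(etype, branch, 0.0, current.gene, (name,)))
                current = cont_lin

    def _finalize_leaf(self, lin: _Lineage, species: str, t_abs: float) -> None:
        self._close(lin, t_abs)
        gene_id = f"{species}|{lin.gene}"
        lin.node.label = gene_id
        locus = gio.GeneLocus(
            gene_id=gene_id,
            species=species,
            scaffold=lin.scaffold,
            start=lin.start,
            end=lin.start + self.span,
            strand=lin.strand,
            exons=self.cfg.exon_layout(lin.start),
            cds="",
        )
        self.loci.append(locus)

    # -- main recursion -------------------------------------------------
    def run(self) -> tuple[Optional[Node], EventLog, list[gio.GeneLocus]]:
        root = Node()
        lineages: list[_Lineage] = []
        scaffold = "scf1"
        pos = 10_000
        names = [name for name, _ in self.cfg.root_genes]
        if len(self.cfg.root_genes) == 1:
            name, clade = self.cfg.root_genes[0]
            root.clade_class = clade
            lineages.append(_Lineage(root, 0.0, name, scaffold, pos, "+", clade))
        else:
            for name, clade in self.cfg.root_genes:
                node = Node(clade_class=clade)
                root.add_child(node)
                lineages.append(_Lineage(node, 0.0, name, scaffold, pos, "+", clade))
                pos += self.span + 12_000
            # binarise the family root if more than two root genes
            while len(root.children) > 2:
                a = root.children.pop()
                b = root.children.pop()
                joint = Node()
                joint.add_child(a)
                joint.add_child(b)
                root.add_child(joint)
                joint.length = 0.0
            root_branch = self.st.tree.label
            for name in names[1:]:
                self.log.add(Event("tandem_duplication", root_branch, 0.0, names[0], (name,)))
        self._process(self.st.tree, lineages, 0.0)
        survivors = {loc.gene_id for loc in self.loci}
        gene_tree = _prune(root, survivors)
        if gene_tree is None:
            self.log.extinct = True
            return None, self.log, []
        gene_tree.length = None
        return gene_tree, self.log, self.loci

    def _process(self, sp_node: Node, lineages: list[_Lineage], t_abs: float) -> None:
        branch = sp_node.label
        length = sp_node.length or 0.0
        ann = self.st.polyploidy.get(branch)
        if ann is not None and lineages:
            self._apply_polyploidy(lineages, ann, branch, t_abs)
        pending = sorted(
            (se for se in self.cfg.scheduled if se.branch == branch), key=lambda se: se.time
        )
        t = 0.0
        while True:
            next_sched = pending[0].time if pending else math.inf
            if lineages and self._total_rate > 0:
                t_next = t + self.rng.exponential(1.0 / (self._total_rate * len(lineages)))
            else:
                t_next = math.inf
            if min(t_next, next_sched) > length:
                break
            if next_sched <= t_next:
                se = pending.pop(0)
                t = se.time
                target = next((l for l in lineages if l.gene == se.parent_gene), None)
                if target is None:
                    continue
                if se.event_type == "loss":
                    self._apply_loss(lineages, target, branch, t, t_abs + t)
                else:
                    self._apply_duplication(
                        lineages, target, se.event_type, branch, t, t_abs + t, se.child_classes
                    )
                continue
            t = t_next
            lin = lineages[int(self.rng.integers(len(lineages)))]
            u = self.rng.random() * self._total_rate
            acc = 0.0
            chosen = "loss"
            for etype, rate in self._dup_rates:
                acc += rate
                if u < acc:
                    chosen = etype
                    break
            if chosen == "loss":
                self._apply_loss(lineages, lin, branch, t, t_abs + t)
            else:
                self._apply_duplication(lineages, lin, chosen, branch, t, t_abs + t)

        t_end = t_abs + length
        self.log.true_counts[branch] = len(lineages)
        if sp_node.is_leaf:
            for lin in lineages:
                self._finalize_leaf(lin, branch, t_end)
            return
        for lin in lineages:
            self._close(lin, t_end)
        for child in sp_node.children:
            child_lineages = []
            for lin in lineages:
                node = self._child_node(lin, t_end, lin.clade)
                child_lineages.append(
                    _Lineage(node, t_end, lin.gene, lin.scaffold, lin.start, lin.strand, lin.clade)
                )
            self._process(child, child_lineages, t_end)


def _prune(root: Node, keep_labels: set[str]) -> Optional[Node]:
    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node.label in keep_labels else None
        kept = [k for k in (rec(c) for c in list(node.children)) if k is not None]
        for c in list(node.children):
            node.remove_child(c)
        for k in kept:
            node.add_child(k)
        return node if kept else None

    trimmed = rec(root)
    if trimmed is None:
        return None
    return trimmed.suppress_unary()


def simulate_gene_family(
    species_tree: SpeciesTree, config: SimulationConfig, seed
) -> tuple[Optional[Node], EventLog, list[gio.GeneLocus]]:
    """Simulate a gene family; returns (true gene tree, event log, loci).

    A fully extinct family yields ``(None, log, [])`` with
    ``log.extinct`` set — extinction is an outcome, not an error.
    """
    if not config.root_genes:
        raise ValueError("cannot simulate a family with zero root genes")
    return _Simulator(species_tree, config, seed).run()


# ----------------------------------------------------------------------
# Sequence evolution

def evolve_codon_sequences(
    gene_tree: Node,
    kappa: float,
    omega_by_class: dict[str, float],
    pi: Optional[np.ndarray],
    n_codons: int,
    seed,
) -> MultipleAlignment:
    """Evolve a gap-free codon alignment down the gene tree.

    Branch lengths are expected substitutions per codon; each branch uses
    the rate matrix of its class.
    """
    if pi is None:
        pi = uniform_pi()
    pi = np.asarray(pi, dtype=float)
    rng = np.random.default_rng(seed)
    spectra: dict[str, SpectralGenerator] = {}

    def spectrum(node: Node) -> SpectralGenerator:
        cls = node.clade_class or "background"
        if cls not in omega_by_class:
            raise ValueError(f"branch class {cls!r} (node {node.label!r}) has no omega")
        if cls not in spectra:
            spectra[cls] = SpectralGenerator(build_rate_matrix(kappa, omega_by_class[cls], pi), pi)
        return spectra[cls]

    states: dict[int, np.ndarray] = {
        id(gene_tree): rng.choice(N_CODONS, size=n_codons, p=pi)
    }
    records: list[tuple[str, str]] = []
    from .selection import CODONS

    for node in gene_tree.preorder():
        if node.is_root:
            continue
        parent_states = states[id(node.parent)]
        t = node.length or 0.0
        if t <= 0:
            child_states = parent_states.copy()
        else:
            p = spectrum(node).probs(t)
            rows = p[parent_states]
            rows = rows / rows.sum(axis=1, keepdims=True)
            u = rng.random(n_codons)
            child_states = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
            np.clip(child_states, 0, N_CODONS - 1, out=child_states)
        states[id(node)] = child_states
        if node.is_leaf:
            seq = "".join(CODONS[s] for s in child_states)
            records.append((node.label, seq))
    if gene_tree.is_leaf:
        seq = "".join(CODONS[s] for s in states[id(gene_tree)])
        records.append((gene_tree.label, seq))
    return MultipleAlignment(records, alphabet="codon")


# ----------------------------------------------------------------------
# Presets and fixtures

def _balanced(names: list[str], inner_len: float, leaf_len: float) -> Node:
    nodes = [Node(n, length=leaf_len) for n in names]
    while len(nodes) > 1:
        paired = []
        for i in range(0, len(nodes) - 1, 2):
            parent = Node(length=inner_len)
            parent.add_child(nodes[i])
            parent.add_child(nodes[i + 1])
            paired.append(parent)
        if len(nodes) % 2:
            paired.append(nodes[-1])
        nodes = paired
    return nodes[0]


def _toy4() -> tuple[SpeciesTree, SimulationConfig]:
    tree = Node(
        "R",
        children=[
            Node("AB", 0.2, children=[Node("A", 0.3), Node("B", 0.3)]),
            Node("CD", 0.2, children=[Node("C", 0.3), Node("D", 0.3)]),
        ],
    )
    cfg = SimulationConfig(
        rates={},
        root_genes=(("FLC", None),),
        omega_by_class={"background": 0.3},
        n_codons=120,
    )
    return SpeciesTree(tree), cfg


def _core16() -> tuple[SpeciesTree, SimulationConfig]:
    left = _balanced([f"S{i:02d}" for i in range(1, 9)], 0.08, 0.1)
    right = _balanced([f"S{i:02d}" for i in range(9, 17)], 0.08, 0.1)
    left.length = 0.1
    left.label = "coreL"
    right.length = 0.1
    tree = Node("R", children=[left, right])
    cfg = SimulationConfig(
        rates={
            "tandem_duplication": 0.5,
            "tandem_triplication": 0.08,
            "inverted_duplication": 0.08,
            "segmental_duplication": 0.05,
            "transposed_duplication": 0.12,
            "loss": 0.3,
        },
        root_genes=(("FLC", "FLC_sstr"), ("MAF", None)),
        scheduled=(
            ScheduledEvent(
                branch="coreL",
                time=0.05,
                event_type="tandem_duplication",
                parent_gene="MAF",
                child_classes=("MAF123", "MAF45"),
            ),
        ),
        n_codons=150,
    )
    return SpeciesTree(tree), cfg


def _brassicaceae_like() -> tuple[SpeciesTree, SimulationConfig]:
    lineage1 = _balanced(
        ["Arabidopsis_like", "Camelina_like", "Nasturtium_like"]
        + [f"LI_sp{i}" for i in range(4, 10)],
        0.05,
        0.08,
    )
    lineage1.label = "lineageI"
    lineage1.length = 0.08
    brassiceae = _balanced([f"Brassiceae_sp{i}" for i in range(1, 6)], 0.04, 0.06)
    brassiceae.label = "Brassiceae"
    brassiceae.length = 0.05
    lineage2_rest = _balanced([f"LII_sp{i}" for i in range(1, 5)], 0.05, 0.08)
    lineage2 = Node("lineageII", 0.08, children=[brassiceae, lineage2_rest])
    lineage2_rest.length = 0.05
    lineage3 = _balanced([f"LIII_sp{i}" for i in range(1, 10)], 0.05, 0.08)
    lineage3.label = "lineageIII"
    lineage3.length = 0.08
    inner = Node("lineageII_III", 0.05, children=[lineage2, lineage3])
    core = Node("coreBrassicaceae", 0.12, children=[lineage1, inner])
    brassicaceae = Node("Brassicaceae", 0.15, children=[Node("Aethionema_like", 0.35), core])
    root = Node("R", children=[Node("Tarenaya_like", 0.5), brassicaceae])

    polyploidy = {
        "Camelina_like": Polyploidy("WGT", (0.5, 0.5)),
        "Brassiceae": Polyploidy("WGT", (0.45, 0.45)),
        "Nasturtium_like": Polyploidy("WGD", (0.6,)),
    }
    cfg = SimulationConfig(
        rates={
            # calibrated so core species typically carry 1-9 MAF-like genes
            "tandem_duplication": 0.45,
            "tandem_triplication": 0.07,
            "inverted_duplication": 0.05,
            "segmental_duplication": 0.03,
            "transposed_duplication": 0.1,
            "loss": 0.35,
        },
        root_genes=(("FLC", "FLC_sstr"), ("MAF", None)),
        scheduled=(
            ScheduledEvent(
                branch="coreBrassicaceae",
                time=0.06,
                event_type="tandem_duplication",
                parent_gene="MAF",
                child_classes=("MAF123", "MAF45"),
            ),
            # the outgroup keeps only its FLC-like representatives, so its
            # genes root the family tree between the FLC and MAF clades
            ScheduledEvent(
                branch="Tarenaya_like",
                time=0.01,
                event_type="loss",
                parent_gene="MAF",
            ),
        ),
        n_codons=180,
    )
    return SpeciesTree(root, polyploidy), cfg


PRESETS = {
    "toy4": _toy4,
    "core16": _core16,
    "brassicaceae_like": _brassicaceae_like,
}


@dataclass
class FixtureBundle:
    species_tree: SpeciesTree
    gene_tree: Optional[Node]
    event_log: EventLog
    loci: list[gio.GeneLocus]
    alignment: Optional[MultipleAlignment]
    config: SimulationConfig


def make_fixture(preset: str, seed, out_dir: Optional[str | os.PathLike] = None) -> FixtureBundle:
    """Simulate a named preset and (optionally) write all files."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    species_tree, cfg = PRESETS[preset]()
    gene_tree, log, loci = simulate_gene_family(species_tree, cfg, seed)
    alignment = None
    if gene_tree is not None and not gene_tree.is_leaf:
        alignment = evolve_codon_sequences(
            gene_tree, cfg.kappa, cfg.omega_by_class, cfg.pi, cfg.n_codons, seed
        )
        seq_of = dict(alignment.records)
        for locus in loci:
            locus.cds = seq_of[locus.gene_id]
    bundle = FixtureBundle(species_tree, gene_tree, log, loci, alignment, cfg)
    if out_dir is not None:
        write_fixture(bundle, out_dir, seed=seed, preset=preset)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir: str | os.PathLike, **meta) -> None:
    os.makedirs(out_dir, exist_ok=True)
    out = str(out_dir)
    gio.write_newick(bundle.species_tree.tree, os.path.join(out, "species_tree.nwk"))
    if bundle.gene_tree is not None:
        gio.write_newick(
            bundle.gene_tree, os.path.join(out, "gene_tree.nwk"), with_classes=True
        )
    gio.write_loci_table(bundle.loci, os.path.join(out, "loci.tsv"))
    bundle.event_log.write_tsv(os.path.join(out, "events.tsv"))
    if bundle.alignment is not None:
        gio.write_fasta(
            [gio.SequenceRecord(rid, seq) for rid, seq in bundle.alignment.records],
            os.path.join(out, "cds.fasta"),
        )
    cfg = asdict(bundle.config)
    cfg["pi"] = None if bundle.config.pi is None else list(map(float, bundle.config.pi))
    cfg["polyploidy"] = {
        k: {"kind": v.kind, "retention": list(v.retention)}
        for k, v in bundle.species_tree.polyploidy.items()
    }
    cfg.update(meta)
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)


# ----------------------------------------------------------------------
# Fixed labelled tree for selection experiments

def selection_tree() -> Node:
    """A 12-taxon rooted tree whose branches are labelled into the four
    selection classes (three 3-leaf ingroup clades plus a background
    outgroup); used for simulation-and-refit experiments."""

    def clade(names, cls, tips, inner, stem):
        a = Node(names[0], tips[0], clade_class=cls)
        b = Node(names[1], tips[1], clade_class=cls)
        c = Node(names[2], tips[2], clade_class=cls)
        ab = Node(length=inner, clade_class=cls, children=[a, b])
        return Node(length=stem, clade_class=cls, children=[ab, c])

    flc = clade(["flc1", "flc2", "flc3"], "FLC_sstr", (0.12, 0.15, 0.2), 0.1, 0.15)
    maf123 = clade(["m1a", "m1b", "m1c"], "MAF123", (0.15, 0.18, 0.22), 0.12, 0.15)
    maf45 = clade(["m4a", "m4b", "m4c"], "MAF45", (0.18, 0.22, 0.25), 0.15, 0.18)
    maf = Node(length=0.12, children=[maf123, maf45])
    ingroup = Node(length=0.15, children=[flc, maf])
    o1 = Node("out1", 0.2)
    o2 = Node("out2", 0.15)
    o3 = Node("out3", 0.18)
    o23 = Node(length=0.1, children=[o2, o3])
    outgroup = Node(length=0.12, children=[o1, o23])
    return Node(children=[outgroup, ingroup])


def tree_length(tree: Node) -> float:
    """Sum of branch lengths below (and excluding) the root edge."""
    return sum(n.length or 0.0 for n in tree.postorder() if not n.is_root)
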