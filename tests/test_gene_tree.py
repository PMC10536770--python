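import itertools

import numpy as np
import pytest

from genefam.gene_tree import (
    DistanceMatrix,
    MultipleAlignment,
    _splits,
    bootstrap_support,
    nj_tree,
    protein_distance,
    root_by_outgroup,
    trim_alignment,
)
from genefam.tree import Node, parse_newick


def aln(*rows, alphabet="protein"):
    return MultipleAlignment([(f"s{i}", r) for i, r in enumerate(rows)], alphabet)


# ----------------------------------------------------------------------
# Trimming

def test_trim_removes_gappy_column():
    a = MultipleAlignment(
        [("a", "A-"), ("b", "A-"), ("c", "A-"), ("d", "AC"), ("e", "AC")]
    )
    trimmed, kept = trim_alignment(a, max_gap_fraction=0.5)
    assert kept == [0]
    assert trimmed.records[0][1] == "A"


def test_trim_identity_on_conserved():
    a = aln("MKV", "MKV", "MKV")
    trimmed, kept = trim_alignment(a)
    assert kept == [0, 1, 2]
    assert trimmed.records == a.records


def test_trim_designed_columns():
    # 4x10 alignment; columns 2, 5, 8 designed to fail
    rows = [
        "MA-VD-KL-R",
        "MA-VDAKL-R",
        "MAWVD-KL-R",
        "MA-VDCKLQR",
    ]
    # col 2: gaps 3/4 > 0.5 -> removed; col 5: gaps 2/4 ok but residues A,C
    # distinct (majority 1/2 >= 0.1 keeps it) -> adjust with min_identity 0.6
    a = aln(*rows)
    trimmed, kept = trim_alignment(a, max_gap_fraction=0.5, min_identity=0.6)
    assert kept == [0, 1, 3, 4, 6, 7, 9]  # cols 2, 5, 8 removed


def test_trim_idempotent():
    rows = ["MA-VD-KL-R", "MA-VDAKL-R", "MAWVD-KL-R", "MA-VDCKLQR"]
    a = aln(*rows)
    once, kept1 = trim_alignment(a)
    twice, kept2 = trim_alignment(once)
    assert twice.records == once.records


def test_trim_all_removed():
    a = MultipleAlignment([("a", "-A"), ("b", "-C"), ("c", "-G"), ("d", "-T")])
    with pytest.raises(ValueError, match="relax"):
        trim_alignment(a, max_gap_fraction=0.0, min_identity=1.0)


def test_trim_codon_units():
    a = MultipleAlignment(
        [("a", "ATG---"), ("b", "ATG---"), ("c", "ATGAAA"), ("d", "ATGAAA")],
        alphabet="codon",
    )
    trimmed, kept = trim_alignment(a, max_gap_fraction=0.4)
    assert kept == [0]
    assert trimmed.length == 3


# ----------------------------------------------------------------------
# Distances

def test_distance_identical_zero():
    d = protein_distance(aln("MKVL", "MKVL"))
    assert d.matrix[0, 1] == 0.0


def test_distance_closed_form():
    # p = 0.1 over 10 columns -> d = -ln(1 - 0.1 - 0.002)
    d = protein_distance(aln("AAAAAAAAAA", "AAAAAAAAAC"))
    assert d.matrix[0, 1] == pytest.approx(-np.log(1 - 0.1 - 0.2 * 0.01))
    assert d.matrix[0, 1] == pytest.approx(0.1076, abs=1e-4)


def test_distance_symmetric_random(rng):
    rows = ["".join(rng.choice(list("ACDEFGHIKL"), size=40)) for _ in range(5)]
    d = protein_distance(aln(*rows))
    assert np.allclose(d.matrix, d.matrix.T)
    assert np.all(np.diag(d.matrix) == 0)


def test_distance_no_overlap():
    with pytest.raises(ValueError, match="no ungapped"):
        protein_distance(aln("AA--", "--CC"))


def test_distance_saturation_cap():
    with pytest.warns(UserWarning, match="saturated"):
        d = protein_distance(aln("AAAAAAAAAA", "CCCCCCCCCC"))
    assert d.matrix[0, 1] == 5.0


# ----------------------------------------------------------------------
# Neighbor joining

def _path_distance(tree, a, b):
    anc = {}
    n, d = a, 0.0
    while n is not None:
        anc[id(n)] = d
        d += n.length or 0.0
        n = n.parent
    n, d = b, 0.0
    while id(n) not in anc:
        d += n.length or 0.0
        n = n.parent
    return d + anc[id(n)]


def _additive_matrix(tree):
    leaves = tree.leaves()
    labels = [l.label for l in leaves]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _path_distance(tree, leaves[i], leaves[j])
    return DistanceMatrix(labels, m)


def test_nj_three_taxa_closed_form():
    m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = nj_tree(DistanceMatrix(["A", "B", "C"], m))
    lengths = {n.label: n.length for n in tree.children}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_four_taxon_split():
    source = parse_newick("((A:1,B:2):1.5,(C:1,D:3):1);")
    tree = nj_tree(_additive_matrix(source))
    assert frozenset({"A", "B"}) in {frozenset(s) for s in _splits(tree)} or \
        frozenset({"C", "D"}) in {frozenset(s) for s in _splits(tree)}


def test_nj_five_taxon_exact_lengths():
    source = parse_newick("((A:2,B:3):1,(C:2,(D:1,E:4):2):2);")
    dm = _additive_matrix(source)
    tree = nj_tree(dm)
    # exact branch-length recovery: NJ distances reproduce the input matrix
    recovered = _additive_matrix(tree)
    order = [recovered.labels.index(l) for l in dm.labels]
    assert np.allclose(recovered.matrix[np.ix_(order, order)], dm.matrix, atol=1e-9)


def test_nj_too_few():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


def _all_unrooted_topologies(labels):
    """Enumerate all unrooted binary topologies by sequential insertion."""
    base = Node(children=[Node(labels[0]), Node(labels[1]), Node(labels[2])])
    trees = [base]
    for label in labels[3:]:
        grown = []
        for t in trees:
            edges = [n for n in t.postorder() if not n.is_root]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.postorder() if not n.is_root]
                child = edges2[k]
                parent = child.parent
                idx = parent.children.index(child)
                mid = Node(children=[child, Node(label)])
                parent.children[idx] = mid
                mid.parent = parent
                grown.append(t2)
        trees = grown
    return trees


def _ls_error(topology, dm):
    """Least-squares branch-length fit of a topology to a distance matrix."""
    leaves = {l.label: l for l in topology.leaves()}
    branches = [n for n in topology.postorder() if not n.is_root]
    pos = {id(n): i for i, n in enumerate(branches)}
    rows, y = [], []
    for a, b in itertools.combinations(dm.labels, 2):
        row = np.zeros(len(branches))
        anc = {}
        n = leaves[a]
        while n is not None:
            anc[id(n)] = True
            n = n.parent
        n = leaves[b]
        path_b = []
        while id(n) not in anc:
            path_b.append(n)
            n = n.parent
        meet = n
        n = leaves[a]
        while n is not meet:
            row[pos[id(n)]] = 1
            n = n.parent
        for node in path_b:
            row[pos[id(node)]] = 1
        rows.append(row)
        y.append(dm.matrix[dm.labels.index(a), dm.labels.index(b)])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    return float(np.sum((A @ sol - np.array(y)) ** 2))


@pytest.mark.parametrize("n_leaves,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
def test_nj_recovers_additive_topology_brute_force(n_leaves, seed):
    rng = np.random.default_rng(seed)
    labels = [f"T{i}" for i in range(n_leaves)]
    # random binary tree with positive lengths
    nodes = [Node(l, length=float(rng.uniform(0.5, 3))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = Node(length=float(rng.uniform(0.5, 3)))
        p.add_child(nodes[i])
        p.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [p]
    dm = _additive_matrix(nodes[0])
    nj = nj_tree(dm)
    # brute-force oracle: topology with minimal least-squares error
    best = min(_all_unrooted_topologies(labels), key=lambda t: _ls_error(t, dm))
    assert set(map(frozenset, _splits(nj))) == set(map(frozenset, _splits(best)))


# ----------------------------------------------------------------------
# Bootstrap

def _signal_alignment(rng, n_cols=120):
    # two clean clades
    a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_cols))
    b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_cols))
    def mutate(s, k):
        s = list(s)
        idx = rng.choice(n_cols, size=k, replace=False)
        for i in idx:
            s[i] = rng.choice([c for c in "ACDEFGHIKL" if c != s[i]])
        return "".join(s)
    return MultipleAlignment(
        [("a1", mutate(a, 3)), ("a2", mutate(a, 3)), ("b1", mutate(b, 3)), ("b2", mutate(b, 3)),
         ("c1", mutate(mutate(a, 40), 3)), ("c2", mutate(mutate(b, 40), 3))]
    )


def test_bootstrap_strong_signal(rng):
    a = _signal_alignment(rng)
    tree = bootstrap_support(a, n_replicates=100, seed=7)
    supports = [n.support for n in tree.postorder() if not (n.is_leaf or n.is_root)]
    assert supports and all(s >= 90 for s in supports)


def test_bootstrap_single_replicate(rng):
    a = _signal_alignment(rng)
    tree = bootstrap_support(a, n_replicates=1, seed=3)
    supports = {n.support for n in tree.postorder() if not (n.is_leaf or n.is_root)}
    assert supports <= {0.0, 100.0}


def test_bootstrap_deterministic(rng):
    a = _signal_alignment(rng)
    t1 = bootstrap_support(a, n_replicates=25, seed=11)
    t2 = bootstrap_support(a, n_replicates=25, seed=11)
    assert t1.to_newick() == t2.to_newick()


def test_bootstrap_row_order_invariance(rng):
    a = _signal_alignment(rng)
    shuffled = MultipleAlignment(list(reversed(a.records)), a.alphabet)
    t1 = bootstrap_support(a, n_replicates=25, seed=5)
    t2 = bootstrap_support(shuffled, n_replicates=25, seed=5)
    s1 = {frozenset(s): n.support for s, n in
          ((frozenset(x.leaf_labels()), x) for x in t1.postorder() if not (x.is_leaf or x.is_root))}
    s2 = {frozenset(s): n.support for s, n in
          ((frozenset(x.leaf_labels()), x) for x in t2.postorder() if not (x.is_leaf or x.is_root))}
    assert s1 == s2


def test_bootstrap_requires_rows(rng):
    a = aln("MKV", "MKL")
    with pytest.raises(ValueError):
        bootstrap_support(a, 10, 1)
    with pytest.raises(ValueError):
        bootstrap_support(_signal_alignment(rng), 0, 1)


# ----------------------------------------------------------------------
# Rooting

def test_root_by_outgroup_simple():
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = root_by_outgroup(tree, ["D"])
    assert len(rooted.children) == 2
    sides = [set(c.leaf_labels()) for c in rooted.children]
    assert {"D"} in sides


def test_root_by_outgroup_all_leaves_error():
    tree = parse_newick("((A:1,B:1):1,C:1);")
    with pytest.raises(ValueError):
        root_by_outgroup(tree, ["A", "B", "C"])


def test_root_by_outgroup_non_monophyletic():
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(ValueError, match="monophyletic"):
        root_by_outgroup(tree, ["A", "C"])


def test_root_brassicaceae_fixture_separates_clades():
    from genefam.events import leaf_classes
    from genefam.synthetic import make_fixture

    bundle = make_fixture("brassicaceae_like", seed=2)
    og = [l for l in bundle.gene_tree.leaf_labels() if l.startswith("Tarenaya_like|")]
    rooted = root_by_outgroup(bundle.gene_tree, og)
    ingroup = next(c for c in rooted.children if set(c.leaf_labels()) != set(og))
    classes = leaf_classes(bundle.gene_tree)
    sides = [{classes[l] for l in child.leaf_labels()} for child in ingroup.children]
    assert {"FLC_sstr"} in sides
    other = next(s for s in sides if s != {"FLC_sstr"})
    assert "FLC_sstr" not in other
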