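import itertools

import numpy as np
import pytest
from scipy.stats import chi2

from genefam.gene_tree import MultipleAlignment
from genefam.selection import (
    CODONS,
    CODON_INDEX,
    N_CODONS,
    BranchModelFit,
    CodonModelParams,
    build_rate_matrix,
    chi2_pvalue,
    encode_codon_alignment,
    estimate_f3x4,
    fit_model,
    log_likelihood,
    lrt,
    selection_table,
    transition_probs,
    uniform_pi,
)
from genefam.synthetic import evolve_codon_sequences
from genefam.tree import parse_newick


PI = uniform_pi()


# ----------------------------------------------------------------------
# Rate matrix

def test_rate_ratio_transition_vs_nonsyn_transversion():
    q = build_rate_matrix(2.0, 0.5, PI)
    # TTT->TTC synonymous transition (Phe), TTT->TTA nonsynonymous
    # transversion (Phe->Leu): ratio kappa/omega = 4
    r1 = q[CODON_INDEX["TTT"], CODON_INDEX["TTC"]]
    r2 = q[CODON_INDEX["TTT"], CODON_INDEX["TTA"]]
    assert r1 / r2 == pytest.approx(2.0 / 0.5)


def test_rate_zero_for_multiple_differences():
    q = build_rate_matrix(2.0, 0.5, PI)
    assert q[CODON_INDEX["TTT"], CODON_INDEX["GGG"]] == 0.0


def test_detailed_balance():
    rng = np.random.default_rng(0)
    pi = rng.dirichlet(np.ones(N_CODONS))
    q = build_rate_matrix(3.1, 0.7, pi)
    flux = pi[:, None] * q
    assert np.allclose(flux, flux.T, atol=1e-14)


def test_rate_matrix_scaling_and_rowsums():
    rng = np.random.default_rng(1)
    pi = rng.dirichlet(np.ones(N_CODONS))
    q = build_rate_matrix(1.5, 0.3, pi)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
    assert -float(np.dot(pi, np.diag(q))) == pytest.approx(1.0)


def test_rate_matrix_rejects_bad_pi():
    with pytest.raises(ValueError):
        build_rate_matrix(2.0, 0.5, np.ones(64) / 64)


# ----------------------------------------------------------------------
# Transition probabilities

def test_transition_probs_identity_at_zero():
    q = build_rate_matrix(2.0, 0.5, PI)
    assert np.allclose(transition_probs(q, 0.0), np.eye(N_CODONS), atol=1e-10)


def test_transition_probs_ergodic_limit():
    rng = np.random.default_rng(2)
    pi = rng.dirichlet(np.ones(N_CODONS) * 5)
    q = build_rate_matrix(2.0, 0.5, pi)
    p = transition_probs(q, 50.0)
    assert np.allclose(p, np.tile(pi, (N_CODONS, 1)), atol=1e-5)


def test_transition_probs_semigroup():
    q = build_rate_matrix(2.0, 0.5, PI)
    p = transition_probs
    assert np.allclose(p(q, 0.9), p(q, 0.4) @ p(q, 0.5), atol=1e-8)
    assert np.allclose(p(q, 0.9).sum(axis=1), 1.0, atol=1e-10)


def test_transition_probs_negative_time():
    q = build_rate_matrix(2.0, 0.5, PI)
    with pytest.raises(ValueError):
        transition_probs(q, -0.1)


# ----------------------------------------------------------------------
# F3x4

def test_f3x4_single_codon():
    aln = MultipleAlignment([("a", "AAA" * 200), ("b", "AAA" * 200)], "codon")
    pi = estimate_f3x4(aln)
    assert pi[CODON_INDEX["AAA"]] > 0.95
    assert pi.sum() == pytest.approx(1.0)


def test_f3x4_uniform_composition():
    # all four nucleotides equally often at every position
    s = "".join(CODONS) + "TAATAGTGA".replace("TAA", "").join([""])  # only sense codons
    rows = [("a", "".join(CODONS)), ("b", "".join(CODONS))]
    pi = estimate_f3x4(MultipleAlignment(rows, "codon"))
    # composition of the 61 sense codons is near-uniform per position;
    # resulting pi is close to uniform over sense codons
    assert pi.sum() == pytest.approx(1.0)
    assert pi.max() / pi.min() < 2.0


def test_f3x4_exact_arithmetic():
    # hand-computable: sequences use A and C at every position equally
    rows = [("a", "AAACCC"), ("b", "CCCAAA")]
    pi = estimate_f3x4(MultipleAlignment(rows, "codon"), pseudocount=0.0)
    # each position: A 1/2, C 1/2; codons over {A,C}^3 each get (1/2)^3,
    # none are stops, so 8 codons at 1/8 after renormalisation
    nonzero = pi[pi > 0]
    assert len(nonzero) == 8
    assert np.allclose(nonzero, 1 / 8)


def test_f3x4_sums_to_one_random(rng):
    seqs = ["".join(rng.choice(CODONS, size=30)) for _ in range(4)]
    pi = estimate_f3x4(MultipleAlignment([(f"s{i}", s) for i, s in enumerate(seqs)], "codon"))
    assert pi.sum() == pytest.approx(1.0)
    assert (pi > 0).all()


# ----------------------------------------------------------------------
# Likelihood

def params(kappa=2.0, omega=0.5, pi=None, classes=("background",)):
    return CodonModelParams(kappa, {c: omega for c in classes}, PI if pi is None else pi)


def test_lnl_degenerate_identical_pair():
    codon = "ATG"
    aln = MultipleAlignment([("A|x", codon), ("B|y", codon)], "codon")
    tree = parse_newick("(A|x:0,B|y:0);")
    lnl = log_likelihood(aln, tree, params())
    assert lnl == pytest.approx(np.log(PI[CODON_INDEX[codon]]))


def _brute_force_lnl(aln, tree, p):
    """Sum over all internal-state assignments, per site."""
    ids, mat = encode_codon_alignment(aln)
    row = {rid: r for r, rid in enumerate(ids)}
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    pmat = {}
    for n in nodes:
        if n.is_root:
            continue
        q = build_rate_matrix(p.kappa, p.omega_by_class[n.clade_class or "background"], p.pi)
        pmat[id(n)] = transition_probs(q, n.length or 0.0)
    total = 0.0
    for site in range(mat.shape[1]):
        site_lik = 0.0
        for combo in itertools.product(range(N_CODONS), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, combo)}
            for n in nodes:
                if n.is_leaf:
                    state[id(n)] = mat[row[n.label], site]
            term = p.pi[state[id(tree)]]
            for n in nodes:
                if n.is_root:
                    continue
                s = state[id(n)]
                if s < 0:
                    continue  # missing data: sum over leaf state = 1
                term *= pmat[id(n)][state[id(n.parent)], s]
            site_lik += term
        total += np.log(site_lik)
    return total


def test_lnl_matches_brute_force_three_taxa():
    rng = np.random.default_rng(3)
    tree = parse_newick("((A|a:0.2,B|b:0.4):0.1,C|c:0.3);")
    seqs = ["".join(rng.choice(CODONS, size=2)) for _ in range(3)]
    aln = MultipleAlignment([("A|a", seqs[0]), ("B|b", seqs[1]), ("C|c", seqs[2])], "codon")
    p = params()
    assert log_likelihood(aln, tree, p) == pytest.approx(_brute_force_lnl(aln, tree, p))


@pytest.mark.parametrize("seed", [0, 1])
def test_lnl_matches_brute_force_four_taxa_with_gap(seed):
    rng = np.random.default_rng(seed)
    tree = parse_newick("((A|a:0.15,B|b:0.3):0.2,(C|c:0.25,D|d:0.1):0.05);")
    seqs = ["".join(rng.choice(CODONS, size=2)) for _ in range(4)]
    seqs[1] = "---" + seqs[1][3:]  # gap = missing data
    aln = MultipleAlignment(
        [("A|a", seqs[0]), ("B|b", seqs[1]), ("C|c", seqs[2]), ("D|d", seqs[3])], "codon"
    )
    p = params(kappa=1.7, omega=0.9)
    assert log_likelihood(aln, tree, p) == pytest.approx(_brute_force_lnl(aln, tree, p))


def test_lnl_doubled_alignment():
    rng = np.random.default_rng(4)
    tree = parse_newick("((A|a:0.2,B|b:0.4):0.1,C|c:0.3);")
    seqs = ["".join(rng.choice(CODONS, size=5)) for _ in range(3)]
    aln1 = MultipleAlignment(list(zip(["A|a", "B|b", "C|c"], seqs)), "codon")
    aln2 = MultipleAlignment([(i, s + s) for i, s in zip(["A|a", "B|b", "C|c"], seqs)], "codon")
    p = params()
    assert log_likelihood(aln2, tree, p) == pytest.approx(2 * log_likelihood(aln1, tree, p))


def test_lnl_row_permutation_invariance():
    rng = np.random.default_rng(5)
    tree = parse_newick("((A|a:0.2,B|b:0.4):0.1,(C|c:0.3,D|d:0.2):0.2);")
    rows = [(l, "".join(rng.choice(CODONS, size=20))) for l in ["A|a", "B|b", "C|c", "D|d"]]
    p = params()
    a = log_likelihood(MultipleAlignment(rows, "codon"), tree, p)
    b = log_likelihood(MultipleAlignment(rows[::-1], "codon"), tree, p)
    assert a == pytest.approx(b)


def test_lnl_id_mismatch():
    tree = parse_newick("(A|a:0.1,B|b:0.1);")
    aln = MultipleAlignment([("A|a", "ATG"), ("X|x", "ATG")], "codon")
    with pytest.raises(ValueError, match="X|x"):
        log_likelihood(aln, tree, params())


def test_mb_with_equal_omegas_reproduces_m0():
    rng = np.random.default_rng(6)
    tree = parse_newick(
        "((A|a#FLC_sstr:0.2,B|b#FLC_sstr:0.4)#FLC_sstr:0.1,(C|c:0.3,D|d:0.2):0.2);"
    )
    rows = [(l, "".join(rng.choice(CODONS, size=30))) for l in ["A|a", "B|b", "C|c", "D|d"]]
    aln = MultipleAlignment(rows, "codon")
    m0 = CodonModelParams(2.0, {"background": 0.4, "FLC_sstr": 0.4}, PI)
    mb_equal = CodonModelParams(2.0, {"background": 0.4, "FLC_sstr": 0.4}, PI)
    assert log_likelihood(aln, tree, m0) == pytest.approx(
        log_likelihood(aln, tree, mb_equal), abs=1e-6
    )


# ----------------------------------------------------------------------
# Fitting

def test_fit_all_synonymous_pair_drives_omega_down():
    # two sequences differing only by synonymous changes
    s1 = "TTT CTT ATT GTT TCT CCT ACT GCT TAT CAT AAT GAT".replace(" ", "") * 3
    s2 = "TTC CTC ATC GTC TCC CCC ACC GCC TAC CAC AAC GAC".replace(" ", "") * 3
    aln = MultipleAlignment([("A|a", s1), ("B|b", s2)], "codon")
    tree = parse_newick("(A|a:0.2,B|b:0.2);")
    fit = fit_model(aln, tree, model="M0", starts=(1.0,))
    assert fit.params.omega_by_class["all"] < 0.02


def test_fit_mb_nests_m0():
    tree = parse_newick(
        "((A|a#FLC_sstr:0.3,B|b#FLC_sstr:0.3)#FLC_sstr:0.2,(C|c:0.3,D|d:0.3):0.2);"
    )
    aln = evolve_codon_sequences(tree, 2.0, {"background": 0.4, "FLC_sstr": 0.4}, None, 150, seed=8)
    m0 = fit_model(aln, tree, model="M0", starts=(0.5, 1.0))
    mb = fit_model(aln, tree, model="Mb", starts=(0.5, 1.0))
    assert mb.lnl >= m0.lnl - 1e-6
    assert mb.np_ - m0.np_ == 1  # only two classes on this tree
    omegas = list(mb.params.omega_by_class.values())
    assert abs(omegas[0] - omegas[1]) < 0.25  # generated under equal omegas


def test_lrt_paper_arithmetic():
    assert round(chi2_pvalue(24.03, 3), 6) == 0.000025


def test_lrt_from_lnl_pair():
    null = BranchModelFit("M0", -19_989.78, 292, params(), True, 3)
    alt = BranchModelFit("Mb", -19_965.76, 295, params(), True, 3)
    res = lrt(null, alt)
    assert res.stat == pytest.approx(48.04, abs=1e-6)
    assert res.df == 3
    assert res.p == pytest.approx(2.1e-10, rel=0.05)


def test_lrt_identical_fits():
    a = BranchModelFit("M0", -100.0, 10, params(), True, 3)
    b = BranchModelFit("Mb", -100.0, 13, params(), True, 3)
    res = lrt(a, b)
    assert res.stat == 0.0 and res.p == 1.0


def test_lrt_np_order_enforced():
    a = BranchModelFit("M0", -100.0, 13, params(), True, 3)
    b = BranchModelFit("Mb", -99.0, 13, params(), True, 3)
    with pytest.raises(ValueError):
        lrt(a, b)


def test_selection_table_shape():
    null = BranchModelFit("M0", -200.0, 20, params(classes=("all",)), True, 3)
    alt = BranchModelFit(
        "Mb", -195.0, 23,
        CodonModelParams(2.0, {"background": 0.3, "MAF45": 0.4, "MAF123": 0.35,
                               "FLC_sstr": 0.2}, PI),
        True, 3,
    )
    table = selection_table(null, alt)
    assert list(table["model"]) == ["M0", "Mb"]
    assert table.loc[0, "dnp"] == 3
    assert table.loc[1, "omega3"] == 0.2
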