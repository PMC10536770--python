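"""Codon substitution branch models and the likelihood-ratio test.

Implements a Goldman–Yang-style codon model: single-nucleotide codon
exchanges with transition/transversion bias ``kappa``, target-codon
frequencies ``pi`` and a nonsynonymous/synonymous rate ratio ``omega``
that may differ between branch classes.  The one-ratio model ``M0`` and
the branch model ``Mb`` are fitted by maximum likelihood (Felsenstein
pruning, multi-start bounded quasi-Newton) and compared with a
chi-square likelihood-ratio test.

Branch classes are carried on the gene tree as ``Node.clade_class``
(``None`` means ``"background"``); in newick text they are written as a
``#classname`` suffix on the branch's child node label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize
from scipy.stats import chi2

from .io import CODON_TO_AA, STOP_CODONS
from .tree import Node

# ----------------------------------------------------------------------
# Codon space

_NT = "TCAG"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}
ALL_CODONS = [a + b + c for a in _NT for b in _NT for c in _NT]
CODONS: list[str] = [c for c in ALL_CODONS if c not in STOP_CODONS]
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_AA = [CODON_TO_AA[c] for c in CODONS]

_PURINES = frozenset("AG")


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    one_diff = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            one_diff[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = _AA[i] != _AA[j]
    return one_diff, transition, nonsyn


_ONE_DIFF, _TRANSITION, _NONSYN = _pair_tables()


# ----------------------------------------------------------------------
# Parameters and results

@dataclass
class CodonModelParams:
    """Parameter set of the codon branch model."""

    kappa: float
    omega_by_class: dict[str, float]
    pi: np.ndarray
    branch_lengths: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries, got {self.pi.shape}")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-6):
            raise ValueError("pi must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for cls, w in self.omega_by_class.items():
            if w <= 0:
                raise ValueError(f"omega for class {cls!r} must be positive")


@dataclass
class BranchModelFit:
    model: str
    lnl: float
    np_: int
    params: CodonModelParams
    converged: bool
    n_starts_agreeing: int
    tree: Optional[Node] = None
    start_lnls: list[float] = field(default_factory=list)


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


# ----------------------------------------------------------------------
# Rate matrix and transition probabilities

def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94-style 61x61 generator, scaled to one expected substitution
    per codon per unit time at stationarity."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"pi must have {N_CODONS} entries (sense codons only)")
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    q = np.where(_ONE_DIFF, pi[None, :], 0.0)
    q = q * np.where(_TRANSITION, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(q)))
    if mu <= 0:
        raise ValueError("degenerate rate matrix (check pi)")
    return q / mu


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector)."""
    w, v = np.linalg.eig(q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


class SpectralGenerator:
    """Eigendecomposition of a reversible generator for fast ``expm``.

    Uses the similarity transform ``S = D^{1/2} Q D^{-1/2}`` (symmetric for
    reversible ``Q``), so ``P(t)`` and ``Q P(t)`` are two dense matmuls.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray) -> None:
        d = np.sqrt(pi)
        s = q * d[:, None] / d[None, :]
        s = 0.5 * (s + s.T)
        self.evals, self.evecs = eigh(s)
        self._left = self.evecs / d[:, None]
        self._right = self.evecs.T * d[None, :]

    def probs(self, t: float) -> np.ndarray:
        p = (self._left * np.exp(self.evals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def probs_and_dt(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        e = np.exp(self.evals * t)
        p = (self._left * e) @ self._right
        dp = (self._left * (self.evals * e)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p, dp


def transition_probs(q: np.ndarray, t: float) -> np.ndarray:
    """``P(t) = expm(Q t)`` for a reversible generator ``q``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    pi = stationary_distribution(q)
    return SpectralGenerator(q, pi).probs(t)


# ----------------------------------------------------------------------
# Codon frequencies

_AMBIG_OK = frozenset("ACGT")


def _aligned_rows(alignment) -> list[tuple[str, str]]:
    """Accept a MultipleAlignment, a list of SequenceRecords, or a list of
    (id, seq) pairs."""
    if hasattr(alignment, "records"):
        alignment = alignment.records
    rows = []
    for item in alignment:
        if hasattr(item, "id"):
            rows.append((item.id, item.seq))
        else:
            rid, seq = item
            rows.append((rid, seq))
    return rows


def estimate_f3x4(alignment, pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies: per-codon-position nucleotide frequencies,
    multiplied across positions, stop codons removed, renormalised."""
    rows = _aligned_rows(alignment)
    if not rows:
        raise ValueError("empty alignment")
    counts = np.full((3, 4), pseudocount, dtype=float)
    for _, seq in rows:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            raise ValueError("codon alignment length must be a multiple of 3")
        for k in range(0, len(seq), 3):
            codon = seq[k : k + 3]
            if "-" in codon:
                continue
            for pos, nt in enumerate(codon):
                if nt in _AMBIG_OK:
                    counts[pos, _NT_INDEX[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, _NT_INDEX[c[0]]] * freqs[1, _NT_INDEX[c[1]]] * freqs[2, _NT_INDEX[c[2]]]
         for c in CODONS]
    )
    return pi / pi.sum()


def uniform_pi() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def encode_codon_alignment(alignment) -> tuple[list[str], np.ndarray]:
    """Encode aligned CDS rows as codon-state indices; gaps and codons with
    ambiguous nucleotides become -1 (missing data)."""
    rows = _aligned_rows(alignment)
    ids = [rid for rid, _ in rows]
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError("codon alignment length must be a multiple of 3")
    n_sites = length // 3
    mat = np.full((len(rows), n_sites), -1, dtype=np.int32)
    for r, (rid, seq) in enumerate(rows):
        seq = seq.upper()
        for k in range(n_sites):
            codon = seq[3 * k : 3 * k + 3]
            idx = CODON_INDEX.get(codon, -1)
            if idx < 0 and "-" not in codon and codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} in sequence {rid!r} at codon {k}")
            mat[r, k] = idx
    return ids, mat


# ----------------------------------------------------------------------
# Likelihood engine

class _Engine:
    """Pruning likelihood over codon site patterns with analytic
    branch-length gradients.

    The input tree may be rooted (degree-2 root) or already unrooted
    (degree-3 root); a degree-2 root whose two child edges share a branch
    class is collapsed so that every remaining branch length is
    identifiable.
    """

    def __init__(self, alignment, tree: Node) -> None:
        ids, mat = encode_codon_alignment(alignment)
        self.tree = tree.copy()
        if len(self.tree.children) == 2:
            c0, c1 = self.tree.children
            if (c0.clade_class or "background") == (c1.clade_class or "background") and not (
                c0.is_leaf and c1.is_leaf
            ):
                # merge the two root edges into one
                inner = c1 if not c1.is_leaf else c0
                outer = c0 if inner is c1 else c1
                merged = (c0.length or 0.0) + (c1.length or 0.0)
                self.tree.remove_child(inner)
                for gc in list(inner.children):
                    inner.remove_child(gc)
                    self.tree.add_child(gc)
                outer.length = merged
        leaf_labels = set(self.tree.leaf_labels())
        missing = leaf_labels.symmetric_difference(ids)
        if missing:
            raise ValueError(f"alignment/tree id mismatch: {sorted(missing)}")
        row_of = {rid: r for r, rid in enumerate(ids)}

        # unique site patterns
        patterns, self.weights = np.unique(mat, axis=1, return_counts=True)
        self.n_patterns = patterns.shape[1]

        self.nodes = list(self.tree.postorder())
        self.branch_nodes = [n for n in self.nodes if not n.is_root]
        self.branch_classes = [n.clade_class or "background" for n in self.branch_nodes]
        self.n_branches = len(self.branch_nodes)

        self.leaf_onehot: dict[int, np.ndarray] = {}
        for n in self.nodes:
            if n.is_leaf:
                states = patterns[row_of[n.label]]
                oh = np.zeros((self.n_patterns, N_CODONS))
                known = states >= 0
                oh[known, states[known]] = 1.0
                oh[~known, :] = 1.0
                self.leaf_onehot[id(n)] = oh

    def initial_lengths(self) -> np.ndarray:
        return np.full(self.n_branches, 0.2)

    def _spectra(self, kappa: float, omega_by_class: dict[str, float], pi: np.ndarray):
        spectra = {}
        for node in self.branch_nodes:
            cls = node.clade_class or "background"
            if cls not in omega_by_class:
                raise ValueError(f"branch class {cls!r} (node {node.label!r}) has no omega")
            if cls not in spectra:
                q = build_rate_matrix(kappa, omega_by_class[cls], pi)
                spectra[cls] = SpectralGenerator(q, pi)
        return spectra

    def lnl(
        self,
        lengths: np.ndarray,
        kappa: float,
        omega_by_class: dict[str, float],
        pi: np.ndarray,
        grad: bool = False,
    ):
        spectra = self._spectra(kappa, omega_by_class, pi)
        P: dict[int, np.ndarray] = {}
        dP: dict[int, np.ndarray] = {}
        for node, t in zip(self.branch_nodes, lengths):
            spec = spectra[node.clade_class or "background"]
            if grad:
                P[id(node)], dP[id(node)] = spec.probs_and_dt(t)
            else:
                P[id(node)] = spec.probs(t)

        B: dict[int, np.ndarray] = {}
        M: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for node in self.nodes:
            if node.is_leaf:
                b = self.leaf_onehot[id(node)]
            else:
                b = np.ones((self.n_patterns, N_CODONS))
                for c in node.children:
                    b = b * M[id(c)]
                mx = b.max(axis=1)
                mx[mx == 0.0] = 1.0
                b = b / mx[:, None]
                logscale += np.log(mx)
            B[id(node)] = b
            if not node.is_root:
                M[id(node)] = b @ P[id(node)].T

        # floor avoids -inf at extreme trial points, which stalls L-BFGS-B
        root_site = np.maximum(B[id(self.tree)] @ pi, 1e-290)
        lnl = float(np.dot(self.weights, np.log(root_site) + logscale))
        if not grad:
            return lnl

        # up pass: outside partials and per-branch derivatives
        grads = np.zeros(self.n_branches)
        branch_pos = {id(n): i for i, n in enumerate(self.branch_nodes)}
        A: dict[int, np.ndarray] = {id(self.tree): np.tile(pi, (self.n_patterns, 1))}
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            a = A[id(node)]
            kids = node.children
            msgs = [M[id(c)] for c in kids]
            for i, c in enumerate(kids):
                e = a.copy()
                for j, m in enumerate(msgs):
                    if j != i:
                        e = e * m
                den = np.maximum(np.einsum("ps,ps->p", e, msgs[i]), 1e-290)
                dm = B[id(c)] @ dP[id(c)].T
                num = np.einsum("ps,ps->p", e, dm)
                grads[branch_pos[id(c)]] = float(np.dot(self.weights, num / den))
                if not c.is_leaf:
                    a_c = e @ P[id(c)]
                    mx = a_c.max(axis=1)
                    mx[mx == 0.0] = 1.0
                    A[id(c)] = a_c / mx[:, None]
        return lnl, grads

    def fitted_tree(self, lengths: np.ndarray) -> Node:
        out = self.tree.copy()
        for node, t in zip((n for n in out.postorder() if not n.is_root), lengths):
            node.length = float(t)
        return out


def log_likelihood(alignment, tree: Node, params: CodonModelParams) -> float:
    """Pruning log likelihood of a codon alignment on a classed tree,
    using the branch lengths stored on the tree."""
    engine = _Engine(alignment, tree)
    lengths = np.array([max(n.length or 0.0, 0.0) for n in engine.branch_nodes])
    return engine.lnl(lengths, params.kappa, params.omega_by_class, params.pi)


# ----------------------------------------------------------------------
# Model fitting

_KAPPA_BOUNDS = (0.01, 20.0)
_OMEGA_BOUNDS = (1e-4, 20.0)
_LENGTH_BOUNDS = (1e-6, 10.0)
M0_CLASS = "all"
MB_CLASSES = ("background", "MAF45", "MAF123", "FLC_sstr")


def _model_classes(model: str, engine: _Engine) -> list[str]:
    if model == "M0":
        return [M0_CLASS]
    if model == "Mb":
        present = sorted(set(engine.branch_classes))
        # keep canonical ordering for reporting
        ordered = [c for c in MB_CLASSES if c in present]
        ordered += [c for c in present if c not in ordered]
        return ordered
    raise ValueError(f"unknown model {model!r}; expected 'M0' or 'Mb'")


def fit_model(
    alignment,
    tree: Node,
    model: str = "M0",
    starts: Sequence[float] = (0.5, 1.0, 2.0),
    pi: Optional[np.ndarray] = None,
    max_cycles: int = 200,
    agree_tol: float = 1e-3,
) -> BranchModelFit:
    """Maximum-likelihood fit of M0 or Mb with free branch lengths.

    Each start value seeds every omega class; the best of all starts is
    returned, and convergence requires at least two starts to agree
    within ``agree_tol`` log-likelihood units (single-start fits rely on
    the optimizer's own status).
    """
    engine = _Engine(alignment, tree)
    if pi is None:
        pi = estimate_f3x4(alignment)
    classes = _model_classes(model, engine)
    n_classes = len(classes)
    n_b = engine.n_branches

    # all parameters are optimised on the log scale: multiplicative steps
    # keep the line search well conditioned near the t -> 0 boundary
    def unpack(y: np.ndarray):
        x = np.exp(y)
        lengths = x[:n_b]
        kappa = x[n_b]
        if model == "M0":
            omega_map = {cls: x[n_b + 1] for cls in set(engine.branch_classes) | {M0_CLASS}}
        else:
            omega_map = {cls: x[n_b + 1 + i] for i, cls in enumerate(classes)}
        return lengths, kappa, omega_map

    def objective(y: np.ndarray):
        lengths, kappa, omega_map = unpack(y)
        lnl, tgrads = engine.lnl(lengths, kappa, omega_map, pi, grad=True)
        g = np.zeros_like(y)
        g[:n_b] = tgrads * lengths  # chain rule for the log transform
        # forward differences (in log space) for kappa and the omegas
        for k in range(n_b, len(y)):
            h = 1e-5
            yp = y.copy()
            yp[k] += h
            l2, k2, o2 = unpack(yp)
            g[k] = (engine.lnl(l2, k2, o2, pi) - lnl) / h
        return -lnl, -g

    bounds = (
        [tuple(np.log(_LENGTH_BOUNDS))] * n_b
        + [tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_OMEGA_BOUNDS))] * n_classes
    )
    results = []
    for w0 in starts:
        y0 = np.log(np.concatenate([engine.initial_lengths(), [2.0], np.full(n_classes, w0)]))
        res = minimize(
            objective,
            y0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_cycles * 5, "ftol": 1e-11, "gtol": 1e-6},
        )
        results.append(res)

    best = max(results, key=lambda r: -r.fun)
    start_lnls = [-r.fun for r in results]
    n_agree = sum(1 for v in start_lnls if abs(v - (-best.fun)) <= agree_tol)
    converged = n_agree >= 2 if len(starts) >= 2 else bool(best.success)
    lengths, kappa, omega_map = unpack(best.x)
    if model == "M0":
        omega_report = {M0_CLASS: omega_map[M0_CLASS]}
    else:
        omega_report = {cls: omega_map[cls] for cls in classes}
    fitted = engine.fitted_tree(lengths)
    blen = {
        (n.label or f"node{i}"): float(t)
        for i, (n, t) in enumerate(zip(engine.branch_nodes, lengths))
    }
    np_ = n_b + 1 + n_classes + 9  # branch lengths + kappa + omegas + F3x4
    return BranchModelFit(
        model=model,
        lnl=-float(best.fun),
        np_=np_,
        params=CodonModelParams(kappa=float(kappa), omega_by_class=omega_report,
                                pi=pi, branch_lengths=blen),
        converged=converged,
        n_starts_agreeing=n_agree,
        tree=fitted,
        start_lnls=start_lnls,
    )


def lrt(fit_null: BranchModelFit, fit_alt: BranchModelFit) -> LRTResult:
    """Chi-square likelihood-ratio test of two nested fits."""
    if fit_alt.np_ <= fit_null.np_:
        raise ValueError(
            f"alternative model must have more parameters "
            f"({fit_alt.np_} <= {fit_null.np_})"
        )
    stat = 2.0 * (fit_alt.lnl - fit_null.lnl)
    if stat < 0:
        if stat < -1e-6:
            warnings.warn(f"negative LRT statistic {stat:.3g} clamped to 0")
        stat = 0.0
    df = fit_alt.np_ - fit_null.np_
    return LRTResult(stat=stat, df=df, p=float(chi2.sf(stat, df)))


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability (the LRT reference distribution)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.sf(stat, df))


# ----------------------------------------------------------------------
# Reporting

def selection_table(
    fit_null: BranchModelFit, fit_alt: Optional[BranchModelFit] = None
) -> "pandas.DataFrame":  # noqa: F821
    """Render fits in the standard selection-analysis column order."""
    import pandas as pd

    def row(fit: BranchModelFit, test: Optional[LRTResult]):
        om = fit.params.omega_by_class
        return {
            "model": fit.model,
            "lnL": fit.lnl,
            "np": fit.np_,
            "omega0": om.get(M0_CLASS, om.get("background")),
            "omega1": om.get("MAF45"),
            "omega2": om.get("MAF123"),
            "omega3": om.get("FLC_sstr"),
            "kappa": fit.params.kappa,
            "2dLnL": test.stat if test else None,
            "dnp": test.df if test else None,
            "p": test.p if test else None,
        }

    rows = [row(fit_null, None)]
    if fit_alt is not None:
        test = lrt(fit_null, fit_alt)
        rows[0].update({"2dLnL": test.stat, "dnp": test.df, "p": test.p})
        rows.append(row(fit_alt, None))
    return pd.DataFrame(rows)
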