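"""Goldman–Yang codon substitution model with branch-category dN/dS.

The model: codon substitution rates follow GY94,

    q_ij = 0                     (codons differing at >1 position)
    q_ij = pi_j                  (synonymous transversion)
    q_ij = kappa * pi_j          (synonymous transition)
    q_ij = omega * pi_j          (nonsynonymous transversion)
    q_ij = omega * kappa * pi_j  (nonsynonymous transition)

with equilibrium frequencies ``pi`` over the 61 sense codons (F3x4 by
default) and the generator scaled to one expected substitution per codon
per unit branch length.  Each branch belongs to a named category with
its own omega; likelihoods are computed by Felsenstein pruning with
ambiguous codons (gap, N, ``?``, stop) fully ambiguous over all 61
states.

The public surface follows the Model/Results convention:
:class:`CodonBranchModel` is built from a :class:`CodonAlignment` and a
:class:`LabeledTree`; ``fit`` returns :class:`BranchModelResults`
carrying ML estimates, the log-likelihood and a ``summary()`` table, and
nested fits are compared with :func:`lrt_neutral` (chi-square LRT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .alignment import CodonAlignment
from .codons import (
    N_STATES,
    NEIGHBOUR_MASK,
    NONSYN_MASK,
    SENSE_CODONS,
    TRANSITION_MASK,
)
from .trees import BACKGROUND, LabeledTree

OMEGA_BOUNDS = (1e-4, 10.0)
KAPPA_BOUNDS = (0.1, 20.0)
BRANCH_BOUNDS = (1e-6, 50.0)

_NT = "TCAG"


class CodonModelError(ValueError):
    pass


# ----------------------------------------------------------------------
# equilibrium frequencies and rate matrix
# ----------------------------------------------------------------------

def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 sense-codon frequencies from position-specific nucleotide counts.

    Counts unambiguous nucleotides at each of the three codon positions,
    forms each codon's frequency as the product of its positional
    nucleotide frequencies, removes the stop-codon mass and renormalizes
    over the 61 sense codons.
    """
    counts = np.zeros((3, 4))
    for seq in aln.seqs:
        s = seq.upper()
        for k in range(0, len(s) - len(s) % 3, 3):
            for p in range(3):
                b = s[k + p]
                if b in _NT:
                    counts[p, _NT.index(b)] += 1
    for p in range(3):
        if counts[p].sum() == 0:
            raise CodonModelError(f"codon position {p + 1} has no unambiguous bases")
    posfreq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            posfreq[0, _NT.index(c[0])] * posfreq[1, _NT.index(c[1])] * posfreq[2, _NT.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise CodonModelError("all sense-codon frequencies are zero")
    return pi / total


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray, scale: bool = True) -> np.ndarray:
    """61x61 GY94 generator; rows sum to zero.

    With ``scale=True`` the matrix is normalized so that
    ``sum_i pi_i * sum_{j != i} q_ij == 1`` (branch lengths are expected
    substitutions per codon).
    """
    if kappa <= 0 or omega < 0:
        raise CodonModelError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    Q = np.where(NEIGHBOUR_MASK, np.tile(pi, (N_STATES, 1)), 0.0)
    Q = Q * np.where(TRANSITION_MASK, kappa, 1.0)
    Q = Q * np.where(NONSYN_MASK, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -(pi * np.diag(Q)).sum()
        if mu > 0:
            Q = Q / mu
    return Q


class TransitionKernel:
    """Spectral form of a scaled GY94 generator for fast P(t).

    The reversible generator is symmetrized with ``diag(sqrt(pi))`` and
    eigendecomposed once; each ``P(t)`` is two 61x61 products.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        if np.any(self.pi <= 0):
            raise CodonModelError("codon frequencies must be strictly positive")
        self.Q = gy94_rate_matrix(kappa, omega, self.pi)
        d = np.sqrt(self.pi)
        A = (self.Q * d[:, None]) / d[None, :]
        A = 0.5 * (A + A.T)
        self.evals, U = linalg.eigh(A)
        self.left = U / d[:, None] * 1.0  # D^{-1/2} U
        self.right = (U * d[:, None]).T  # U^T D^{1/2}

    def probs(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.evals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


# ----------------------------------------------------------------------
# parameters / tree indexing
# ----------------------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameter set of the branch model.

    ``branch_lengths`` is ordered like the model's postorder branch list
    (expected substitutions per codon).
    """

    kappa: float
    omega_by_category: dict[str, float]
    codon_freqs: np.ndarray
    branch_lengths: np.ndarray

    def validate(self) -> None:
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise CodonModelError("codon frequencies must sum to 1")
        if self.kappa <= 0:
            raise CodonModelError("kappa must be positive")
        if any(w < 0 for w in self.omega_by_category.values()):
            raise CodonModelError("omega must be nonnegative")


class _TreeIndex:
    """Postorder array view of a labeled tree for pruning."""

    def __init__(self, ltree: LabeledTree, taxa: list[str]):
        nodes = list(ltree.tree.postorder_node_iter())
        self.nodes = nodes
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.index[id(ltree.tree.seed_node)]
        self.children: list[list[int]] = [[] for _ in nodes]
        self.parent = [-1] * len(nodes)
        self.length = np.zeros(len(nodes))
        self.category = [BACKGROUND] * len(nodes)
        self.leaf_row = [-1] * len(nodes)
        taxon_row = {t: i for i, t in enumerate(taxa)}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.length[i] = nd.edge.length if nd.edge.length is not None else 0.1
                self.category[i] = getattr(nd.edge, "category", BACKGROUND)
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in taxon_row:
                    raise CodonModelError(f"tree leaf {label!r} missing from alignment")
                self.leaf_row[i] = taxon_row[label]
        # branches = non-root nodes, in postorder
        self.branch_nodes = [i for i in range(len(nodes)) if i != self.root]

    def branch_categories(self) -> list[str]:
        cats: list[str] = []
        for i in self.branch_nodes:
            if self.category[i] not in cats:
                cats.append(self.category[i])
        return cats


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

def _pruning_loglike(
    states: np.ndarray,
    tindex: _TreeIndex,
    pi: np.ndarray,
    kappa: float,
    omega_by_category: dict[str, float],
    branch_lengths: np.ndarray,
    kernel_cache: dict | None = None,
) -> float:
    n_sites = states.shape[1]
    if kernel_cache is None:
        kernel_cache = {}

    def kernel(cat: str) -> TransitionKernel:
        key = (kappa, omega_by_category[cat])
        if key not in kernel_cache:
            if len(kernel_cache) > 512:
                kernel_cache.clear()
            kernel_cache[key] = TransitionKernel(kappa, omega_by_category[cat], pi)
        return kernel_cache[key]

    t_of = dict(zip(tindex.branch_nodes, branch_lengths))

    # single-node tree: root is the leaf
    if tindex.n_nodes == 1:
        x = states[tindex.leaf_row[tindex.root]]
        ll = 0.0
        for s in range(n_sites):
            ll += np.log(pi[x[s]]) if x[s] >= 0 else 0.0  # sum(pi) = 1
        return float(ll)

    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)
    for i, nd in enumerate(tindex.nodes):
        if not tindex.children[i]:
            continue
        M = np.ones((n_sites, N_STATES))
        for c in tindex.children[i]:
            P = kernel(tindex.category[c]).probs(t_of[c])
            if tindex.leaf_row[c] >= 0:
                x = states[tindex.leaf_row[c]]
                mask = x < 0
                contrib = P.T[np.where(mask, 0, x)]
                if mask.any():
                    contrib = contrib.copy()
                    contrib[mask] = 1.0
            else:
                contrib = partial.pop(c) @ P.T
            M *= contrib
        m = M.max(axis=1)
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            bad = int(np.argmin(m))
            raise CodonModelError(f"non-finite partial likelihood at site {bad}")
        M /= m[:, None]
        logscale += np.log(m)
        partial[i] = M
    site_l = partial[tindex.root] @ pi
    return float(np.sum(np.log(site_l)) + logscale.sum())


def log_likelihood(aln: CodonAlignment, tree: LabeledTree | str, params: CodonModelParams) -> float:
    """Pruning log-likelihood of a codon alignment under the branch model."""
    return CodonBranchModel(aln, tree, codon_freqs=params.codon_freqs).loglike(params)


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class CodonBranchModel:
    """GY94 branch-category dN/dS model bound to data.

    Parameters
    ----------
    alignment : CodonAlignment
        Codon alignment; every taxon must be a leaf of ``tree``.
    tree : LabeledTree or str
        Rooted tree with ``#category`` branch tags (untagged branches
        form the background category).
    codon_freqs : ndarray, optional
        61-vector of sense-codon frequencies; F3x4 from the alignment
        by default.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree | str,
        codon_freqs: np.ndarray | None = None,
    ):
        self.alignment = alignment
        self.tree = tree if isinstance(tree, LabeledTree) else LabeledTree.from_newick(tree)
        if set(alignment.taxa) != set(self.tree.taxa):
            missing = set(alignment.taxa) ^ set(self.tree.taxa)
            raise CodonModelError(f"alignment/tree taxa mismatch: {sorted(missing)}")
        self.codon_freqs = (
            np.asarray(codon_freqs, dtype=float)
            if codon_freqs is not None
            else f3x4_frequencies(alignment)
        )
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise CodonModelError("codon frequencies must sum to 1")
        self._states = alignment.codon_states()
        self._tindex = _TreeIndex(self.tree, alignment.taxa)
        self._kernels: dict = {}

    @classmethod
    def from_files(cls, alignment_fasta, tree_newick) -> "CodonBranchModel":
        from pathlib import Path

        return cls(
            CodonAlignment.from_fasta(alignment_fasta),
            LabeledTree.from_newick(Path(tree_newick).read_text()),
        )

    @property
    def categories(self) -> list[str]:
        return self._tindex.branch_categories()

    @property
    def n_branches(self) -> int:
        return len(self._tindex.branch_nodes)

    def initial_branch_lengths(self) -> np.ndarray:
        t0 = np.array([self._tindex.length[i] for i in self._tindex.branch_nodes])
        return np.clip(t0, *BRANCH_BOUNDS)

    def loglike(self, params: CodonModelParams) -> float:
        params.validate()
        missing = [c for c in self.categories if c not in params.omega_by_category]
        if missing:
            raise CodonModelError(f"no omega for categories {missing}")
        return _pruning_loglike(
            self._states,
            self._tindex,
            params.codon_freqs,
            params.kappa,
            params.omega_by_category,
            np.asarray(params.branch_lengths, dtype=float),
            self._kernels,
        )

    # -- fitting --------------------------------------------------------
    def fit(
        self,
        fixed_omegas: dict[str, float] | None = None,
        starts: tuple[float, ...] = (0.1, 1.0, 2.0),
        kappa_start: float = 2.0,
        maxiter: int = 400,
        tol: float = 1e-8,
    ) -> "BranchModelResults":
        """Maximize the likelihood over kappa, free category omegas and
        all branch lengths (bounded, log-parameterized L-BFGS-B).

        The deterministic ``starts`` seed the free omegas; the
        best-scoring start is polished to convergence.
        """
        fixed_omegas = dict(fixed_omegas or {})
        cats = self.categories
        unknown = set(fixed_omegas) - set(cats)
        if unknown:
            raise CodonModelError(f"fixed omegas for absent categories: {sorted(unknown)}")
        free = [c for c in cats if c not in fixed_omegas]
        nb = self.n_branches
        pi = self.codon_freqs
        t0 = self.initial_branch_lengths()

        def unpack(x: np.ndarray):
            t = np.exp(x[:nb])
            kappa = float(np.exp(x[nb]))
            omegas = dict(fixed_omegas)
            for k, c in enumerate(free):
                omegas[c] = float(np.exp(x[nb + 1 + k]))
            return t, kappa, omegas

        def neg_loglike(x: np.ndarray) -> float:
            t, kappa, omegas = unpack(x)
            try:
                return -_pruning_loglike(
                    self._states, self._tindex, pi, kappa, omegas, t, self._kernels
                )
            except CodonModelError:
                return 1e12

        lo = np.concatenate(
            [
                np.full(nb, np.log(BRANCH_BOUNDS[0])),
                [np.log(KAPPA_BOUNDS[0])],
                np.full(len(free), np.log(OMEGA_BOUNDS[0])),
            ]
        )
        hi = np.concatenate(
            [
                np.full(nb, np.log(BRANCH_BOUNDS[1])),
                [np.log(KAPPA_BOUNDS[1])],
                np.full(len(free), np.log(OMEGA_BOUNDS[1])),
            ]
        )
        bounds = list(zip(lo, hi))

        def make_x0(w0: float) -> np.ndarray:
            return np.concatenate(
                [np.log(t0), [np.log(kappa_start)], np.full(len(free), np.log(w0))]
            )

        x0s = [np.clip(make_x0(w), lo, hi) for w in starts] or [np.clip(make_x0(1.0), lo, hi)]
        best_x0 = min(x0s, key=neg_loglike) if len(x0s) > 1 and free else x0s[0]
        res = optimize.minimize(
            neg_loglike,
            best_x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        t_hat, kappa_hat, omegas_hat = unpack(res.x)
        params = CodonModelParams(
            kappa=kappa_hat,
            omega_by_category=omegas_hat,
            codon_freqs=pi,
            branch_lengths=t_hat,
        )
        return BranchModelResults(
            model=self,
            params=params,
            llf=-float(res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
            fixed_omegas=fixed_omegas,
        )

    def fit_two_ratio(self, focal: str, **kwargs) -> "TwoRatioTest":
        """Focal-category omega free vs fixed at 1 (all other branches
        share one background omega); chi-square LRT with df = 1."""
        two = collapse_to_two_categories(self.tree, focal)
        m = CodonBranchModel(self.alignment, two, codon_freqs=self.codon_freqs)
        alt = m.fit(**kwargs)
        null = m.fit_warm(alt, fixed_omegas={focal: 1.0}, **kwargs)
        return TwoRatioTest(focal=focal, alt=alt, null=null, lrt=lrt_neutral(alt, null))

    def fit_warm(self, warm: "BranchModelResults", fixed_omegas=None, **kwargs) -> "BranchModelResults":
        """Fit with branch lengths/kappa started from a previous fit."""
        t_saved = [self._tindex.length[i] for i in self._tindex.branch_nodes]
        for i, bi in enumerate(self._tindex.branch_nodes):
            self._tindex.length[bi] = warm.params.branch_lengths[i]
        try:
            return self.fit(
                fixed_omegas=fixed_omegas,
                starts=(max(min(np.mean(list(warm.params.omega_by_category.values())), 9.9), 1e-3),),
                kappa_start=warm.params.kappa,
                **{k: v for k, v in kwargs.items() if k not in ("starts", "kappa_start")},
            )
        finally:
            for bi, t in zip(self._tindex.branch_nodes, t_saved):
                self._tindex.length[bi] = t


@dataclass
class BranchModelResults:
    """ML fit of a :class:`CodonBranchModel`."""

    model: CodonBranchModel
    params: CodonModelParams
    llf: float
    converged: bool
    n_iter: int
    fixed_omegas: dict[str, float] = field(default_factory=dict)

    @property
    def n_free_params(self) -> int:
        n_free_omega = len(self.params.omega_by_category) - len(self.fixed_omegas)
        return self.model.n_branches + 1 + n_free_omega

    @property
    def tree_length(self) -> float:
        return float(np.sum(self.params.branch_lengths))

    def lrt_against(self, null: "BranchModelResults") -> "LRTResult":
        return lrt_neutral(self, null)

    def summary(self) -> str:
        lines = []
        lines.append("Codon branch model (GY94, branch-category dN/dS)")
        lines.append("=" * 58)
        lines.append(
            f"No. sequences: {self.model.alignment.n_taxa:>4}    "
            f"No. codon sites: {self.model.alignment.n_codons}"
        )
        lines.append(
            f"Log-likelihood: {self.llf:.4f}    converged: {self.converged}"
            f" ({self.n_iter} iter)"
        )
        lines.append(f"kappa (ts/tv): {self.params.kappa:.4f}    tree length: {self.tree_length:.4f}")
        lines.append("-" * 58)
        lines.append(f"{'branch category':<30}{'omega':>10}  {'status':>8}")
        for cat, w in sorted(self.params.omega_by_category.items()):
            status = "fixed" if cat in self.fixed_omegas else "free"
            lines.append(f"{cat:<30}{w:>10.4f}  {status:>8}")
        lines.append("=" * 58)
        return "\n".join(lines)


@dataclass
class TwoRatioTest:
    focal: str
    alt: BranchModelResults
    null: BranchModelResults
    lrt: "LRTResult"

    @property
    def omega(self) -> float:
        return self.alt.params.omega_by_category[self.focal]

    @property
    def p_value(self) -> float:
        return self.lrt.p_value


@dataclass
class LRTResult:
    """Chi-square likelihood-ratio test of nested branch-model fits."""

    statistic: float
    df: int
    p_value: float


def lrt_neutral(fit_alt: BranchModelResults, fit_null: BranchModelResults) -> LRTResult:
    """LRT of a fit against the nested null with focal omega(s) fixed.

    The null must be the alternative with one or more category omegas
    fixed (conventionally at 1, the neutral expectation); df equals the
    number of newly fixed omegas.
    """
    extra = set(fit_null.fixed_omegas) - set(fit_alt.fixed_omegas)
    shared_ok = all(
        np.isclose(fit_null.fixed_omegas[c], fit_alt.fixed_omegas[c])
        for c in fit_alt.fixed_omegas
        if c in fit_null.fixed_omegas
    )
    same_cats = set(fit_alt.params.omega_by_category) == set(fit_null.params.omega_by_category)
    if not extra or not shared_ok or not same_cats or set(fit_alt.fixed_omegas) - set(fit_null.fixed_omegas):
        raise CodonModelError("fits are not nested via fixing focal-category omegas")
    stat = max(0.0, 2.0 * (fit_alt.llf - fit_null.llf))
    df = len(extra)
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def collapse_to_two_categories(tree: LabeledTree, focal: str) -> LabeledTree:
    """Copy of ``tree`` keeping only the focal category; every other
    branch is relabeled background (the shared-omega two-ratio layout)."""
    out = tree.copy()
    found = False
    for nd in out.branches():
        if getattr(nd.edge, "category", BACKGROUND) == focal:
            found = True
        else:
            nd.edge.category = BACKGROUND
    if not found:
        raise CodonModelError(f"category {focal!r} not present on tree")
    return out


def fit_branch_model(
    aln: CodonAlignment,
    tree: LabeledTree | str,
    fixed_omegas: dict[str, float] | None = None,
    **kwargs,
) -> BranchModelResults:
    """Functional wrapper: build the model and fit it."""
    return CodonBranchModel(aln, tree).fit(fixed_omegas=fixed_omegas, **kwargs)
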