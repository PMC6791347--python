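"""GY94 branch model: frequencies, rate matrix, pruning likelihood,
ML fitting and likelihood-ratio tests."""

import numpy as np
import pytest
from scipy import stats

from ortholoss.alignment import CodonAlignment
from ortholoss.codons import CODON_INDEX, N_STATES, SENSE_CODONS, random_sense_cds
from ortholoss.codonmodel import (
    CodonBranchModel,
    CodonModelError,
    CodonModelParams,
    TransitionKernel,
    _TreeIndex,
    f3x4_frequencies,
    fit_branch_model,
    gy94_rate_matrix,
    lrt_neutral,
)
from ortholoss.simulate import EvolutionSpec, simulate_cds_evolution
from ortholoss.trees import LabeledTree, balanced_tree

from oracles import enumeration_loglike


def uniform_pi():
    return np.full(N_STATES, 1.0 / N_STATES)


class TestF3x4:
    def test_uniform_composition_gives_uniform_codons(self):
        seqs = ["".join(c) for c in zip("ACGT", "ACGT", "ACGT")]
        aln = CodonAlignment(["a"], ["ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"[:48]])
        # build an alignment whose three codon positions each see A,C,G,T equally
        cods = ["".join(x) for x in zip("AAAACCCCGGGGTTTT", "ACGTACGTACGTACGT", "CAGTGTCAATGCTCGA")]
        aln = CodonAlignment(["a"], ["".join(cods)])
        pi = f3x4_frequencies(aln)
        assert pi == pytest.approx(np.full(N_STATES, 1 / N_STATES), abs=1e-12)

    def test_toy_alignment_matches_hand_computation(self):
        # 2 sequences x 3 codons: position-wise nucleotide counts by hand
        aln = CodonAlignment(["a", "b"], ["ATGAAATTT", "ATGAAACCC"])
        pi = f3x4_frequencies(aln)
        # codons ATG,AAA,TTT / ATG,AAA,CCC
        # pos1 = A,A,T,A,A,C ; pos2 = T,A,T,T,A,C ; pos3 = G,A,T,G,A,C
        p1 = {"A": 4 / 6, "T": 1 / 6, "C": 1 / 6}
        p2 = {"T": 3 / 6, "A": 2 / 6, "C": 1 / 6}
        p3 = {"G": 2 / 6, "A": 2 / 6, "T": 1 / 6, "C": 1 / 6}
        raw = {}
        for c in SENSE_CODONS:
            raw[c] = p1.get(c[0], 0) * p2.get(c[1], 0) * p3.get(c[2], 0)
        total = sum(raw.values())
        assert pi[CODON_INDEX["ATG"]] == pytest.approx(raw["ATG"] / total)
        assert pi[CODON_INDEX["AAA"]] == pytest.approx(raw["AAA"] / total)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_ambiguous_position_is_error(self):
        aln = CodonAlignment(["a"], ["A-GA-GA-G"])
        with pytest.raises(CodonModelError):
            f3x4_frequencies(aln)


class TestRateMatrix:
    def test_omega_zero_kills_nonsynonymous_rates(self):
        from ortholoss.codons import NONSYN_MASK

        Q = gy94_rate_matrix(2.0, 0.0, uniform_pi(), scale=False)
        assert np.all(Q[NONSYN_MASK] == 0)

    def test_rows_sum_to_zero_and_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_STATES))
        Q = gy94_rate_matrix(3.0, 0.4, pi)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-10)

    def test_hand_picked_entry(self):
        # TTT -> TTC: synonymous (Phe) transition => kappa * pi_TTC
        pi = uniform_pi()
        Q = gy94_rate_matrix(2.5, 0.3, pi, scale=False)
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTC"]
        assert Q[i, j] == pytest.approx(2.5 * pi[j])
        # TTT -> TTA: nonsynonymous (Phe->Leu) transversion => omega * pi
        k = CODON_INDEX["TTA"]
        assert Q[i, k] == pytest.approx(0.3 * pi[k])
        # two-position change has rate zero
        m = CODON_INDEX["TCC"]
        assert Q[i, m] == 0.0

    def test_scaling_gives_unit_expected_rate(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_STATES))
        Q = gy94_rate_matrix(2.0, 0.5, pi)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_transition_probabilities_match_expm(self):
        from scipy.linalg import expm

        rng = np.random.default_rng(2)
        pi = rng.dirichlet(np.ones(N_STATES) * 5)
        kern = TransitionKernel(2.0, 0.3, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(kern.probs(t), expm(kern.Q * t), atol=1e-10)


def random_instance(seed, max_leaves=4, max_codons=10):
    """Random small tree + alignment + parameters for oracle checks."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(2, max_leaves + 1))
    taxa = [f"t{i}" for i in range(n_leaves)]
    nodes = [f"{t}:{rng.uniform(0.02, 1.5):.4f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.02, 1.5):.4f}")
    newick = nodes[0][: nodes[0].rfind(":")] + ";"
    n_codons = int(rng.integers(2, max_codons + 1))
    seqs = []
    for _ in taxa:
        s = random_sense_cds(n_codons, rng)
        # sprinkle ambiguity
        cods = [s[3 * k : 3 * k + 3] for k in range(n_codons)]
        for k in range(n_codons):
            if rng.random() < 0.15:
                cods[k] = "???"
        seqs.append("".join(cods))
    aln = CodonAlignment(taxa, seqs)
    pi = rng.dirichlet(np.ones(N_STATES) * 10)
    kappa = float(rng.uniform(0.5, 6))
    omega = float(rng.uniform(0.05, 3))
    return newick, aln, pi, kappa, omega


class TestPruningLikelihood:
    def test_single_leaf_closed_form(self):
        pi = uniform_pi()
        aln = CodonAlignment(["a"], ["ATGAAA???"])
        model = CodonBranchModel(aln, "a;", codon_freqs=pi)
        p = CodonModelParams(
            kappa=2.0, omega_by_category={}, codon_freqs=pi, branch_lengths=np.array([])
        )
        expected = np.log(pi[CODON_INDEX["ATG"]]) + np.log(pi[CODON_INDEX["AAA"]]) + 0.0
        assert model.loglike(p) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(25))
    def test_pruning_matches_exhaustive_enumeration(self, seed):
        """Felsenstein pruning equals brute-force summation over all
        internal-node codon states on small random instances."""
        newick, aln, pi, kappa, omega = random_instance(seed)
        model = CodonBranchModel(aln, newick, codon_freqs=pi)
        params = CodonModelParams(
            kappa=kappa,
            omega_by_category={"background": omega},
            codon_freqs=pi,
            branch_lengths=model.initial_branch_lengths(),
        )
        ll = model.loglike(params)
        tindex = model._tindex
        kern = TransitionKernel(kappa, omega, pi)
        P_of = {
            i: kern.probs(t)
            for i, t in zip(tindex.branch_nodes, params.branch_lengths)
        }
        spec = {
            "root": tindex.root,
            "children": {i: tindex.children[i] for i in range(tindex.n_nodes)},
            "leaf_row": {i: tindex.leaf_row[i] for i in range(tindex.n_nodes)},
        }
        ll_oracle = enumeration_loglike(spec, model._states, pi, P_of)
        assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_invariant_to_rerooting(self):
        """Pulley principle: likelihood of a reversible model does not
        depend on root placement along a branch."""
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(N_STATES) * 10)
        aln = CodonAlignment(
            ["a", "b", "c"],
            [random_sense_cds(8, rng) for _ in range(3)],
        )

        def ll(newick):
            m = CodonBranchModel(aln, newick, codon_freqs=pi)
            p = CodonModelParams(
                kappa=2.0,
                omega_by_category={"background": 0.4},
                codon_freqs=pi,
                branch_lengths=m.initial_branch_lengths(),
            )
            return m.loglike(p)

        # same unrooted tree, root slid along the a-branch
        assert ll("(a:0.4,(b:0.3,c:0.2):0.1);") == pytest.approx(
            ll("(a:0.1,(b:0.3,c:0.2):0.4);"), abs=1e-9
        )

    def test_branch_length_scaling_compensation(self):
        """Doubling all branch lengths while halving the generator (via
        the kernel's own scaling) leaves the likelihood unchanged."""
        rng = np.random.default_rng(8)
        aln = CodonAlignment(["a", "b"], [random_sense_cds(10, rng) for _ in range(2)])
        pi = uniform_pi()
        m = CodonBranchModel(aln, "(a:0.3,b:0.5);", codon_freqs=pi)
        p1 = CodonModelParams(
            kappa=2.0, omega_by_category={"background": 0.5}, codon_freqs=pi,
            branch_lengths=np.array([0.3, 0.5]),
        )
        kern = TransitionKernel(2.0, 0.5, pi)
        # P(2t) under Q/2 equals P(t) under Q
        assert np.allclose(kern.probs(0.6) @ kern.probs(-0.0), kern.probs(0.6))
        p2 = CodonModelParams(
            kappa=2.0, omega_by_category={"background": 0.5}, codon_freqs=pi,
            branch_lengths=np.array([0.6, 1.0]),
        )
        m2 = CodonBranchModel(aln, "(a:0.6,b:1.0);", codon_freqs=pi)
        # direct identity: exp(Q*2t/2) == exp(Q*t)
        half = TransitionKernel(2.0, 0.5, pi)
        assert m.loglike(p1) == pytest.approx(
            _scaled_loglike(m2, p2, factor=0.5), abs=1e-9
        )


def _scaled_loglike(model, params, factor):
    scaled = CodonModelParams(
        kappa=params.kappa,
        omega_by_category=params.omega_by_category,
        codon_freqs=params.codon_freqs,
        branch_lengths=params.branch_lengths * factor,
    )
    return model.loglike(scaled)


class TestFitting:
    def test_parameter_recovery_purifying(self):
        rng = np.random.default_rng(3)
        nwk = balanced_tree(8, 0.15)
        spec = EvolutionSpec(
            tree=nwk, omega={"background": 0.2}, kappa=2.0,
            root_cds=random_sense_cds(500, rng), seed=99,
        )
        _, aln = simulate_cds_evolution(spec)
        res = fit_branch_model(aln, nwk)
        assert res.converged
        assert 0.1 <= res.params.omega_by_category["background"] <= 0.35
        assert 1.2 <= res.params.kappa <= 3.2

    def test_fixing_omega_never_beats_free_fit(self):
        rng = np.random.default_rng(4)
        nwk = balanced_tree(4, 0.2)
        spec = EvolutionSpec(
            tree=nwk, omega={"background": 0.5}, kappa=2.0,
            root_cds=random_sense_cds(120, rng), seed=5,
        )
        _, aln = simulate_cds_evolution(spec)
        model = CodonBranchModel(aln, nwk)
        free = model.fit()
        fixed = model.fit(fixed_omegas={"background": 1.0})
        assert free.llf >= fixed.llf - 1e-6

    def test_results_summary_mentions_categories(self):
        rng = np.random.default_rng(5)
        nwk = balanced_tree(4, 0.1)
        spec = EvolutionSpec(
            tree=nwk, omega={"background": 0.5}, kappa=2.0,
            root_cds=random_sense_cds(60, rng), seed=6,
        )
        _, aln = simulate_cds_evolution(spec)
        res = CodonBranchModel(aln, nwk).fit()
        text = res.summary()
        assert "background" in text and "Log-likelihood" in text


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        lr = _fake_lrt(0.0)
        assert lr.statistic == 0.0 and lr.p_value == pytest.approx(1.0)

    def test_chi2_critical_value(self):
        lr = _fake_lrt(3.84 / 2)
        assert lr.p_value == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_fits_rejected(self):
        rng = np.random.default_rng(6)
        nwk = "((a:0.1,b:0.1)#fg:0.1,(c:0.1,d:0.1):0.1);"
        spec = EvolutionSpec(
            tree=nwk, omega={"background": 0.5, "fg": 0.5}, kappa=2.0,
            root_cds=random_sense_cds(60, rng), seed=7,
        )
        _, aln = simulate_cds_evolution(spec)
        m = CodonBranchModel(aln, nwk)
        alt = m.fit()
        with pytest.raises(CodonModelError, match="nested"):
            lrt_neutral(alt, alt)


def _fake_lrt(delta):
    """LRT from two synthetic results differing by delta in loglike."""
    import types

    from ortholoss.codonmodel import BranchModelResults, LRTResult

    class _M:
        n_branches = 2

    base = dict(
        model=_M(),
        params=CodonModelParams(
            kappa=2.0,
            omega_by_category={"fg": 0.5, "background": 0.5},
            codon_freqs=uniform_pi(),
            branch_lengths=np.array([0.1, 0.1]),
        ),
        converged=True,
        n_iter=1,
    )
    alt = BranchModelResults(llf=-100.0 + delta, fixed_omegas={}, **base)
    null = BranchModelResults(llf=-100.0, fixed_omegas={"fg": 1.0}, **base)
    return lrt_neutral(alt, null)
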