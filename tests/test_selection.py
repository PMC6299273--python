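"""Codon substitution model, branch-model fits, LRT and counting dN/dS."""

import math

import numpy as np
import pytest

from mitoarch.codon_model import (
    BranchModelSpec,
    CodonAlignment,
    PhyloTree,
    f3x4_frequencies,
    fit_branch_model,
    log_likelihood,
)
from mitoarch.selection import (
    likelihood_ratio_test,
    ng86_pairwise,
    protein_divergence,
)
from mitoarch.synthetic import simulate_codon_alignment


class TestProteinDivergence:
    def test_identical_sequences(self):
        seqs = {k: "MKVLF" for k in "fabc"}
        assert protein_divergence(seqs, "f") == (0, 0.0)

    def test_hand_counted_site(self):
        seqs = {"f": "MKV", "a": "MKV", "b": "MRV", "c": "MKV"}
        n, p = protein_divergence(seqs, "f")
        assert n == 1 and p == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            protein_divergence({"f": "MKV", "a": "MK"}, "f")

    def test_gaps_ignored_unless_flagged(self):
        seqs = {"f": "MKV", "a": "M-V"}
        assert protein_divergence(seqs, "f")[0] == 0
        assert protein_divergence(seqs, "f", count_gaps=True)[0] == 1


class TestRateMatrix:
    def test_rows_sum_to_zero_and_stationarity(self, codon_model, uniform_pi):
        Q = codon_model.rate_matrix(2.0, 0.3, uniform_pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-10
        assert np.abs(uniform_pi @ Q).max() < 1e-10

    def test_mean_rate_scaled_to_one(self, codon_model, uniform_pi):
        Q = codon_model.rate_matrix(3.0, 0.7, uniform_pi)
        assert -(uniform_pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_multi_step_entries_zero(self, codon_model, uniform_pi):
        Q = codon_model.rate_matrix(2.0, 0.5, uniform_pi)
        i = codon_model.index["TTT"]
        j = codon_model.index["CCT"]  # two positions differ
        assert Q[i, j] == 0.0

    def test_kappa_omega_classification(self, codon_model, uniform_pi):
        """TTT->TTC is a synonymous transition, TTT->TTA a non-synonymous
        transversion (Phe->Leu), so their rate ratio is kappa/omega."""
        kappa, omega = 2.0, 0.4
        Q = codon_model.rate_matrix(kappa, omega, uniform_pi, scale=False)
        i = codon_model.index["TTT"]
        syn_ts = Q[i, codon_model.index["TTC"]]
        nonsyn_tv = Q[i, codon_model.index["TTA"]]
        assert syn_ts / nonsyn_tv == pytest.approx(kappa / omega)

    def test_uniform_neutral_model_collapses(self, codon_model, uniform_pi):
        """With omega = kappa = 1 and uniform pi every allowed off-diagonal
        entry is identical before scaling."""
        Q = codon_model.rate_matrix(1.0, 1.0, uniform_pi, scale=False)
        off = Q[(Q > 0)]
        assert np.allclose(off, off[0])

    def test_transition_matrix_identity_at_zero(self, codon_model, uniform_pi):
        P0 = codon_model.transition_matrix(2.0, 0.5, uniform_pi, 0.0)
        assert np.abs(P0 - np.eye(codon_model.n)).max() < 1e-12


class TestLikelihood:
    def two_taxon_aln(self):
        return CodonAlignment({"A": "ATGGCTCATTTTGGA", "B": "ATGGCCCATTTCGGA"})

    def test_zero_branch_lengths_identical_sequences(self, codon_model,
                                                     uniform_pi):
        import dendropy

        aln = CodonAlignment({"A": "ATGGCTCAT", "B": "ATGGCTCAT",
                              "C": "ATGGCTCAT"})
        tree = dendropy.Tree.get(data="(A:0,B:0,C:0);", schema="newick")
        tree.is_rooted = True
        ll = log_likelihood(aln, tree, kappa=2.0, omega=0.5, pi=uniform_pi)
        expected = sum(
            math.log(uniform_pi[codon_model.index[c]])
            for c in ("ATG", "GCT", "CAT")
        )
        assert ll == pytest.approx(expected)

    def test_matches_bruteforce_two_taxon_sum(self, codon_model, uniform_pi):
        """Pruning equals the direct sum over states pi_i P_ij(t) for a
        two-taxon tree."""
        import dendropy

        aln = self.two_taxon_aln()
        t1, t2 = 0.17, 0.31
        tree = dendropy.Tree.get(
            data=f"(A:{t1},B:{t2});", schema="newick"
        )
        tree.is_rooted = True
        kappa, omega = 2.2, 0.45
        ll = log_likelihood(aln, PhyloTree(tree, deroot=False), kappa=kappa,
                            omega=omega, pi=uniform_pi)
        P1 = codon_model.transition_matrix(kappa, omega, uniform_pi, t1)
        P2 = codon_model.transition_matrix(kappa, omega, uniform_pi, t2)
        brute = 0.0
        for ca, cb in zip(aln.columns["A"], aln.columns["B"]):
            ia, ib = codon_model.index[ca], codon_model.index[cb]
            brute += math.log(
                sum(
                    uniform_pi[k] * P1[k, ia] * P2[k, ib]
                    for k in range(codon_model.n)
                )
            )
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_rerooting_invariance(self, uniform_pi, quartet_tree):
        """Under the reversible model the likelihood does not depend on the
        root position (pulley principle)."""
        import dendropy

        aln = simulate_codon_alignment(
            quartet_tree, omega=0.4, kappa=2.0, pi=uniform_pi, n_codons=60,
            seed=5,
        )
        ll1 = log_likelihood(aln, quartet_tree, kappa=2.0, omega=0.4,
                             pi=uniform_pi)
        rerooted = dendropy.Tree.get(
            data="(A:0.2,(B:0.3,((C:0.15,D:0.25):0.05):0.1):0.0);",
            schema="newick",
        )
        rerooted.is_rooted = True
        ll2 = log_likelihood(aln, rerooted, kappa=2.0, omega=0.4,
                             pi=uniform_pi)
        assert ll1 == pytest.approx(ll2, abs=1e-6)

    def test_f3x4_is_probability_vector(self, codon_model):
        aln = self.two_taxon_aln()
        pi = f3x4_frequencies(aln, codon_model)
        assert pi.shape == (codon_model.n,)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()


@pytest.fixture(scope="module")
def sim_and_fits():
    """Shared fits on one simulated alignment (omega 0.3 everywhere)."""
    import dendropy

    tree = dendropy.Tree.get(
        data="((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);", schema="newick"
    )
    tree.is_rooted = True
    ptree = PhyloTree(tree)
    pi = np.full(62, 1 / 62)
    aln = simulate_codon_alignment(
        ptree, omega=0.3, kappa=2.0, pi=pi, n_codons=300, seed=11
    )
    one = fit_branch_model(aln, ptree, BranchModelSpec("one_ratio"),
                           n_restarts=2, seed=0)
    two = fit_branch_model(
        aln, ptree, BranchModelSpec("two_ratios", foreground="A"),
        n_restarts=1, seed=0, init=one,
    )
    free = fit_branch_model(aln, ptree, BranchModelSpec("free_ratios"),
                            n_restarts=1, seed=0, init=two)
    return aln, ptree, one, two, free


class TestBranchModels:

    def test_nesting_inequalities(self, sim_and_fits):
        _, _, one, two, free = sim_and_fits
        assert two.log_likelihood >= one.log_likelihood - 1e-6
        assert free.log_likelihood >= two.log_likelihood - 1e-6

    def test_parameter_counts_on_quartet(self, sim_and_fits):
        _, ptree, one, two, free = sim_and_fits
        assert ptree.n_branches == 5  # unrooted 4-taxon topology
        assert one.parameter_count == 1 + 5 + 1
        assert two.parameter_count == 1 + 5 + 2
        assert free.parameter_count == 1 + 5 + 5
        assert len(set(free.omega_by_branch)) == 5

    def test_two_ratio_collapses_to_one_ratio_under_constraint(
        self, sim_and_fits
    ):
        """Evaluating a branch-wise omega map with the foreground omega
        constrained equal to the background reproduces the one-ratio
        likelihood at the same parameter values."""
        aln, ptree, one, two, free = sim_and_fits
        om = one.omegas[0]
        import dendropy

        constrained = {bid: om for bid in ptree.branch_ids()}
        # plug the one-ratio MLE branch lengths back into the tree
        for b in ptree.branches:
            b.length = one.branch_lengths[b.id]
        ll = log_likelihood(aln, ptree, kappa=one.kappa, omega=constrained,
                            pi=one.pi)
        assert ll == pytest.approx(one.log_likelihood, abs=1e-6)

    def test_parameter_recovery_purifying(self, quartet_ptree, uniform_pi):
        ests = []
        for seed in range(3):
            aln = simulate_codon_alignment(
                quartet_ptree, omega=0.2, kappa=2.0, pi=uniform_pi,
                n_codons=500, seed=40 + seed,
            )
            fit = fit_branch_model(
                aln, quartet_ptree, BranchModelSpec("one_ratio"),
                n_restarts=1, seed=seed,
            )
            ests.append(fit.omegas[0])
        assert abs(np.median(ests) - 0.2) <= 0.1


class TestLRT:
    def test_equal_likelihoods_not_significant(self):
        from mitoarch.codon_model import BranchModelFit, BranchModelSpec

        null = BranchModelFit(
            BranchModelSpec("one_ratio"), -100.0, 2.0, {"A": 0.5}, {"A": 0.1},
            parameter_count=3, converged=True, pi=np.full(62, 1 / 62),
        )
        alt = BranchModelFit(
            BranchModelSpec("two_ratios", foreground="A"), -100.0, 2.0,
            {"A": 0.5}, {"A": 0.1}, parameter_count=4, converged=True,
            pi=np.full(62, 1 / 62),
        )
        res = likelihood_ratio_test(null, alt)
        assert res.statistic == 0.0 and not res.significant

    def test_statistic_4_df1(self):
        from mitoarch.codon_model import BranchModelFit, BranchModelSpec

        null = BranchModelFit(
            BranchModelSpec("one_ratio"), -102.0, 2.0, {}, {},
            parameter_count=3, converged=True, pi=np.full(62, 1 / 62),
        )
        alt = BranchModelFit(
            BranchModelSpec("two_ratios", foreground="A"), -100.0, 2.0, {}, {},
            parameter_count=4, converged=True, pi=np.full(62, 1 / 62),
        )
        res = likelihood_ratio_test(null, alt)
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0455, abs=2e-3)
        assert res.significant  # 4.0 > 3.84

    def test_negative_statistic_warns(self):
        from mitoarch.codon_model import BranchModelFit, BranchModelSpec

        null = BranchModelFit(
            BranchModelSpec("one_ratio"), -100.0, 2.0, {}, {},
            parameter_count=3, converged=True, pi=np.full(62, 1 / 62),
        )
        alt = BranchModelFit(
            BranchModelSpec("free_ratios"), -101.0, 2.0, {}, {},
            parameter_count=5, converged=True, pi=np.full(62, 1 / 62),
        )
        res = likelihood_ratio_test(null, alt)
        assert res.warning is not None
        assert res.statistic == 0.0


class TestNG86:
    def test_identical_sequences(self):
        s = "ATGGCTCATTTTGGA"
        r = ng86_pairwise(s, s)
        assert r.dN == 0 and r.dS == 0

    def test_single_synonymous_difference(self):
        a = "ATGGCTCAT" * 30
        b = "ATGGCCCAT" + "ATGGCTCAT" * 29  # GCT->GCC, synonymous
        r = ng86_pairwise(a, b)
        assert r.dN == 0.0
        assert r.dS > 0
        assert math.isnan(r.omega) is False

    def test_ds_zero_flags_omega_nan(self):
        a = "ATGGCTCAT" * 10
        b = "ATGCCTCAT" + "ATGGCTCAT" * 9  # GCT->CCT non-synonymous
        r = ng86_pairwise(a, b)
        assert r.dS == 0 and math.isnan(r.omega)

    def test_counting_omega_below_one_under_purifying_selection(
        self, quartet_ptree, uniform_pi
    ):
        below = 0
        n_rep = 12
        for seed in range(n_rep):
            aln = simulate_codon_alignment(
                quartet_ptree, omega=0.2, kappa=2.0, pi=uniform_pi,
                n_codons=300, seed=900 + seed,
            )
            r = ng86_pairwise(
                "".join(aln.columns["A"]), "".join(aln.columns["B"])
            )
            if not math.isnan(r.omega) and r.omega < 1:
                below += 1
        assert below >= 0.85 * n_rep
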