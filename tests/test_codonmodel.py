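"""Codon model internals: rate matrices, transition probabilities, pruning
likelihood vs exhaustive enumeration, and maximum-likelihood fits."""

import numpy as np
import pytest

from conftest import (
    brute_force_lnL_quartet,
    brute_force_lnL_star3,
    make_codon_alignment,
)
from endoselect.codonmodel import (
    CODON_INDEX,
    CodonModelParams,
    CodonPruner,
    N_STATES,
    SENSE_CODONS,
    build_rate_matrix,
    decompose,
    f3x4_frequencies,
    fit_model,
    transition_matrix,
    uniform_frequencies,
)
from endoselect.simulate import SimulationSpec, simulate_codon_alignment, simulate_tree
from endoselect.trees import parse_newick


PI = uniform_frequencies()


class TestRateMatrix:
    def test_multi_position_changes_forbidden(self):
        Q, _ = build_rate_matrix(2.0, 0.5, PI)
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["GGG"]] == 0.0
        assert Q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0

    def test_detailed_balance(self, rng):
        pi = rng.dirichlet(np.ones(N_STATES))
        Q, _ = build_rate_matrix(3.1, 0.4, pi)
        flow = pi[:, None] * Q
        assert np.allclose(flow, flow.T, atol=1e-12)

    def test_rows_sum_to_zero_and_rate_normalisation(self):
        Q, rate = build_rate_matrix(2.0, 1.0, PI)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(PI, np.diag(Q / rate)) == pytest.approx(1.0)

    def test_transition_matrix_limits(self):
        P0 = transition_matrix(2.0, 0.5, PI, 0.0)
        assert np.allclose(P0, np.eye(N_STATES), atol=1e-10)
        Pt = transition_matrix(2.0, 0.5, PI, 0.7)
        assert np.allclose(Pt.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(PI @ Pt, PI, atol=1e-10)  # stationarity
        Pinf = transition_matrix(2.0, 0.5, PI, 400.0)
        assert np.allclose(Pinf, np.tile(PI, (N_STATES, 1)), atol=1e-6)


class TestPruningOracle:
    """Pruning equals exhaustive internal-state enumeration on tiny trees."""

    def test_three_taxon_m0(self):
        aln = make_codon_alignment(
            {"A": "ATGTGTCATAAG", "B": "ATGTGCCACAAG", "C": "ATATGTCATAGG"}
        )
        tree = parse_newick("(A:0.2,B:0.35,C:0.15);")
        kappa, w = 2.3, 0.4
        params = CodonModelParams("M0", kappa, PI, {"omega": w})
        pruner = CodonPruner(aln, tree)
        got = pruner.loglik(np.array([0.2, 0.35, 0.15]), params)
        want = brute_force_lnL_star3(
            aln, {"A": 0.2, "B": 0.35, "C": 0.15}, kappa, PI, [(1.0, w, w)]
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_quartet_m0_and_branch_site(self):
        aln = make_codon_alignment(
            {
                "A": "ATGTGTCATAAGTTT",
                "B": "ATGTGCCACAAGTTC",
                "C": "ATATGTCATAGGCTT",
                "D": "ATATGTCACAGGCTG",
            }
        )
        lengths = {"A": 0.1, "B": 0.2, "C": 0.15, "D": 0.25, "AB": 0.08, "CD": 0.3}
        kappa = 1.9
        newick = (
            f"((A:{lengths['A']},B:{lengths['B']}):{lengths['AB']},"
            f"(C:{lengths['C']},D:{lengths['D']})#1:{lengths['CD']});"
        )
        tree = parse_newick(newick)
        pruner = CodonPruner(aln, tree)
        t = pruner.edge_lengths0

        m0 = CodonModelParams("M0", kappa, PI, {"omega": 0.6})
        want = brute_force_lnL_quartet(
            aln, lengths, kappa, PI, [(1.0, 0.6, 0.6)]
        )
        assert pruner.loglik(t, m0) == pytest.approx(want, abs=1e-8)

        bsa = CodonModelParams(
            "bsA", kappa, PI,
            {"omega0": 0.3, "omega2": 3.5, "p0": 0.55, "p1": 0.3},
        )
        want = brute_force_lnL_quartet(
            aln, lengths, kappa, PI, bsa.site_classes(), fg_edge="CD"
        )
        assert pruner.loglik(t, bsa) == pytest.approx(want, abs=1e-8)

    def test_missing_data_codon(self):
        """A gap codon integrates out: equals enumeration without that tip's
        factor."""
        aln = make_codon_alignment({"A": "ATG", "B": "---", "C": "ATA"})
        tree = parse_newick("(A:0.2,B:0.35,C:0.15);")
        params = CodonModelParams("M0", 2.0, PI, {"omega": 0.5})
        pruner = CodonPruner(aln, tree)
        got = pruner.loglik(np.array([0.2, 0.35, 0.15]), params)
        two = make_codon_alignment({"A": "ATG", "C": "ATA"})
        want = brute_force_lnL_star3(
            two, {"A": 0.2, "C": 0.15}, 2.0, PI, [(1.0, 0.5, 0.5)]
        )
        assert got == pytest.approx(want, abs=1e-8)


class TestDegenerateLimits:
    def test_zero_branch_lengths_give_pi(self):
        aln = make_codon_alignment({"A": "ATGAAA", "B": "ATGAAA"})
        tree = parse_newick("(A:0.0,B:0.0);")
        params = CodonModelParams("M0", 2.0, PI, {"omega": 0.5})
        pruner = CodonPruner(aln, tree)
        got = pruner.loglik(np.array([0.0, 0.0]), params)
        want = 2 * np.log(1.0 / 61)
        assert got == pytest.approx(want, abs=1e-9)

    def test_long_branches_factorise(self):
        aln = make_codon_alignment({"A": "ATGAAA", "B": "TGTCCC"})
        tree = parse_newick("(A:200.0,B:200.0);")
        params = CodonModelParams("M0", 2.0, PI, {"omega": 0.5})
        pruner = CodonPruner(aln, tree)
        got = pruner.loglik(np.array([200.0, 200.0]), params)
        want = 4 * np.log(1.0 / 61)  # independent tips, 2 sites x 2 tips
        assert got == pytest.approx(want, abs=1e-5)


class TestFits:
    def test_m0_parameter_recovery(self):
        spec = SimulationSpec(
            n_codons=500, p0=1.0, p1=0.0, omega0=0.2, omega2=1.0, seed=42
        )
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        fit = fit_model(aln, tree, "M0", start_omega=0.5, freqs="uniform")
        assert fit.converged
        assert 0.15 <= fit.params.omegas["omega"] <= 0.25

    def test_identical_sequences_collapse_branch_lengths(self):
        rows = {f"s{i}": "ATGTGTAAGCATTTTGGA" for i in range(4)}
        aln = make_codon_alignment(rows)
        tree = parse_newick("((s0:0.1,s1:0.1):0.05,(s2:0.1,s3:0.1):0.05);")
        fit = fit_model(aln, tree, "M0", freqs="uniform")
        # all-identical data: ML branch lengths go to ~0 and lnL -> sum log pi
        assert fit.branch_table["t"].max() < 1e-4
        assert fit.lnL == pytest.approx(6 * np.log(1 / 61), abs=1e-3)

    def test_nesting_alt_at_least_null(self):
        spec = SimulationSpec(n_codons=120, omega2=1.0, seed=9)
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        m0 = fit_model(aln, tree, "M0")
        alt = fit_model(
            aln, tree, "bsA", branch_lengths=m0.branch_lengths, fix_kappa=m0.kappa
        )
        null = fit_model(
            aln, tree, "bsA_null", branch_lengths=m0.branch_lengths,
            fix_kappa=m0.kappa,
        )
        assert alt.lnL >= null.lnL - 1e-4  # optimiser tolerance

    def test_branch_site_requires_foreground(self):
        aln = make_codon_alignment({"A": "ATG", "B": "ATA", "C": "ATT"})
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="foreground"):
            fit_model(aln, tree, "bsA")

    def test_dn_ds_decomposition_positive(self):
        spec = SimulationSpec(n_codons=150, seed=2)
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        fit = fit_model(aln, tree, "M0")
        tab = fit.branch_table
        assert (tab["dN"] >= 0).all() and (tab["dS"] >= 0).all()
        # purifying simulation: dN/dS well below 1 overall
        assert tab["dN"].sum() < tab["dS"].sum()


class TestFrequencies:
    def test_f3x4_sums_to_one_and_floors_zeros(self):
        aln = make_codon_alignment({"A": "ATGATG", "B": "ATGATG"})
        pi = f3x4_frequencies(aln)
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()

    def test_gradient_matches_numeric(self):
        spec = SimulationSpec(n_codons=80, seed=7)
        tree, _ = simulate_tree(spec)
        aln, _ = simulate_codon_alignment(tree, spec)
        pruner = CodonPruner(aln, tree)
        params = CodonModelParams("M0", 2.4, f3x4_frequencies(aln), {"omega": 0.37})
        t = pruner.edge_lengths0.copy()
        ll, grad = pruner.loglik_and_tgrad(t, params)
        assert ll == pytest.approx(pruner.loglik(t, params), abs=1e-9)
        h = 1e-6
        for e in range(len(t)):
            tp, tm = t.copy(), t.copy()
            tp[e] += h
            tm[e] -= h
            num = (pruner.loglik(tp, params) - pruner.loglik(tm, params)) / (2 * h)
            assert grad[e] == pytest.approx(num, rel=1e-4, abs=1e-6)
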