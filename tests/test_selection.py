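"""Codon alignments, GY94 machinery, pruning likelihood, and model fits."""

import numpy as np
import pytest
from scipy.linalg import expm

from grevol.codon import (
    SENSE_CODONS,
    EigenQ,
    f3x4_frequencies,
    gy94_rate_matrix,
    uniform_frequencies,
)
from grevol.selection import (
    CodonAlignment,
    CodonModelParams,
    InvariantAlignmentError,
    SiteClasses,
    _Engine,
    backtranslate_alignment,
    beta_class_omegas,
    branch_site_classes,
    codon_log_likelihood,
    drop_gappy_sequences,
    fit_branch_site,
    fit_m0,
    fit_m8_pair,
    m8_site_classes,
)
from grevol.seqio import read_tree
from grevol.simulate import simulate_codon_alignment, simulate_m0_alignment

UNIFORM = uniform_frequencies()


def brute_force_lnl(alignment, tree, kappa, classes, pi):
    """Oracle: per-site likelihood by explicit summation over all internal
    node states (and omega classes), no pruning."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    taxa_idx = {t: i for i, t in enumerate(alignment.taxa)}
    total = 0.0
    omegas = classes.omegas
    for site in range(alignment.n_sites):
        site_lik = 0.0
        for k, w in enumerate(classes.weights):
            q = gy94_rate_matrix(kappa, omegas[k], pi, scale=False)
            rates = [
                -np.dot(pi, np.diag(gy94_rate_matrix(kappa, om, pi, scale=False)))
                for om in omegas
            ]
            q = q / np.dot(classes.weights, rates)
            pmats = {id(n): expm(q * (n.edge.length or 0.0)) for n in nodes if n.parent_node}
            lik = 0.0
            for states in np.ndindex(*([len(SENSE_CODONS)] * len(internals))):
                assign = {id(n): s for n, s in zip(internals, states)}
                term = pi[assign[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    parent_state = assign[id(n.parent_node)]
                    if n.is_leaf():
                        obs = alignment.codons[taxa_idx[n.taxon.label], site]
                        term *= 1.0 if obs < 0 else pmats[id(n)][parent_state, obs]
                    else:
                        term *= pmats[id(n)][parent_state, assign[id(n)]]
                lik += term
            site_lik += w * lik
        total += np.log(site_lik)
    return total


class TestCodonAlignment:
    def test_from_nucleotides_and_back(self):
        rows = {"a": "ATGAAA---", "b": "ATGAAGTGG"}
        aln = CodonAlignment.from_nucleotides(rows)
        assert aln.n_sites == 3
        assert aln.to_nucleotides() == rows

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment.from_nucleotides({"a": "ATGTAAAAA"})

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment.from_nucleotides({"a": "ATGAAA", "b": "ATG"})


class TestBacktranslate:
    def test_gap_expansion(self):
        aln = backtranslate_alignment({"x": "M-K"}, {"x": "ATGAAA"})
        assert aln.to_nucleotides() == {"x": "ATG---AAA"}

    def test_round_trip_reproduces_protein_alignment(self, rng):
        from grevol.codon import translate
        from grevol.simulate import _backtranslate, _random_protein

        prots, cds = {}, {}
        for i in range(4):
            p = _random_protein(rng, 30)
            cds[f"t{i}"] = "ATG" + _backtranslate(rng, p)
            gapped = "M" + p[:10] + "-" * (i + 1) + p[10 : 30 - (i + 1)]
            prots[f"t{i}"] = gapped
            cds[f"t{i}"] = "ATG" + _backtranslate(np.random.default_rng(i), gapped.replace("-", "")[1:])
        aln = backtranslate_alignment(prots, cds)
        for name, row in aln.to_nucleotides().items():
            rebuilt = "".join(
                "-" if row[i : i + 3] == "---" else translate(row[i : i + 3])
                for i in range(0, len(row), 3)
            )
            assert rebuilt == prots[name]

    def test_wrong_length_cds_is_error(self):
        with pytest.raises(ValueError):
            backtranslate_alignment({"x": "MK"}, {"x": "ATGAA"})

    def test_translation_mismatch_is_error(self):
        with pytest.raises(ValueError, match="does not match"):
            backtranslate_alignment({"x": "MW"}, {"x": "ATGAAA"})

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate_alignment({"x": "M*K"}, {"x": "ATGTAAAAA"})


class TestDropGappy:
    def test_gappy_row_removed(self):
        aln = CodonAlignment.from_nucleotides(
            {"a": "ATGAAATGG", "b": "---------", "c": "ATGAAGTGG"}
        )
        out = drop_gappy_sequences(aln, max_gap_fraction=0.5)
        assert out.taxa == ["a", "c"]

    def test_no_gappy_rows_is_identity(self):
        aln = CodonAlignment.from_nucleotides({"a": "ATGAAA", "b": "ATGAAG"})
        out = drop_gappy_sequences(aln)
        assert out.taxa == aln.taxa and out.n_sites == aln.n_sites

    def test_gap_fractions_never_increase(self, rng):
        mat = rng.integers(-1, 61, size=(6, 40))
        aln = CodonAlignment(taxa=[f"t{i}" for i in range(6)], codons=mat)
        out = drop_gappy_sequences(aln, max_gap_fraction=0.5)
        before = {t: aln.gap_fraction(i) for i, t in enumerate(aln.taxa)}
        for i, t in enumerate(out.taxa):
            assert out.gap_fraction(i) <= before[t] + 1e-12

    def test_all_rows_removed_is_error(self):
        aln = CodonAlignment.from_nucleotides({"a": "---ATG", "b": "ATG---"})
        with pytest.raises(ValueError):
            drop_gappy_sequences(aln, max_gap_fraction=0.2)


class TestGy94:
    def test_neutral_symmetric_case(self):
        q = gy94_rate_matrix(1.0, 1.0, UNIFORM)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(q, q.T, atol=1e-12)  # uniform pi: fully symmetric

    def test_detailed_balance(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = gy94_rate_matrix(2.3, 0.4, pi)
        flux = pi[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_expected_rate(self, rng):
        pi = rng.dirichlet(np.ones(61))
        q = gy94_rate_matrix(1.7, 0.2, pi)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)

    def test_stationary_distribution_reached(self, rng):
        pi = rng.dirichlet(np.ones(61) * 5)
        q = gy94_rate_matrix(2.0, 0.5, pi)
        p_long = expm(q * 60.0)
        assert np.allclose(p_long, np.tile(pi, (61, 1)), atol=1e-8)

    def test_eigen_propagator_matches_expm(self, rng):
        pi = rng.dirichlet(np.ones(61) * 5)
        q = gy94_rate_matrix(2.0, 0.5, pi)
        eig = EigenQ(q, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(eig.p(t), expm(q * t), atol=1e-10)

    def test_f3x4_on_uniform_codons(self):
        cols = np.arange(61).reshape(1, -1)
        pi = f3x4_frequencies(cols)
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi > 0)


class TestPruningLikelihood:
    def test_zero_distance_identical_pair(self):
        tree = read_tree("(x:0.0000001,y:0.0000001)r;")
        aln = CodonAlignment(taxa=["x", "y"], codons=np.array([[5, 7, 9], [5, 7, 9]]))
        params = CodonModelParams(
            kappa=1.0,
            site_classes=SiteClasses(weights=np.array([1.0]), omegas=np.array([1.0])),
            pi=UNIFORM,
        )
        lnl = codon_log_likelihood(aln, tree, params)
        assert lnl == pytest.approx(3 * np.log(1 / 61), abs=1e-4)

    @pytest.mark.parametrize("with_gap", [False, True])
    def test_matches_brute_force_three_taxa(self, with_gap, rng):
        tree = read_tree("((t1:0.3,t2:0.5)n1:0.2,t3:0.4)root;")
        mat = rng.integers(0, 61, size=(3, 4))
        if with_gap:
            mat[1, 2] = -1
        aln = CodonAlignment(taxa=["t1", "t2", "t3"], codons=mat)
        classes = SiteClasses(weights=np.array([0.6, 0.4]), omegas=np.array([0.2, 1.5]))
        engine = _Engine(aln, tree, pi=UNIFORM)
        lnl = engine.log_likelihood(2.0, classes, engine.ti.init_lengths)
        oracle = brute_force_lnl(aln, tree, 2.0, classes, UNIFORM)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_matches_brute_force_four_taxa(self, four_taxon_tree, rng):
        mat = rng.integers(0, 61, size=(4, 3))
        aln = CodonAlignment(taxa=["s1", "s2", "s3", "s4"], codons=mat)
        classes = SiteClasses(weights=np.array([1.0]), omegas=np.array([0.7]))
        engine = _Engine(aln, four_taxon_tree, pi=UNIFORM)
        lnl = engine.log_likelihood(1.5, classes, engine.ti.init_lengths)
        oracle = brute_force_lnl(aln, four_taxon_tree, 1.5, classes, UNIFORM)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_leaf_mismatch_is_error(self, four_taxon_tree):
        aln = CodonAlignment(taxa=["s1", "s2", "s3", "sX"], codons=np.zeros((4, 2), dtype=int))
        with pytest.raises(ValueError):
            _Engine(aln, four_taxon_tree)


class TestBetaDiscretisation:
    def test_class_means_average_to_beta_mean(self):
        for p, q in ((0.5, 1.5), (2.0, 2.0), (0.2, 0.8)):
            omegas = beta_class_omegas(p, q, 10)
            assert np.mean(omegas) == pytest.approx(p / (p + q), abs=1e-6)
            assert np.all((omegas > 0) & (omegas <= 1))
            assert np.all(np.diff(omegas) >= 0)

    def test_m8_class_structure(self):
        sc = m8_site_classes(0.9, 0.5, 1.5, 2.5)
        assert sc.weights.sum() == pytest.approx(1.0)
        assert sc.weights[-1] == pytest.approx(0.1)
        assert sc.omegas[-1] == 2.5

    def test_branch_site_class_structure(self):
        sc = branch_site_classes(0.7, 0.2, 0.1, 3.0)
        assert sc.weights.sum() == pytest.approx(1.0)
        assert list(sc.omegas) == [0.1, 1.0, 0.1, 1.0]
        assert list(sc.omegas_fg) == [0.1, 1.0, 3.0, 3.0]


class TestFits:
    def test_m0_recovery_loose(self, four_taxon_tree):
        sim = simulate_m0_alignment(four_taxon_tree, kappa=2.0, omega=0.2,
                                    n_codons=500, seed=21)
        fit = fit_m0(sim.alignment, four_taxon_tree)
        assert 0.1 < fit.omega < 0.3
        assert 1.0 < fit.kappa < 4.0

    def test_invariant_alignment_diagnosed(self, four_taxon_tree):
        aln = CodonAlignment(
            taxa=["s1", "s2", "s3", "s4"], codons=np.full((4, 30), 7, dtype=int)
        )
        with pytest.raises(InvariantAlignmentError):
            fit_m0(aln, four_taxon_tree)

    def test_m8_nesting_holds(self, four_taxon_tree):
        sim = simulate_codon_alignment(
            four_taxon_tree, 2.0, m8_site_classes(0.9, 0.5, 1.5, 1.0), 80, seed=3
        )
        pair = fit_m8_pair(sim.alignment, four_taxon_tree, restarts=1, maxiter=40)
        assert pair.lnL_m8 >= pair.lnL_m8a - 1e-6
        assert 0.0 <= pair.p_value <= 1.0

    def test_branch_site_detects_planted_selection(self, four_taxon_tree):
        classes = branch_site_classes(0.75, 0.15, 0.1, 6.0)
        sim = simulate_codon_alignment(
            four_taxon_tree, 2.0, classes, 400, seed=17, foreground_branch="s1"
        )
        fit = fit_branch_site(
            sim.alignment, four_taxon_tree, "s1", restarts=1, maxiter=80
        )
        assert fit.lnL_alt >= fit.lnL_null - 1e-6
        assert fit.p_value < 0.05
        assert fit.omega2 > 1.5
        # reported sites overlap the planted positive-selection sites
        if fit.selected_sites:
            truth = set(np.flatnonzero(sim.positive_sites))
            overlap = len(truth & set(fit.selected_sites)) / len(fit.selected_sites)
            assert overlap > 0.5
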