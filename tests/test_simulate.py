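"""Structured-coalescent and sequence simulation checks against closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import kstest

from gdikit import gdi, simulate
from gdikit.ctmc import IMParams
from gdikit.pairwise import jc_mismatch_prob
from gdikit.simulate import MigrationBand, SpeciesNode, SpeciesTree, SubstModel


def single_population(theta=0.01):
    return SpeciesTree(SpeciesNode("A", 0.0, theta))


class TestSpeciesTree:
    def test_validation(self):
        with pytest.raises(ValueError):
            root = SpeciesNode("AB", 0.01, 0.01)
            root.children = [SpeciesNode("A", 0.02, 0.01), SpeciesNode("B", 0.0, 0.01)]
            SpeciesTree(root)
        with pytest.raises(ValueError):
            SpeciesTree(SpeciesNode("A", 0.0, -1.0))

    def test_two_population_tree_needs_ancestral_theta(self):
        with pytest.raises(ValueError):
            simulate.two_population_tree(IMParams(0.01, 0.01, 0.01))


class TestGeneTreeSimulation:
    def test_unknown_species_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate.simulate_gene_tree(single_population(), [], {"Z": 2}, rng)

    def test_single_deme_mean_coalescent_time(self, rng):
        theta = 0.01
        tree = single_population(theta)
        times = np.array([
            simulate.simulate_gene_tree(tree, [], {"A": 2}, rng).root.time
            for _ in range(20_000)
        ])
        # pairwise coalescent time is Exp(2/theta), mean theta/2
        se = theta / 2.0 / np.sqrt(times.size)
        assert abs(times.mean() - theta / 2.0) < 3 * se

    def test_isolation_topology_frequency(self, rng):
        # two species, samples (2,1), no migration, divergence 0.22 units
        p = IMParams(0.01, 0.01, 0.22 * 0.01 / 2.0, 0.0, 0.0, theta_AB=0.01)
        tree = simulate.two_population_tree(p)
        n = 20_000
        hits = sum(
            simulate.simulate_gene_tree(tree, [], {"A": 2, "B": 1}, rng).is_clade(
                ["A1", "A2"]
            )
            for _ in range(n)
        )
        p1 = gdi.P1_no_migration(p.tau, p.theta_A)  # about 0.47
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(hits / n - p1) < 3 * se

    def test_pair_coalescence_before_tau_with_migration(self, symmetric_im, rng):
        tree = simulate.two_population_tree(symmetric_im)
        bands = simulate.im_bands(symmetric_im)
        n = 20_000
        hits = sum(
            simulate.simulate_gene_tree(tree, bands, {"A": 1, "B": 1}, rng).root.time
            < symmetric_im.tau
            for _ in range(n)
        )
        target = gdi.pair_coal_prob_before_tau(symmetric_im)  # 0.6275
        se = np.sqrt(target * (1 - target) / n)
        assert abs(hits / n - target) < 3 * se

    def test_backward_migration_direction(self, rng):
        # forward band A -> B means the *B* lineage is traced into A at rate
        # 4 M / theta_B; with no reverse band the A lineage never moves.
        p = IMParams(0.01, 0.02, 5.0, 0.0, 0.0, theta_AB=0.01)
        tree = simulate.two_population_tree(p)
        band = MigrationBand("A", "B", 5.0)
        waits = []
        for _ in range(4000):
            gt = simulate.simulate_gene_tree(tree, [band], {"A": 1, "B": 1}, rng)
            for tip in gt.tips:
                if tip.species == "A":
                    assert tip.migrations == []
                elif tip.migrations:
                    assert tip.migrations[0][1:] == ("B", "A")
                    waits.append(tip.migrations[0][0])
        rate = 4.0 * band.M / p.theta_B  # 1000 per unit time
        # first-event times below tau follow a truncated exponential
        waits = np.array(waits)
        trunc_mean = 1 / rate - p.tau * np.exp(-rate * p.tau) / -np.expm1(-rate * p.tau)
        assert abs(waits.mean() - trunc_mean) < 3 * waits.std() / np.sqrt(waits.size)

    def test_ancestral_coalescence_is_exponential(self, rng):
        # with M = 0 and samples (1,1), coalescence happens only in the
        # ancestor: (t - tau) should be Exp(2/theta_AB)
        p = IMParams(0.01, 0.01, 0.005, 0.0, 0.0, theta_AB=0.02)
        tree = simulate.two_population_tree(p)
        times = np.array([
            simulate.simulate_gene_tree(tree, [], {"A": 1, "B": 1}, rng).root.time
            for _ in range(10_000)
        ])
        assert (times > p.tau).all()
        stat = kstest(times - p.tau, "expon", args=(0, p.theta_AB / 2.0))
        assert stat.pvalue > 0.01

    def test_seeded_reproducibility(self, symmetric_im):
        tree = simulate.two_population_tree(symmetric_im)
        bands = simulate.im_bands(symmetric_im)
        nwk = [
            simulate.simulate_gene_tree(
                tree, bands, {"A": 2, "B": 1}, np.random.default_rng(42)
            ).newick()
            for _ in range(2)
        ]
        assert nwk[0] == nwk[1]


class TestJumpChainTopologyCounts:
    def test_matches_analytic_P1(self, symmetric_im, rng):
        n = 50_000
        count = simulate.simulate_topology_counts(symmetric_im, n, rng)
        p1 = gdi.prob_gene_tree_G1(symmetric_im).P1
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(count / n - p1) < 3 * se

    def test_no_migration_case(self, rng):
        p = IMParams(0.01, 0.01, 0.006, 0.0, 0.0)
        n = 50_000
        count = simulate.simulate_topology_counts(p, n, rng)
        p1 = gdi.P1_no_migration(p.tau, p.theta_A)
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(count / n - p1) < 3 * se


class TestSubstModels:
    def test_jc_constraints(self):
        with pytest.raises(ValueError):
            SubstModel("JC", kappa=3.0)
        with pytest.raises(ValueError):
            SubstModel("HKY", kappa=3.0, freqs=(0.5, 0.5, 0.5, 0.5))

    def test_transition_probs_against_expm(self):
        model = SubstModel("HKY", kappa=3.0, freqs=(0.3, 0.2, 0.3, 0.2))
        Q = model.rate_matrix()
        for t in (0.01, 0.1, 1.0):
            assert np.abs(model.transition_probs(t) - expm(Q * t)).max() < 1e-10

    def test_unit_rate_normalization(self):
        for model in (SubstModel("JC"), SubstModel("HKY", 3.0, (0.3, 0.2, 0.3, 0.2))):
            Q = model.rate_matrix()
            f = np.asarray(model.freqs)
            assert -(f * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_stationarity(self):
        model = SubstModel("HKY", kappa=3.0, freqs=(0.3, 0.2, 0.3, 0.2))
        f = np.asarray(model.freqs)
        assert np.abs(f @ model.transition_probs(0.7) - f).max() < 1e-12


class TestAlignmentSimulation:
    def test_zero_length_tree_identical_sequences(self, rng):
        a = simulate.GeneNode("x1", 0.0)
        b = simulate.GeneNode("x2", 0.0)
        root = simulate.GeneNode("r", 0.0, children=[a, b])
        aln = simulate.simulate_alignment(
            simulate.GeneTree(root), 200, SubstModel("JC"), rng
        )
        assert np.array_equal(aln["x1"], aln["x2"])

    def test_jc_pairwise_mismatch_fraction(self, rng):
        t = 0.02  # one-lineage depth; total path 2t
        a = simulate.GeneNode("x1", 0.0)
        b = simulate.GeneNode("x2", 0.0)
        root = simulate.GeneNode("r", t, children=[a, b])
        n = 100_000
        aln = simulate.simulate_alignment(
            simulate.GeneTree(root), n, SubstModel("JC"), rng
        )
        frac = (aln["x1"] != aln["x2"]).mean()
        p = jc_mismatch_prob(t)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_hky_base_composition(self, rng):
        freqs = (0.3, 0.2, 0.3, 0.2)
        a = simulate.GeneNode("x1", 0.0)
        b = simulate.GeneNode("x2", 0.0)
        root = simulate.GeneNode("r", 0.5, children=[a, b])
        n = 100_000
        aln = simulate.simulate_alignment(
            simulate.GeneTree(root), n, SubstModel("HKY", 3.0, freqs), rng
        )
        counts = np.bincount(np.concatenate([aln["x1"], aln["x2"]]), minlength=4)
        for k, f in enumerate(freqs):
            se = np.sqrt(f * (1 - f) / (2 * n))
            assert abs(counts[k] / (2 * n) - f) < 3 * se


class TestDataset:
    def test_shapes_and_determinism(self, symmetric_im):
        tree = simulate.two_population_tree(symmetric_im)
        bands = simulate.im_bands(symmetric_im)
        runs = []
        for _ in range(2):
            ds = simulate.simulate_dataset(
                tree, bands, {"A": 2, "B": 1}, 3, 50, SubstModel("JC"),
                np.random.default_rng(7),
            )
            runs.append(ds)
        assert runs[0].n_loci == 3
        assert set(runs[0].alignments[0]) == {"A1", "A2", "B1"}
        for a0, a1 in zip(runs[0].alignments, runs[1].alignments):
            for k in a0:
                assert np.array_equal(a0[k], a1[k])
        assert [g.newick() for g in runs[0].gene_trees] == [
            g.newick() for g in runs[1].gene_trees
        ]
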