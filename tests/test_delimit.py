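"""Posterior gdi, the decision rule, and the hierarchical collapse."""

import io

import numpy as np
import pytest

from gdikit import delimit
from gdikit.delimit import (
    PosteriorSample,
    Topology,
    classify,
    gdi_posterior,
    hierarchical_collapse,
    parse_posterior_table,
    point_gdi,
    synthetic_posterior,
)


def table(text: str) -> PosteriorSample:
    return parse_posterior_table(io.StringIO(text))


class TestParsing:
    def test_basic(self):
        s = table("tau_A_B theta_A\n0.01 0.02\n0.011 0.019\n0.009 0.021\n")
        assert s.n_draws == 3

    def test_column_map(self):
        s = parse_posterior_table(
            io.StringIO("t th\n0.01 0.02\n"),
            column_map={"t": "tau_A_B", "th": "theta_A"},
        )
        assert "tau_A_B" in s.table.columns

    def test_negative_theta_reports_line(self):
        with pytest.raises(ValueError, match="line 3"):
            table("tau_A_B theta_A\n0.01 0.02\n0.01 -0.5\n")

    def test_non_numeric_cell(self):
        with pytest.raises(ValueError, match="non-numeric"):
            table("tau_A_B theta_A\n0.01 oops\n")

    def test_duplicate_columns(self):
        with pytest.raises(ValueError, match="duplicate"):
            table("a a\n1 2\n")


class TestGdiPosterior:
    def test_point_mass(self):
        s = table("tau_A_B theta_A\n0.005 0.01\n0.005 0.01\n")
        post = gdi_posterior(s, "tau_A_B", theta_col="theta_A")
        assert np.allclose(post.draws, 1.0 - np.exp(-1.0))

    def test_zero_tau_gives_zero(self):
        s = table("tau_A_B theta_A\n0 0.01\n0 0.02\n")
        post = gdi_posterior(s, "tau_A_B", theta_col="theta_A")
        assert np.all(post.draws == 0.0)

    def test_theta_pair_average(self):
        s = table("tau_A_B theta_A theta_B\n0.005 0.005 0.015\n")
        post = gdi_posterior(s, "tau_A_B", theta_pair=("theta_A", "theta_B"))
        assert post.draws[0] == pytest.approx(1.0 - np.exp(-1.0))

    def test_jensen_gap(self, rng):
        spec = {
            "tau_A_B": ("lognormal", np.log(0.005), 0.5),
            "theta_A": ("lognormal", np.log(0.01), 0.5),
        }
        s = synthetic_posterior(spec, 20_000, rng)
        post = gdi_posterior(s, "tau_A_B", theta_col="theta_A")
        pt = point_gdi(s, "tau_A_B", theta_col="theta_A")
        assert post.mean != pytest.approx(pt, abs=1e-4)  # the two variants differ

    def test_posterior_mean_matches_direct_monte_carlo(self, rng):
        spec = {
            "tau_A_B": ("lognormal", np.log(0.005), 0.3),
            "theta_A": ("lognormal", np.log(0.01), 0.3),
        }
        s = synthetic_posterior(spec, 10_000, rng)
        post = gdi_posterior(s, "tau_A_B", theta_col="theta_A")
        # independent large-sample oracle for E[1 - exp(-2 tau/theta)]
        rng2 = np.random.default_rng(555)
        tau = rng2.lognormal(np.log(0.005), 0.3, 1_000_000)
        theta = rng2.lognormal(np.log(0.01), 0.3, 1_000_000)
        oracle = (1.0 - np.exp(-2 * tau / theta)).mean()
        se = post.draws.std() / np.sqrt(post.draws.size)
        assert abs(post.mean - oracle) < 3 * se

    def test_scale_equivariance(self):
        s1 = table("tau_A_B theta_A\n0.005 0.01\n0.002 0.03\n")
        scaled = s1.table * 7.5
        s2 = PosteriorSample(scaled)
        d1 = gdi_posterior(s1, "tau_A_B", theta_col="theta_A").draws
        d2 = gdi_posterior(s2, "tau_A_B", theta_col="theta_A").draws
        assert np.allclose(d1, d2)


class TestClassify:
    @pytest.mark.parametrize(
        "stat,verdict", [(0.1, "single"), (0.5, "ambiguous"), (0.9, "distinct")]
    )
    def test_verdicts(self, stat, verdict):
        assert classify(stat).verdict == verdict

    def test_monotone(self):
        order = {"single": 0, "ambiguous": 1, "distinct": 2}
        grid = np.linspace(0, 1, 101)
        ranks = [order[classify(g).verdict] for g in grid]
        assert ranks == sorted(ranks)

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify(0.5, lower=0.7, upper=0.2)


class TestTopology:
    def test_parse_and_cherries(self):
        t = Topology.from_newick("(X,((A,B),(C,D)));")
        assert t.tips == ["X", "A", "B", "C", "D"]
        assert t.cherries() == [("A", "B"), ("C", "D")]

    def test_collapse_is_nested(self):
        t = Topology.from_newick("(X,((A,B),(C,D)));")
        t2 = t.collapse(("A", "B"))
        assert "A+B" in t2.tips
        assert t2.cherries() == [("C", "D")]
        # cannot collapse a non-cherry: structure unchanged
        assert t.collapse(("A", "C")).structure == t.structure

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            Topology.from_newick("(A,B,C);")


def constant_provider(gdi_by_pair):
    """Provider mapping each cherry to a fixed 2tau/theta (hence fixed gdi)."""

    def provider(tree):
        spec = {}
        for a, b in tree.cherries():
            g = gdi_by_pair(frozenset((a, b)))
            tau = -np.log1p(-g) * 0.01 / 2.0  # invert gdi on theta = 0.01
            spec[f"tau_{a}_{b}"] = ("point", tau)
            spec[f"theta_{a}"] = ("point", 0.01)
            spec[f"theta_{b}"] = ("point", 0.01)
        return synthetic_posterior(spec, 50, np.random.default_rng(1))

    return provider


class TestHierarchicalCollapse:
    def test_two_tip_single_species(self):
        t = Topology.from_newick("(A,B);")
        trace = hierarchical_collapse(t, constant_provider(lambda p: 0.05))
        assert trace.final_species == ["A+B"]
        assert len(trace.iterations) == 1

    def test_no_collapse_when_all_distinct(self):
        t = Topology.from_newick("(X,((A,B),(C,D)));")
        trace = hierarchical_collapse(t, constant_provider(lambda p: 0.9))
        assert trace.final_species == ["X", "A", "B", "C", "D"]
        assert len(trace.iterations) == 1

    def test_stepping_stone_collapse_order(self):
        # A+B and C+D merge first, then AB+CD, then the procedure stops at
        # the root cherry (new species X vs the merged complex)
        def g(pair):
            if pair in (frozenset("AB"), frozenset("CD"), frozenset(("A+B", "C+D"))):
                return 0.05
            return 0.85

        t = Topology.from_newick("(X,((A,B),(C,D)));")
        trace = hierarchical_collapse(t, constant_provider(g))
        collapsed = [
            sorted(d.pair) for it in trace.iterations for d in it if d.collapsed
        ]
        assert collapsed == [["A", "B"], ["C", "D"], ["A+B", "C+D"]]
        assert sorted(trace.final_species) == ["A+B+C+D", "X"]

    def test_asymmetric_directions_block_collapse(self):
        # one direction single, the other not: the conservative rule keeps
        # the populations separate
        def provider(tree):
            (a, b) = tree.cherries()[0]
            return synthetic_posterior(
                {
                    f"tau_{a}_{b}": ("point", 0.004),
                    f"theta_{a}": ("point", 0.1),   # gdi ~ 0.077 -> single
                    f"theta_{b}": ("point", 0.004),  # gdi ~ 0.86 -> distinct
                },
                50,
                np.random.default_rng(2),
            )

        t = Topology.from_newick("(A,B);")
        trace = hierarchical_collapse(t, provider)
        assert trace.final_species == ["A", "B"]
        decs = trace.iterations[0][0]
        assert decs.decisions["A"].verdict == "single"
        assert decs.decisions["B"].verdict == "distinct"

    def test_terminates_within_internal_node_count(self):
        t = Topology.from_newick("((((A,B),C),D),E);")
        trace = hierarchical_collapse(t, constant_provider(lambda p: 0.0))
        assert trace.final_species == ["A+B+C+D+E"]
        assert len(trace.iterations) <= 4


class TestSyntheticPosterior:
    def test_point_mass_and_determinism(self):
        spec = {"tau_A_B": ("point", 0.01), "theta_A": ("point", 0.02)}
        a = synthetic_posterior(spec, 10, np.random.default_rng(3))
        b = synthetic_posterior(spec, 10, np.random.default_rng(3))
        assert (a.table == b.table).all().all()
        assert (a.table["tau_A_B"] == 0.01).all()

    def test_moments(self, rng):
        spec = {"theta_A": ("gamma", 4.0, 0.005)}
        s = synthetic_posterior(spec, 10_000, rng)
        draws = s.table["theta_A"].to_numpy()
        mean, sd = 4.0 * 0.005, np.sqrt(4.0) * 0.005
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(draws.size)

    def test_order_constraints(self, rng):
        spec = {
            "tau_root": ("uniform", 0.0, 0.02),
            "tau_AB": ("uniform", 0.0, 0.02),
        }
        s = synthetic_posterior(
            spec, 2000, rng, order_constraints=[("tau_root", "tau_AB")]
        )
        assert (s.table["tau_root"] >= s.table["tau_AB"]).all()

    def test_infeasible_constraints(self, rng):
        spec = {"tau_root": ("point", 0.001), "tau_AB": ("point", 0.002)}
        with pytest.raises(RuntimeError):
            synthetic_posterior(
                spec, 10, rng, order_constraints=[("tau_root", "tau_AB")]
            )
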