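import numpy as np
import pytest

from coewc import (
    EssentialSet,
    PPINetwork,
    jackknife,
    overlap_analysis,
    random_baseline,
    reference_value,
    top_k,
)
from coewc.centrality import ScoreTable


def table_from_ranking(ranking):
    """Build a ScoreTable whose ranking is exactly `ranking`."""
    n = len(ranking)
    return ScoreTable("toy", {pid: float(n - i) for i, pid in enumerate(ranking)})


class TestTopK:
    def test_perfect_prediction(self):
        t = table_from_ranking(["E1", "E2", "N1"])
        r = top_k(t, EssentialSet(frozenset({"E1", "E2"})), 2)
        assert r.true_positive_count == 2
        assert r.precision == 1.0

    def test_disjoint_essential_set(self):
        t = table_from_ranking(["A", "B"])
        r = top_k(t, EssentialSet(frozenset({"X"})), 2)
        assert r.true_positive_count == 0

    def test_k_out_of_range(self):
        t = table_from_ranking(["A", "B"])
        with pytest.raises(ValueError):
            top_k(t, EssentialSet(frozenset({"A"})), 3)


class TestJackknife:
    def test_all_essential_ranked_first(self):
        ranking = ["E1", "E2", "E3", "N1", "N2"]
        curve = jackknife(
            table_from_ranking(ranking), EssentialSet(frozenset({"E1", "E2", "E3"})), 3
        )
        assert curve.cumulative == (1, 2, 3)

    def test_no_essential_in_prefix_gives_zero_auc(self):
        curve = jackknife(
            table_from_ranking(["N1", "N2", "N3"]),
            EssentialSet(frozenset({"E9"})),
            3,
        )
        assert curve.cumulative == (0, 0, 0)
        assert curve.auc == 0.0

    def test_alternating_ranking_trapezoid_auc(self):
        # hand trapezoid sum over 3 unit intervals: 1 + 1.5 + 2 = 4.5
        curve = jackknife(
            table_from_ranking(["E1", "N1", "E2", "N2"]),
            EssentialSet(frozenset({"E1", "E2"})),
            4,
        )
        assert curve.cumulative == (1, 1, 2, 2)
        assert curve.auc == pytest.approx(4.5)

    def test_curve_is_nondecreasing_with_unit_steps(self):
        rng = np.random.default_rng(0)
        ranking = [f"P{i}" for i in rng.permutation(50)]
        ess = EssentialSet(frozenset(f"P{i}" for i in range(0, 50, 3)))
        cum = jackknife(table_from_ranking(ranking), ess, 50).cumulative
        steps = np.diff(cum)
        assert set(steps) <= {0, 1}

    def test_final_cumulative_matches_top_k(self):
        rng = np.random.default_rng(1)
        ranking = [f"P{i}" for i in rng.permutation(40)]
        ess = EssentialSet(frozenset(f"P{i}" for i in range(10)))
        t = table_from_ranking(ranking)
        assert jackknife(t, ess, 25).cumulative[-1] == top_k(t, ess, 25).true_positive_count

    def test_promoting_an_essential_never_decreases_auc(self):
        ess = EssentialSet(frozenset({"E"}))
        base = ["N1", "N2", "E", "N3"]
        aucs = []
        for pos in range(3, -1, -1):
            ranking = [p for p in base if p != "E"]
            ranking.insert(pos, "E")
            aucs.append(jackknife(table_from_ranking(ranking), ess, 4).auc)
        assert aucs == sorted(aucs)


class TestRandomBaseline:
    @pytest.fixture
    def net(self):
        return PPINetwork(
            edges=[(f"P{i}", f"P{i+1}") for i in range(99)]
        )

    def test_number_of_curves_and_reproducibility(self, net):
        ess = EssentialSet(frozenset(f"P{i}" for i in range(30)))
        a = random_baseline(net, ess, 50, n_shuffles=10, seed=42)
        b = random_baseline(net, ess, 50, n_shuffles=10, seed=42)
        assert len(a) == 10
        assert [c.cumulative for c in a] == [c.cumulative for c in b]

    def test_different_seed_differs(self, net):
        ess = EssentialSet(frozenset(f"P{i}" for i in range(30)))
        a = random_baseline(net, ess, 50, n_shuffles=5, seed=1)
        b = random_baseline(net, ess, 50, n_shuffles=5, seed=2)
        assert [c.cumulative for c in a] != [c.cumulative for c in b]

    def test_mean_curve_matches_hypergeometric_expectation(self, net):
        """E[cumulative at rank r] = r·K/N for a uniform shuffle."""
        K, N, shuffles = 30, 100, 200
        ess = EssentialSet(frozenset(f"P{i}" for i in range(K)))
        curves = random_baseline(net, ess, N, n_shuffles=shuffles, seed=0)
        cum = np.array([c.cumulative for c in curves], dtype=float)
        mean = cum.mean(axis=0)
        for r in (10, 25, 50, 75, 90):
            expect = r * K / N
            sd = np.sqrt(
                r * (K / N) * (1 - K / N) * (N - r) / (N - 1)
            )
            assert abs(mean[r - 1] - expect) <= 3 * sd / np.sqrt(shuffles)


class TestOverlapAnalysis:
    def test_identical_rankings(self):
        t = table_from_ranking(["A", "B", "C"])
        rep = overlap_analysis(t, t, EssentialSet(frozenset({"A"})), 3)
        assert rep.common_count == 3
        assert not rep.only_a and not rep.only_b

    def test_disjoint_top_k(self):
        a = table_from_ranking(["A1", "A2", "B1", "B2"])
        b = table_from_ranking(["B1", "B2", "A1", "A2"])
        rep = overlap_analysis(a, b, EssentialSet(frozenset({"A1"})), 2)
        assert rep.common_count == 0

    def test_toy_essential_fractions(self):
        a = table_from_ranking(["p1", "p2", "p3", "p4"])
        b = table_from_ranking(["p2", "p3", "p4", "p1"])
        rep = overlap_analysis(a, b, EssentialSet(frozenset({"p1"})), 3)
        assert rep.only_a == frozenset({"p1"})
        assert rep.only_b == frozenset({"p4"})
        assert rep.essential_fraction_only_a == 1.0
        assert rep.essential_fraction_only_b == 0.0
        # partition identity: |common| + |only_a| = k
        assert rep.common_count + len(rep.only_a) == 3

    def test_symmetry_under_swap(self):
        a = table_from_ranking(["x", "y", "z", "w"])
        b = table_from_ranking(["y", "w", "x", "z"])
        ess = EssentialSet(frozenset({"z"}))
        fwd = overlap_analysis(a, b, ess, 2)
        rev = overlap_analysis(b, a, ess, 2)
        assert fwd.only_a == rev.only_b
        assert fwd.only_b == rev.only_a
        assert fwd.essential_fraction_only_a == rev.essential_fraction_only_b


class TestReferenceValue:
    def test_extremes_and_tie_passthrough(self):
        t = ScoreTable("m", {"a": 5.0, "b": 4.0, "c": 4.0, "d": 1.0})
        assert reference_value(t, 1) == 5.0
        assert reference_value(t, 4) == 1.0
        assert reference_value(t, 3) == 4.0

    def test_out_of_range(self):
        t = ScoreTable("m", {"a": 1.0})
        with pytest.raises(ValueError):
            reference_value(t, 2)
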