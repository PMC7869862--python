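import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxcyto.histocyto import (
    Gate,
    GateCondition,
    apply_gate,
    compare_means_welch,
    compare_volumes_mwu,
    population_frequencies,
    positional_export,
)


@pytest.fixture
def table():
    return pd.DataFrame(
        {
            "object_id": [1, 2, 3],
            "x_um": [1.0, 2.0, 3.0],
            "y_um": [4.0, 5.0, 6.0],
            "shortest_distance_um": [-1.0, 10.0, 30.0],
            "population": ["within", "surrounding", "peripheral"],
        }
    )


class TestApplyGate:
    def test_population_gate(self, table):
        g = Gate("within", [GateCondition("population", "==", "within")])
        assert len(apply_gate(table, g)) == 1

    def test_tautological_gate_is_identity(self, table):
        g = Gate("all", [])
        pd.testing.assert_frame_equal(apply_gate(table, g), table)

    def test_contradictory_gate_empty_no_error(self, table):
        g = Gate("none", [GateCondition("shortest_distance_um", "<", -100.0)])
        assert len(apply_gate(table, g)) == 0

    def test_unknown_column(self, table):
        g = Gate("bad", [GateCondition("nope", "<", 1)])
        with pytest.raises(KeyError, match="nope"):
            apply_gate(table, g)

    def test_interval_condition(self, table):
        g = Gate("band", [GateCondition("shortest_distance_um", "in", (0.5, 20.0))])
        assert apply_gate(table, g)["object_id"].tolist() == [2]

    def test_gate_dict_round_trip(self):
        g = Gate("x", [GateCondition("a", "<", 1.0)], parent="p")
        assert Gate.from_dict(g.to_dict()) == g


class TestFrequencies:
    def test_parent_relative_percentage(self):
        df = pd.DataFrame({"v": np.arange(100)})
        gates = [
            Gate("parent", [GateCondition("v", ">=", 0)]),
            Gate("child", [GateCondition("v", "<", 35)], parent="parent"),
        ]
        out = population_frequencies(df, gates).set_index("gate")
        assert out.loc["child", "frequency_pct"] == pytest.approx(35.0)
        assert out.loc["child", "parent_count"] == 100

    def test_empty_parent_undefined_marker(self):
        df = pd.DataFrame({"v": [1.0, 2.0]})
        gates = [
            Gate("none", [GateCondition("v", ">", 100)]),
            Gate("sub", [GateCondition("v", ">", 0)], parent="none"),
        ]
        out = population_frequencies(df, gates).set_index("gate")
        assert np.isnan(out.loc["sub", "frequency_pct"])
        assert out.loc["sub", "count"] == 0

    def test_cyclic_tree_rejected(self):
        gates = [Gate("a", parent="b"), Gate("b", parent="a")]
        with pytest.raises(ValueError, match="cyclic"):
            population_frequencies(pd.DataFrame({"v": [1]}), gates)

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            population_frequencies(pd.DataFrame({"v": [1]}), [Gate("a", parent="zz")])

    def test_sibling_conservation(self):
        """Mutually exclusive, exhaustive siblings sum exactly to parent."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"d": rng.uniform(-5, 40, 333)})
        gates = [
            Gate("gated", [GateCondition("d", "<=", 20.0)]),
            Gate("within", [GateCondition("d", "<", 0.5)], parent="gated"),
            Gate("surrounding", [GateCondition("d", "in", (0.5, 20.0))], parent="gated"),
        ]
        out = population_frequencies(df, gates).set_index("gate")
        assert out.loc["within", "count"] + out.loc["surrounding", "count"] \
            == out.loc["gated", "count"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"d": rng.uniform(0, 10, 50)})
        gates = [Gate("g", [GateCondition("d", "<", 5.0)])]
        a = population_frequencies(df, gates)
        b = population_frequencies(df.sample(frac=1, random_state=2), gates)
        pd.testing.assert_frame_equal(a, b)


class TestPositionalExport:
    def test_one_row_per_object_per_gate(self, table):
        g = Gate("all", [])
        out = positional_export(table, [g])
        assert len(out) == 3
        assert set(out.columns) == {"object_id", "x_um", "y_um", "gate"}

    def test_object_in_two_sibling_gates_appears_twice(self, table):
        g1 = Gate("a", [GateCondition("shortest_distance_um", "<", 15.0)])
        g2 = Gate("b", [GateCondition("shortest_distance_um", "<", 15.0)])
        out = positional_export(table, [g1, g2])
        assert (out["object_id"] == 1).sum() == 2

    def test_missing_centroids_rejected(self):
        with pytest.raises(KeyError):
            positional_export(pd.DataFrame({"a": [1]}), [Gate("g", [])])


def mwu_enumeration_oracle(a, b):
    """Brute-force two-tailed MWU p by enumerating all C(n1+n2, n1) group
    assignments of the pooled sample (tie-free data only).  Counting
    arrangements with min(U, U') <= observed min(U, U') covers both tails
    at once, so no doubling is applied."""
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)

    def u_of(ga, gb):
        return sum(x > y for x in ga for y in gb)

    u_small_obs = min(u_of(a, b), n1 * n2 - u_of(a, b))
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = u_of(ga, gb)
        if min(u, n1 * n2 - u) <= u_small_obs:
            hits += 1
        total += 1
    return min(1.0, hits / total)


class TestMannWhitney:
    def test_textbook_example(self):
        out = compare_volumes_mwu([1, 2, 3], [4, 5, 6])
        assert out["U"] == 0
        assert out["p_two_tailed"] == pytest.approx(0.100, abs=1e-9)
        assert out["method"] == "exact"

    def test_identical_groups_p_near_one(self):
        out = compare_volumes_mwu([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p_two_tailed"] >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_volumes_mwu([], [1.0])

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_exact_path_matches_enumeration_oracle(self, data):
        n1 = data.draw(st.integers(1, 5))
        n2 = data.draw(st.integers(1, min(5, 10 - n1)))
        values = data.draw(
            st.lists(st.integers(0, 10_000), min_size=n1 + n2, max_size=n1 + n2,
                     unique=True)
        )
        a, b = values[:n1], values[n1:]
        got = compare_volumes_mwu(a, b)
        assert got["method"] == "exact"
        assert got["p_two_tailed"] == pytest.approx(mwu_enumeration_oracle(a, b))

    def test_shifted_distributions_power(self):
        """Planted stochastic dominance at n=50 is detected in >=95% of
        seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, 50)
            b = rng.normal(1.0, 1.0, 50)
            if compare_volumes_mwu(a, b)["p_two_tailed"] < 0.01:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_normal_path_with_ties(self):
        a = [1.0, 1.0, 2.0, 2.0, 3.0] * 3
        b = [2.0, 3.0, 3.0, 4.0, 4.0] * 3
        out = compare_volumes_mwu(a, b)
        assert out["method"] == "normal"
        assert 0.0 < out["p_two_tailed"] <= 1.0


class TestWelch:
    def test_equal_groups(self):
        out = compare_means_welch([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert out["t"] == 0.0
        assert out["p_two_tailed"] == pytest.approx(1.0)

    def test_shifted_group_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]
        out = compare_means_welch(a, b)
        # closed form: t = -10 / sqrt(2 * (5/3) / 4), df = 6
        expected_t = -10.0 / np.sqrt(2 * (5.0 / 3.0) / 4)
        assert out["t"] == pytest.approx(expected_t)
        assert out["df"] == pytest.approx(6.0)
        assert out["p_two_tailed"] < 0.01

    def test_minimal_n2_finite_df(self):
        out = compare_means_welch([1.0, 2.0], [5.0, 7.0])
        assert np.isfinite(out["df"]) and out["df"] > 0

    def test_degenerate_variance_both_groups(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_means_welch([1.0, 1.0], [2.0, 2.0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_means_welch([1.0], [2.0, 3.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 13), rng.normal(0.4, 2, 9)
        from scipy import stats as sps

        ref = sps.ttest_ind(a, b, equal_var=False)
        out = compare_means_welch(a, b)
        assert out["t"] == pytest.approx(ref.statistic)
        assert out["p_two_tailed"] == pytest.approx(ref.pvalue)
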