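"""Jonckheere-Terpstra statistic, exact/permutation p-values, step-down TNZ."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoneutral.trend import (
    NoTnzDetectedError,
    TemperatureGroups,
    jt_exact_p,
    jt_permutation_p,
    jt_statistic,
    max_pair_count,
    step_down_tnz,
)


def brute_force_jt(groups):
    """Plain double loop over cross-group value pairs (independent oracle)."""
    j = 0.0
    vals = [v for _, v in sorted(groups, key=lambda g: g[0])]
    for a, b in itertools.combinations(vals, 2):
        for x in a:
            for y in b:
                j += 1.0 if y > x else (0.5 if y == x else 0.0)
    return j


def brute_force_exact_p(groups, alternative="increasing"):
    """Exact p by enumerating every permutation of the pooled values
    (multiplicity-correct for ties; independent of the package's
    combination recursion)."""
    vals = [np.asarray(v, float) for _, v in sorted(groups, key=lambda g: g[0])]
    if alternative == "decreasing":
        vals = vals[::-1]
    sizes = [len(v) for v in vals]
    pooled = np.concatenate(vals)

    def stat(pool):
        bounds = np.cumsum([0] + sizes)
        gs = [(i, pool[bounds[i]:bounds[i + 1]]) for i in range(len(sizes))]
        return brute_force_jt(gs)

    obs = stat(pooled)
    count = total = 0
    for perm in itertools.permutations(pooled):
        total += 1
        if stat(np.array(perm)) >= obs - 1e-9:
            count += 1
    return count / total


small_groups = st.lists(
    st.lists(st.integers(0, 5), min_size=1, max_size=3),
    min_size=2, max_size=3,
).map(lambda gs: [(26.0 + 2 * i, v) for i, v in enumerate(gs)])


class TestStatistic:
    @pytest.mark.parametrize(
        "groups,expected",
        [
            ([(26, [1, 2]), (28, [3, 4])], 4.0),       # complete separation
            ([(26, [3, 4]), (28, [1, 2])], 0.0),       # complete reversal
            ([(26, [1, 3]), (28, [2, 4])], 3.0),
            ([(26, [1, 2]), (28, [2, 3])], 3.5),       # one tie at 1/2
        ],
    )
    def test_known_pair_counts(self, groups, expected):
        assert jt_statistic(groups) == expected
        assert jt_statistic(groups) == brute_force_jt(groups)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            jt_statistic([(26, [1, 2])])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_groups)
    def test_matches_brute_force_and_bounds(self, groups):
        j = jt_statistic(groups)
        assert j == brute_force_jt(groups)
        assert 0.0 <= j <= max_pair_count(groups)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(small_groups)
    def test_increasing_plus_decreasing_identity(self, groups):
        # for tie-free data J_inc + J_dec equals the number of cross pairs
        tiefree = [(ta, [10 * i + r for r, x in enumerate(v)])
                   for i, (ta, v) in enumerate(groups)]
        total = max_pair_count(tiefree)
        assert jt_statistic(tiefree, "increasing") + \
            jt_statistic(tiefree, "decreasing") == total


class TestExactP:
    @pytest.mark.parametrize(
        "groups,expected",
        [
            ([(26, [1.0]), (28, [2.0])], 0.5),
            ([(26, [1.0]), (28, [2.0]), (30, [3.0])], 1 / 6),
        ],
    )
    def test_tiny_enumerations(self, groups, expected):
        res = jt_exact_p(groups)
        assert res.p_value == pytest.approx(expected)
        assert res.method == "exact"

    def test_all_identical_values_give_p_one(self):
        assert jt_exact_p([(26, [2, 2]), (28, [2]), (30, [2, 2])]).p_value == 1.0

    def test_matches_permutation_enumeration_oracle(self, rng):
        for _ in range(10):
            sizes = rng.integers(1, 3, size=int(rng.integers(2, 4)))
            groups = [(26.0 + 2 * i, rng.integers(0, 4, size=s).tolist())
                      for i, s in enumerate(sizes)]
            alt = rng.choice(["increasing", "decreasing"])
            assert jt_exact_p(groups, alt).p_value == pytest.approx(
                brute_force_exact_p(groups, alt))

    def test_arrangement_cap(self):
        groups = [(26, list(range(10))), (28, list(range(10)))]
        with pytest.raises(ValueError, match="cap"):
            jt_exact_p(groups, max_arrangements=100)


class TestPermutationP:
    def test_deterministic_under_seed(self):
        groups = [(26, [1.0, 2.0]), (28, [1.5, 2.5]), (30, [3.0])]
        a = jt_permutation_p(groups, n_perm=500, seed=7)
        b = jt_permutation_p(groups, n_perm=500, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic

    def test_invariant_to_within_group_order(self):
        a = jt_permutation_p([(26, [3.0, 1.0, 2.0]), (28, [5.0, 4.0])],
                             n_perm=500, seed=7)
        b = jt_permutation_p([(26, [1.0, 2.0, 3.0]), (28, [4.0, 5.0])],
                             n_perm=500, seed=7)
        assert a.p_value == b.p_value

    def test_reversed_data_has_large_p(self):
        groups = [(26, [4.0, 5.0]), (28, [2.0, 3.0]), (30, [0.0, 1.0])]
        assert jt_permutation_p(groups, "increasing",
                                n_perm=999, seed=1).p_value >= 0.5

    def test_converges_to_exact(self):
        groups = [(26, [1.0]), (28, [2.0]), (30, [3.0])]
        res = jt_permutation_p(groups, n_perm=100_000, seed=3)
        pe = 1 / 6
        tol = 3 * np.sqrt(pe * (1 - pe) / 100_000) + 2 / 100_001
        assert abs(res.p_value - pe) <= tol

    def test_add_one_estimator_never_zero(self):
        groups = [(26, [1.0, 2.0]), (28, [3.0, 4.0]), (30, [5.0, 6.0])]
        res = jt_permutation_p(groups, n_perm=200, seed=0)
        assert res.p_value >= 1 / 201


def table_from(groups):
    rows = [{"ta_c": ta, "msrmr": x} for ta, v in groups for x in v]
    return pd.DataFrame(rows)


class TestStepDown:
    def test_flat_data_spans_design_with_boundary_flags(self, rng):
        groups = [(float(t), rng.normal(1.0, 0.1, 8).tolist())
                  for t in (20, 24, 28, 32, 36)]
        est = step_down_tnz(groups, min_group_n=5, n_perm=999, seed=11)
        assert est.lct_c == 20.0 and est.uct_c == 36.0
        assert est.lct_flag == "boundary-of-design"
        assert est.uct_flag == "boundary-of-design"
        # a single non-significant test on each side
        assert [s.side for s in est.steps] == ["upper", "lower"]

    def test_v_curve_boundaries_recovered(self):
        # steep, low-noise V: the boundary search must stop exactly at the
        # plateau edges
        rng = np.random.default_rng(1)

        def vals(mean):
            return rng.normal(mean, 0.02, 10).tolist()
        groups = [(20.0, vals(1.8)), (24.0, vals(1.4)), (26.0, vals(1.0)),
                  (28.0, vals(1.0)), (30.0, vals(1.0)), (32.0, vals(1.5)),
                  (34.0, vals(2.0))]
        est = step_down_tnz(groups, min_group_n=5, n_perm=1999, seed=5)
        assert (est.lct_c, est.uct_c) == (26.0, 30.0)
        assert est.lct_flag == "interior" and est.uct_flag == "interior"

    def test_min_group_n_filter_defines_qualifying_set(self):
        # reproductive-style design: only the four n=12 temperatures qualify,
        # and with the lowest mean at 32 the first upper test is 32...33
        rng = np.random.default_rng(2)

        def g(t, n, mean):
            return (float(t), rng.normal(mean, 0.05, n).tolist())
        groups = [g(20, 4, 1.6), g(25, 4, 1.4), g(26, 4, 1.3),
                  g(28, 12, 1.20), g(30, 12, 1.18), g(32, 12, 1.10),
                  g(33, 12, 1.11), g(34, 4, 1.4), g(35, 4, 1.5), g(37, 4, 1.7)]
        est = step_down_tnz(groups, min_group_n=5, n_perm=999, seed=2)
        tested = sorted({t for s in est.steps for t in s.temps})
        assert set(tested) <= {28.0, 30.0, 32.0, 33.0}
        assert est.steps[0].side == "upper"
        assert est.steps[0].temps == [32.0, 33.0]
        assert est.uct_c == 33.0 and est.uct_flag == "boundary-of-design"

    def test_exhausted_loop_raises_with_trail(self, rng):
        groups = [(float(t), (t + rng.normal(0, 0.01, 8)).tolist())
                  for t in (26, 28, 30)]
        with pytest.raises(NoTnzDetectedError) as exc:
            step_down_tnz(groups, min_group_n=5, n_perm=999, seed=3)
        assert len(exc.value.steps) >= 2

    def test_too_few_qualifying_groups_rejected(self):
        groups = [(26.0, [1.0] * 6), (28.0, [1.0] * 6), (30.0, [1.0] * 2)]
        with pytest.raises(ValueError, match="three qualifying"):
            step_down_tnz(groups, min_group_n=5)

    def test_invariant_to_record_order(self, rng):
        table = table_from([(float(t), rng.normal(1.0, 0.2, 8).tolist())
                            for t in (24, 28, 32, 36)])
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = step_down_tnz(TemperatureGroups.from_table(table),
                          min_group_n=5, n_perm=499, seed=9)
        b = step_down_tnz(TemperatureGroups.from_table(shuffled),
                          min_group_n=5, n_perm=499, seed=9)
        assert (a.lct_c, a.uct_c) == (b.lct_c, b.uct_c)
        assert [s.result.p_value for s in a.steps] == \
            [s.result.p_value for s in b.steps]
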