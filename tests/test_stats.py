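import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nirsae as na
from nirsae.io import CohortManifest
from nirsae.stats import UndefinedStatisticError


def exact_mw_enumeration(a, b):
    """Brute-force Mann-Whitney: U and the exact two-sided p by enumerating
    all C(n+m, n) assignments of the pooled values to the two labels."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    observed = u_stat(a, b)
    mean_u = n * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(xs, ys) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return observed, count / total


def cliffs_delta_loops(a, b):
    greater = sum(1 for x in a for y in b if x > y)
    less = sum(1 for x in a for y in b if x < y)
    return (greater - less) / (len(a) * len(b))


class TestSelectWindowSize:
    def test_reported_sweep_selects_20(self):
        table = na.WindowSweepTable(
            rows=((15, 0.04151, 0.11382), (20, 0.03002, 0.09045), (25, 0.03590, 0.10850))
        )
        assert na.select_window_size(table) == 20

    def test_single_row(self):
        assert na.select_window_size(na.WindowSweepTable(rows=((10, 0.5, 0.9),))) == 10

    def test_tie_takes_smallest(self):
        table = na.WindowSweepTable(rows=((20, 0.1, 0.3), (15, 0.2, 0.3), (25, 0.1, 0.4)))
        assert na.select_window_size(table) == 15

    def test_duplicate_sizes_rejected(self):
        with pytest.raises(ValueError):
            na.WindowSweepTable(rows=((15, 0.1, 0.2), (15, 0.1, 0.3)))


class TestRoiPool:
    def _prov(self, subjects, tasks):
        return pd.DataFrame({"subject_id": subjects, "task": tasks, "start": 0})

    def test_constant_errors_pool_to_constant(self):
        errors = np.full((4, 3), 0.2)
        prov = self._prov(["S01", "S01", "S02", "S02"], ["improv"] * 4)
        pooled = na.roi_pool(errors, prov, [2], [1, 2, 3])
        assert set(pooled) == {"S01", "S02"}
        assert all(np.allclose(v, 0.2) for v in pooled.values())

    def test_roi_average_of_two_channels(self):
        errors = np.array([[0.1, 0.5, 0.3]])
        prov = self._prov(["S01"], ["improv"])
        pooled = na.roi_pool(errors, prov, [1, 3], [1, 2, 3])
        assert pooled["S01"][0] == pytest.approx(0.2)

    def test_invalid_channel_rejected(self):
        with pytest.raises(KeyError, match="99"):
            na.roi_pool(np.ones((1, 3)), self._prov(["S01"], ["improv"]), [99], [1, 2, 3])

    def test_subject_without_task_windows_rejected(self):
        errors = np.ones((2, 2))
        prov = self._prov(["S01", "S02"], ["improv", "score"])
        with pytest.raises(ValueError, match="S02"):
            na.roi_pool(errors, prov, [1], [1, 2])


class TestRobustSummaries:
    def test_constant_e_gives_unit_summaries(self):
        summ = na.robust_summaries(np.full(20, math.e))
        assert summ.median_log_mse == pytest.approx(1.0, abs=1e-12)
        assert summ.trimmed_mean_log_mse == pytest.approx(1.0, abs=1e-12)
        assert summ.p90_log_mse == pytest.approx(1.0, abs=1e-12)

    def test_trimmed_mean_drops_one_per_tail(self):
        errors = np.exp(np.arange(1.0, 11.0))
        summ = na.robust_summaries(errors)
        assert summ.trimmed_mean_log_mse == pytest.approx(5.5, abs=1e-9)

    def test_p90_inclusive_linear_interpolation(self):
        errors = np.exp(np.arange(1.0, 11.0))
        summ = na.robust_summaries(errors)
        assert summ.p90_log_mse == pytest.approx(9.1, abs=1e-9)

    def test_zero_errors_guarded_by_epsilon(self):
        summ = na.robust_summaries(np.zeros(5))
        assert np.isfinite(summ.median_log_mse)
        assert summ.median_log_mse == pytest.approx(math.log(1e-12))

    def test_median_le_p90_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            errors = rng.exponential(size=rng.integers(3, 40))
            summ = na.robust_summaries(errors)
            assert summ.median_log_mse <= summ.p90_log_mse + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            na.robust_summaries(np.array([]))


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        res = na.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        res = na.welch_t_test(a, b)
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se, abs=1e-9)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            na.welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestMannWhitney:
    def test_complete_dominance(self):
        res = na.mann_whitney_test([3.0, 4.0], [1.0, 2.0])
        assert res.statistic == 4

    def test_singleton_tie_half_count(self):
        res = na.mann_whitney_test([1.0], [1.0])
        assert res.statistic == 0.5
        assert 0 <= res.p_value <= 1

    def test_exact_p_matches_enumeration_5v4(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=5)
        b = rng.normal(size=4)
        res = na.mann_whitney_test(a, b)
        u, p = exact_mw_enumeration(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(2, 5))
    def test_exact_p_matches_enumeration_property(self, seed, n, m):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n), rng.normal(size=m)
        res = na.mann_whitney_test(a, b)
        u, p = exact_mw_enumeration(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-12)


class TestPermutation:
    def test_identical_multisets_give_high_p(self):
        res = na.permutation_test([1.0, 2.0, 3.0], [3.0, 1.0, 2.0], n_iter=500, seed=0)
        assert res.p_value >= 0.99

    def test_single_iteration_p_in_half_or_one(self):
        for seed in range(6):
            res = na.permutation_test([1.0, 5.0], [2.0, 3.0], n_iter=1, seed=seed)
            assert res.p_value in (0.5, 1.0)

    def test_add_one_estimator_never_zero(self):
        res = na.permutation_test(
            np.arange(10.0) + 100, np.arange(10.0), n_iter=200, seed=1
        )
        assert res.p_value == pytest.approx(1 / 201)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(1, 1, 8), rng.normal(0, 1, 5)
        p_ab = na.permutation_test(a, b, n_iter=4000, seed=2).p_value
        p_ba = na.permutation_test(b, a, n_iter=4000, seed=2).p_value
        assert p_ab == pytest.approx(p_ba, abs=0.02)

    def test_median_statistic_supported(self):
        res = na.permutation_test([1.0, 2.0, 9.0], [1.0, 2.0, 3.0],
                                  statistic="median_diff", n_iter=99, seed=0)
        assert res.method == "permutation_median_diff"

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            na.permutation_test([1.0, 2.0], [3.0, 4.0], statistic="variance_ratio")


class TestEffectSizes:
    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        b = a - 1.0  # identical shape, shifted: pooled sd = sd(a), mean diff = 1
        es = na.effect_sizes(a, b)
        assert es.cohens_d == pytest.approx(1.0 / a.std(ddof=1), abs=1e-9)

    def test_delta_bounds(self):
        assert na.effect_sizes([3.0, 4.0], [1.0, 2.0]).cliffs_delta == 1.0
        assert na.effect_sizes([1.0, 2.0], [3.0, 4.0]).cliffs_delta == -1.0

    def test_delta_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(size=16)
            b = rng.normal(size=6)
            es = na.effect_sizes(a, b)
            assert es.cliffs_delta == pytest.approx(cliffs_delta_loops(a, b), abs=1e-12)

    def test_delta_u_identity_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            u = na.mann_whitney_test(a, b).statistic
            delta = na.effect_sizes(a, b).cliffs_delta
            assert delta == pytest.approx(2 * u / (len(a) * len(b)) - 1, abs=1e-12)

    def test_zero_pooled_sd_raises_but_carries_delta(self):
        with pytest.raises(UndefinedStatisticError) as exc:
            na.effect_sizes([1.0, 1.0], [0.0, 0.0])
        assert exc.value.cliffs_delta == 1.0


def _manifest(groups):
    rows = [
        {"subject_id": sid, "group": grp, "task": task}
        for sid, grp in groups.items()
        for task in ("score", "improv")
    ]
    return CohortManifest(pd.DataFrame(rows))


class TestCompareGroups:
    def _inputs(self, effect=0.0, n_windows=30, seed=0):
        rng = np.random.default_rng(seed)
        groups = {f"P{i:02d}": "pianist" for i in range(6)}
        groups.update({f"N{i:02d}": "non_pianist" for i in range(4)})
        errors, rows = [], []
        for sid, grp in groups.items():
            shift = effect if grp == "pianist" else 0.0
            errors.append(np.exp(rng.normal(shift, 1.0, size=(n_windows, 2))))
            rows.extend({"subject_id": sid, "task": "improv", "start": k} for k in range(n_windows))
        return np.concatenate(errors), pd.DataFrame(rows), _manifest(groups)

    def test_identical_groups_give_zero_effect(self):
        groups = {f"P{i}": "pianist" for i in range(3)}
        groups.update({f"N{i}": "non_pianist" for i in range(3)})
        errors, rows = [], []
        shared = np.exp(np.random.default_rng(1).normal(size=(10, 2)))
        for sid in groups:
            errors.append(shared)
            rows.extend({"subject_id": sid, "task": "improv", "start": k} for k in range(10))
        with pytest.raises(UndefinedStatisticError):
            # identical per-subject summaries -> zero pooled SD -> d undefined
            na.compare_groups(np.concatenate(errors), pd.DataFrame(rows), _manifest(groups),
                              roi_channels=[1, 2], n_permutations=50)

    def test_planted_shift_detected(self):
        errors, prov, manifest = self._inputs(effect=2.0)
        comp = na.compare_groups(errors, prov, manifest, roi_channels=[1, 2],
                                 n_permutations=2000, seed=0)
        assert comp.tests[("p90_log_mse", "permutation")].p_value < 0.05
        assert comp.effects["p90_log_mse"].cohens_d > 1.0

    def test_null_inputs_give_unremarkable_p(self):
        errors, prov, manifest = self._inputs(effect=0.0, seed=3)
        comp = na.compare_groups(errors, prov, manifest, roi_channels=[1, 2],
                                 n_permutations=500, seed=0)
        assert all(0 <= r.p_value <= 1 for r in comp.tests.values())
        assert len(comp.tests) == 9
        assert set(comp.summaries.columns) >= {"subject_id", "group", "p90_log_mse"}

    def test_json_and_text_render(self):
        errors, prov, manifest = self._inputs(effect=1.0)
        comp = na.compare_groups(errors, prov, manifest, roi_channels=[1, 2],
                                 n_permutations=100, seed=0)
        payload = comp.to_json()
        assert "p90_log_mse|welch_t" in payload
        assert "Cliff's delta" in comp.to_text()


class TestRankChannels:
    def _map(self, values):
        rows = [
            {"subject_id": "S01", "task": "improv", "channel": ch, "mean_error": v}
            for ch, v in values.items()
        ]
        return na.ChannelErrorMap(table=pd.DataFrame(rows), channel_ids=tuple(values))

    def test_constant_map_orders_by_id(self):
        ranking = na.rank_channels(self._map({c: 0.3 for c in range(1, 16)}))
        assert ranking["channel"].tolist() == list(range(1, 16))

    def test_doubled_channel_ranks_first(self):
        values = {c: 0.2 for c in range(1, 16)}
        values[7] = 0.4
        ranking = na.rank_channels(self._map(values))
        assert ranking["channel"].iloc[0] == 7
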