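import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import hoconn as hc
import oracles
from conftest import make_tset


class TestIccOneway:
    def test_distinct_constant_rows_perfect(self):
        table = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0], [9.0, 9.0, 9.0]])
        assert hc.icc_oneway(table) == pytest.approx(1.0)

    def test_negative_estimate_clamped_to_zero(self):
        # subject means identical -> MS_b = 0 < MS_w -> raw ICC negative
        table = np.array([[1.0, 2.0], [2.0, 1.0], [0.0, 3.0]])
        assert oracles.anova_icc(table) < 0
        assert hc.icc_oneway(table) == 0.0

    def test_hand_anova_example(self):
        # MS_b = 8, MS_w = 0.5 -> ICC = 7.5/8.5
        table = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        assert hc.icc_oneway(table) == pytest.approx(7.5 / 8.5)
        assert oracles.anova_icc(table) == pytest.approx(7.5 / 8.5)

    def test_zero_total_variance_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(hc.icc_oneway(np.full((4, 3), 2.5)))
        assert "zero total variance" in caplog.text

    def test_nan_rows_dropped(self, caplog):
        table = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [np.nan, 1.0]])
        with caplog.at_level("WARNING"):
            assert hc.icc_oneway(table) == pytest.approx(7.5 / 8.5)
        assert "dropped 1" in caplog.text

    def test_too_few_complete_rows_undefined(self):
        table = np.array([[1.0, 2.0], [np.nan, 4.0], [np.nan, 6.0]])
        assert np.isnan(hc.icc_oneway(table))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_hand_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.standard_normal((int(rng.integers(3, 12)), int(rng.integers(2, 8))))
        expected = max(oracles.anova_icc(table), 0.0)
        assert hc.icc_oneway(table) == pytest.approx(expected, abs=1e-12)

    @given(
        hnp.arrays(
            float,
            (5, 4),
            elements=st.floats(-10, 10, allow_nan=False),
        ),
        st.floats(-100, 100),
        st.floats(0.1, 50),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_and_scale_invariance(self, table, shift, scale):
        base = hc.icc_oneway(table)
        moved = hc.icc_oneway(table * scale + shift)
        if np.isnan(base):
            assert np.isnan(moved)
        else:
            assert moved == pytest.approx(base, abs=1e-8)

    def test_estimator_recovers_known_variance_ratios(self):
        """Tables with sigma_b^2 : sigma_w^2 = 3:1 imply ICC 0.75; with 1:4,
        ICC 0.2. Mean estimate over 500 replicates lands within 0.05."""
        rng = np.random.default_rng(7)
        for sb2, sw2, target in ((3.0, 1.0, 0.75), (1.0, 4.0, 0.2)):
            ests = []
            for _ in range(500):
                b = rng.normal(0, np.sqrt(sb2), size=(25, 1))
                w = rng.normal(0, np.sqrt(sw2), size=(25, 7))
                ests.append(hc.icc_oneway(b + w))
            assert abs(np.mean(ests) - target) < 0.05

    def test_session_noise_monotonically_degrades_icc(self):
        """Adding ever-larger session noise to a fixed subject structure
        drives the mean ICC down monotonically."""
        rng = np.random.default_rng(3)
        b = rng.normal(0, 1.0, size=(25, 1))
        noise = rng.standard_normal((25, 7))
        means = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            means.append(np.mean([hc.icc_oneway(b + scale * noise)]))
        assert all(a > b_ for a, b_ in zip(means, means[1:]))


class TestIccMap:
    def test_subject_structure_without_session_noise_is_perfect(self, rng):
        mats = []
        for s in range(3):
            m = rng.standard_normal((4, 4))
            m = (m + m.T) / 2
            cm = hc.ConnectivityMatrix(np.clip(m, -1, 1), "LOFC")
            mats.append([cm, cm])  # identical across sessions
        rmap = hc.icc_map(mats)
        vals = rmap.connection_values()
        np.testing.assert_allclose(vals, 1.0)

    def test_pure_noise_concentrates_near_zero(self):
        rng = np.random.default_rng(11)
        stack = rng.standard_normal((25, 7, 6, 6))
        rmap = hc.icc_map(stack)
        assert np.nanmedian(rmap.connection_values()) < 0.15

    def test_matches_looped_icc_oneway(self, rng):
        stack = rng.standard_normal((5, 4, 3, 3))
        rmap = hc.icc_map(stack)
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert np.isnan(rmap.icc[i, j])
                    continue
                expected = hc.icc_oneway(stack[:, :, i, j])
                assert rmap.icc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_incomplete_design_rejected(self, rng):
        tset = make_tset(rng)
        mats = [
            [hc.compute_lofc(tset.get(s, e)) for e in tset.sessions]
            for s in tset.subjects
        ]
        mats[1] = mats[1][:1]
        with pytest.raises(ValueError, match="incomplete"):
            hc.icc_map(mats)

    def test_asymmetric_metric_uses_all_offdiagonal_cells(self, rng):
        stack = rng.standard_normal((4, 3, 3, 3))
        rmap = hc.icc_map(stack, metric="aHOFC")
        assert rmap.connection_values().size == 6  # 3x3 minus diagonal


class TestCategorize:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.0, "poor"),
            (0.1, "poor"),
            (0.2, "fair"),
            (0.3, "fair"),
            (0.4, "moderate"),
            (0.6, "good"),
            (0.8, "excellent"),
            (0.85, "excellent"),
            (1.0, "excellent"),
            (float("nan"), "undefined"),
        ],
    )
    def test_bins_left_closed(self, icc, expected):
        assert hc.categorize_icc(icc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hc.categorize_icc(1.2)


class TestSummarize:
    def _map_from_values(self, values):
        """Pack given connection values into a 2x-larger aHOFC-style map."""
        vals = list(values)
        n = len(vals)
        icc = np.full((n, n), np.nan)
        mask = np.zeros((n, n), dtype=bool)
        for idx, v in enumerate(vals):
            icc[idx, (idx + 1) % n] = v
            mask[idx, (idx + 1) % n] = True
        return hc.ReliabilityMap(icc, "aHOFC"), mask

    def test_uniform_moderate(self):
        rmap, mask = self._map_from_values([0.5, 0.5, 0.5])
        s = hc.summarize_reliability(rmap, mask)
        assert s["percentages"]["moderate"] == 100.0
        assert s["fraction_above_0.2"] == 1.0

    def test_hand_vector_counts(self):
        rmap, mask = self._map_from_values([0.1, 0.25, 0.45, 0.9])
        s = hc.summarize_reliability(rmap, mask)
        assert s["percentages"] == {
            "poor": 25.0, "fair": 25.0, "moderate": 25.0, "good": 0.0, "excellent": 25.0,
        }
        assert s["fraction_above_0.2"] == 0.75

    def test_single_connection_percentages_degenerate(self):
        icc = np.array([[np.nan, 0.45], [np.nan, np.nan]])
        s = hc.summarize_reliability(hc.ReliabilityMap(icc, "aHOFC"))
        assert set(s["percentages"].values()) <= {0.0, 100.0}

    def test_percentages_sum_to_hundred(self, rng):
        icc = np.clip(np.abs(rng.standard_normal((6, 6))), 0, 1)
        np.fill_diagonal(icc, np.nan)
        s = hc.summarize_reliability(hc.ReliabilityMap(icc, "ICC"))
        assert sum(s["percentages"].values()) == pytest.approx(100.0)

    def test_empty_mask_rejected(self):
        rmap, _ = self._map_from_values([0.5, 0.5])
        with pytest.raises(ValueError, match="empty"):
            hc.summarize_reliability(rmap, np.zeros_like(rmap.icc, dtype=bool))


class TestDifferenceAndGain:
    def test_self_difference_zero(self, rng):
        icc = np.clip(np.abs(rng.standard_normal((4, 4))), 0, 1)
        rmap = hc.ReliabilityMap(icc, "ICC")
        np.testing.assert_array_equal(hc.icc_difference(rmap, rmap), np.zeros((4, 4)))

    def test_antisymmetric_under_swap(self, rng):
        a = hc.ReliabilityMap(np.clip(np.abs(rng.standard_normal((4, 4))), 0, 1), "ICC")
        b = hc.ReliabilityMap(np.clip(np.abs(rng.standard_normal((4, 4))), 0, 1), "ICC")
        np.testing.assert_allclose(hc.icc_difference(a, b), -hc.icc_difference(b, a))

    def test_hand_subtraction(self):
        a = hc.ReliabilityMap(np.array([[0.0, 0.5], [0.7, 0.0]]), "ICC")
        b = hc.ReliabilityMap(np.array([[0.0, 0.2], [0.9, 0.0]]), "ICC")
        np.testing.assert_allclose(
            hc.icc_difference(a, b), np.array([[0.0, 0.3], [-0.2, 0.0]])
        )

    def test_nan_propagates(self):
        a = hc.ReliabilityMap(np.array([[0.0, np.nan], [0.1, 0.0]]), "ICC")
        b = hc.ReliabilityMap(np.array([[0.0, 0.2], [0.9, 0.0]]), "ICC")
        assert np.isnan(hc.icc_difference(a, b)[0, 1])

    def test_shape_mismatch_rejected(self):
        a = hc.ReliabilityMap(np.zeros((3, 3)), "ICC")
        b = hc.ReliabilityMap(np.zeros((4, 4)), "ICC")
        with pytest.raises(ValueError):
            hc.icc_difference(a, b)

    def test_all_negative_differences_give_zero_gain(self):
        diff = -np.abs(np.random.default_rng(0).standard_normal((4, 4)))
        gains = hc.regional_icc_gain(diff)
        assert all(g == 0.0 for g in gains.values())

    def test_single_positive_entry_credits_both_regions(self):
        diff = np.full((4, 4), -0.1)
        diff[1, 3] = 0.25
        gains = hc.regional_icc_gain(diff, symmetric=False)
        assert gains["R2"] == pytest.approx(0.25)
        assert gains["R4"] == pytest.approx(0.25)
        assert gains["R1"] == gains["R3"] == 0.0

    def test_symmetric_matrix_counts_each_connection_once(self):
        diff = np.zeros((3, 3))
        diff[0, 1] = diff[1, 0] = 0.2
        gains = hc.regional_icc_gain(diff)
        assert gains["R1"] == pytest.approx(0.2)
        assert gains["R2"] == pytest.approx(0.2)

    def test_gains_nonnegative(self, rng):
        diff = rng.standard_normal((5, 5))
        assert all(g >= 0 for g in hc.regional_icc_gain(diff).values())


class TestCompareTopLinks:
    def test_identical_inputs_tie(self, rng):
        v = rng.random(100)
        res = hc.compare_top_links(v, v, n_top=50)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["mean_a"] == res["mean_b"]

    def test_fully_separated_small_n_exact_p(self):
        a = np.array([10.0, 11.0, 12.0, 1.0])
        b = np.array([4.0, 5.0, 6.0, 0.5])
        res = hc.compare_top_links(a, b, n_top=3)
        # minimal attainable two-sided exact p at n=3 vs 3: 2/C(6,3)
        assert res["p_value"] == pytest.approx(oracles.exact_u_pvalue(9.0, 3, 3))
        assert res["p_value"] == pytest.approx(0.1)

    def test_u_statistic_matches_brute_force_ranks(self, rng):
        a = rng.random(20)
        b = rng.random(20)
        res = hc.compare_top_links(a, b, n_top=3)
        top_a = np.sort(a)[-3:]
        top_b = np.sort(b)[-3:]
        assert res["u_statistic"] == pytest.approx(
            oracles.brute_mann_whitney_u(top_a, top_b)
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="fewer than n_top"):
            hc.compare_top_links(np.arange(3.0), np.arange(10.0), n_top=5)
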