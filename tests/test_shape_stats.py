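"""The three-test association battery and the resampling bias checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpgrowth.shape_stats import (
    INDICATORS,
    NestEnvironment,
    TestBatteryResult,
    median_split_test,
    ratio_class_test,
    reliability_verdict,
    representative_resampling,
    run_battery,
    shuffle_null,
    sign_test_vs_value,
    spearman_test,
    spurious_count_pvalue,
)


class TestSpearman:
    def test_identity_and_reversal(self, rng):
        x = rng.uniform(0, 1, 12)
        assert spearman_test(x, x).rho == pytest.approx(1.0)
        assert spearman_test(x, -x).rho == pytest.approx(-1.0)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            spearman_test([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])

    def test_small_sample_exact_p_matches_enumeration_oracle(self, rng):
        x = rng.uniform(0, 1, 7)
        y = rng.uniform(0, 1, 7)
        ours = spearman_test(x, y)

        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        oracle = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=np.inf, alternative="two-sided")
        assert ours.pvalue == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_large_sample_uses_t_approximation(self, rng):
        x = rng.uniform(0, 1, 26)
        y = x + rng.normal(0, 0.5, 26)
        ours = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)


class TestMedianSplit:
    def test_ties_go_to_high_class(self):
        ratios = [0.1, 0.2, 0.3, 0.4, 0.5]
        indicator = [1.0, 2.0, 3.0, 3.0, 4.0]  # median 3 appears twice
        res = median_split_test(ratios, indicator)
        assert (res.n_high, res.n_low) == (3, 2)

    def test_identical_ratios_not_significant(self):
        res = median_split_test([0.5] * 10, list(range(10)))
        assert res.pvalue == pytest.approx(1.0)

    def test_power_at_n30(self, rng):
        indicator = rng.uniform(0, 1, 30)
        ratios = 0.3 + 0.4 * indicator  # strictly monotone effect
        assert median_split_test(ratios, indicator).pvalue < 0.05

    def test_invariance_under_monotone_indicator_transform(self, rng):
        ratios = rng.uniform(0, 1, 21)
        v = rng.lognormal(0, 1, 21)
        p1 = median_split_test(ratios, v).pvalue
        p2 = median_split_test(ratios, np.log(v)).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRatioClass:
    def test_threshold_is_inclusive(self):
        ratios = [0.5, 0.6, 0.4, 0.3, 0.2]
        res = ratio_class_test(ratios, [1, 2, 3, 4, 5], threshold=0.5)
        assert res.n_high == 2  # the exactly-0.5 bird is high-ratio

    def test_identical_indicator_not_significant(self):
        res = ratio_class_test([0.2, 0.3, 0.6, 0.7, 0.8], [5.0] * 5)
        assert res.pvalue == pytest.approx(1.0)

    def test_empty_class_error_names_sizes(self):
        with pytest.raises(ValueError, match="0 high-ratio"):
            ratio_class_test([0.1, 0.2, 0.3], [1, 2, 3], threshold=0.5)

    def test_invariance_under_monotone_ratio_transform(self, rng):
        # test c only uses the high/low classification of the ratio, so any
        # threshold-respecting monotone relabeling of ratios leaves p alone
        ratios = rng.uniform(0, 1, 19)
        v = rng.normal(0, 1, 19)
        p1 = ratio_class_test(ratios, v).pvalue
        p2 = ratio_class_test(np.where(ratios >= 0.5, 1.0, 0.0), v).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestSignTest:
    def test_all_above_reference(self):
        res = sign_test_vs_value(np.linspace(0.4, 0.9, 10), 1 / 3)
        assert res.pvalue == pytest.approx(2.0 ** -10, rel=1e-9)

    def test_symmetric_values_not_significant(self):
        vals = [0.2, 0.25, 0.3, 0.31, 0.32, 0.35, 0.36, 0.4, 0.45, 0.5]
        res = sign_test_vs_value(vals, 1 / 3)
        assert 0.3 < res.pvalue < 0.8

    def test_order_statistic_ci_for_n10(self):
        # Binom(10, 1/2): P(X <= 1) = 0.0107 <= 0.025 < P(X <= 2), so the
        # 95% interval is (x_(2), x_(9))
        x = np.arange(1.0, 11.0)
        res = sign_test_vs_value(x, 0.5)
        assert (res.ci_low, res.ci_high) == (2.0, 9.0)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError):
            sign_test_vs_value([1 / 3] * 6, 1 / 3)


class TestSpuriousCount:
    def test_matches_brute_force_enumeration(self):
        for n, alpha in [(13, 0.05), (9, 0.1), (15, 0.01)]:
            for k in range(n + 1):
                brute = sum(math.comb(n, j) * alpha**j * (1 - alpha) ** (n - j)
                            for j in range(k, n + 1))
                assert spurious_count_pvalue(n, alpha, k) == pytest.approx(brute, abs=1e-12)

    def test_edge_cases(self):
        assert spurious_count_pvalue(13, 0.05, 0) == 1.0
        assert spurious_count_pvalue(13, 0.05, 14) == 0.0


def _nest_frame(rng, n_birds=26, n_nests=13, n_indicators=13, duplicate=False):
    # study-scale nest count: with only a handful of nests the indicator
    # columns are correlated in-sample and the null counts over-disperse
    nests = np.repeat([f"N{i}" for i in range(n_nests)], n_birds // n_nests)
    base = rng.normal(0, 1, (n_nests, n_indicators))
    if duplicate:
        base = np.tile(base[:, :1], (1, n_indicators))
    ind = pd.DataFrame(np.repeat(base, n_birds // n_nests, axis=0),
                       columns=[f"x{j}" for j in range(n_indicators)])
    ratios = rng.uniform(0.2, 0.8, n_birds)
    return ratios, nests, ind


class TestShuffleNull:
    def test_single_shuffle_is_its_own_quantile(self, rng):
        ratios, nests, ind = _nest_frame(rng)
        q95, counts = shuffle_null(ratios, nests, ind, n_shuffles=1, seed=0)
        assert counts.size == 1 and q95 == counts[0]

    def test_independent_indicators_rarely_exceed_two(self, rng):
        ratios, nests, ind = _nest_frame(rng)
        q95, counts = shuffle_null(ratios, nests, ind, n_shuffles=2000, seed=1)
        assert q95 <= 2

    def test_duplicated_indicators_break_binomial_estimate(self, rng):
        # perfectly dependent columns: significant counts come in blocks of
        # 13, which the independence-based binomial estimate cannot capture
        ratios, nests, ind = _nest_frame(rng, duplicate=True)
        q95, counts = shuffle_null(ratios, nests, ind, n_shuffles=2000, seed=1)
        assert set(np.unique(counts)) <= {0, 13}
        assert q95 in (0, 13)

    def test_seeded_reproducibility(self, rng):
        ratios, nests, ind = _nest_frame(rng)
        r1 = shuffle_null(ratios, nests, ind, n_shuffles=200, seed=7)
        r2 = shuffle_null(ratios, nests, ind, n_shuffles=200, seed=7)
        assert np.array_equal(r1[1], r2[1])


class TestRepresentativeResampling:
    def test_singleton_nests_reproduce_full_sample(self, rng):
        n = 12
        ratios = rng.uniform(0, 1, n)
        nests = [f"N{i}" for i in range(n)]
        birds = [f"B{i}" for i in range(n)]
        ind = pd.DataFrame({"x": rng.normal(0, 1, n)})
        res = representative_resampling(ratios, nests, birds, ind)
        assert res["x"].n == n
        full = spearman_test(ratios, ind["x"])
        assert res["x"].rho == pytest.approx(full.rho)

    def test_deterministic_pick_prefers_lower_bird_id(self):
        # two birds equidistant from the nest median ratio
        ratios = [0.4, 0.6, 0.3, 0.5, 0.7, 0.2, 0.9, 0.35, 0.55, 0.65]
        nests = ["N1"] * 2 + ["N2"] * 8
        birds = ["B2", "B1"] + [f"B{i}" for i in range(3, 11)]
        ind = pd.DataFrame({"x": np.arange(10.0)})
        res = representative_resampling(ratios, nests, birds, ind)
        # nest N1 median is 0.5; both birds are 0.1 away; B1 must win.
        # find which index was kept for N1 by checking n == 2 reduced sample
        assert res["x"].n == 2

    def test_bootstrap_single_draw_reproducible(self, rng):
        ratios, nests, ind = _nest_frame(rng)
        birds = [f"B{i}" for i in range(len(ratios))]
        f1 = representative_resampling(ratios, nests, birds, ind,
                                       mode="bootstrap", seed=3, n_boot=1)
        f2 = representative_resampling(ratios, nests, birds, ind,
                                       mode="bootstrap", seed=3, n_boot=1)
        assert f1 == f2


def _battery_frame(rng, effect=0.0, n_per_stratum=20):
    rows = []
    for species in ("blue tit", "great tit"):
        for sex in ("female", "male"):
            ind = {k: rng.normal(0, 1, n_per_stratum) for k in INDICATORS}
            noise = rng.normal(0, 0.1, n_per_stratum)
            ratio = np.clip(0.5 + effect * ind["isa"] + noise, 0.01, 0.99)
            for i in range(n_per_stratum):
                rows.append({"species": species, "sex": sex, "ratio": ratio[i],
                             **{k: ind[k][i] for k in INDICATORS}})
    return pd.DataFrame(rows)


class TestBatteryAndVerdict:
    def test_null_battery_mostly_insignificant(self, rng):
        battery = run_battery(_battery_frame(rng, effect=0.0))
        assert len(battery.table) == 4 * len(INDICATORS)
        frac_sig = (battery.table["p_spearman"] < 0.05).mean()
        assert frac_sig < 0.25

    def test_strong_effect_is_reliable(self, rng):
        battery = run_battery(_battery_frame(rng, effect=-0.15, n_per_stratum=30))
        verdicts = reliability_verdict(battery)
        hit = verdicts[(verdicts.indicator == "isa") & (verdicts.direction == -1.0)]
        assert bool(hit.reliable.iloc[0])

    def test_single_stratum_support_is_not_reliable(self):
        rows = []
        for sp, sex, p in [("blue tit", "female", 0.004), ("blue tit", "male", 0.5),
                           ("great tit", "female", 0.5), ("great tit", "male", 0.5)]:
            rows.append({"species": sp, "sex": sex, "indicator": "isa", "n": 20,
                         "rho": -0.5, "p_spearman": p, "direction": -1.0,
                         "p_median_split": p, "p_ratio_class": p,
                         "ratio_median_high_env": 0.4, "ratio_median_low_env": 0.6,
                         "env_median_high_ratio": 3.0, "env_median_low_ratio": 8.0})
        verdicts = reliability_verdict(TestBatteryResult(table=pd.DataFrame(rows)))
        assert not verdicts.reliable.any()

    def test_table2_pattern_is_reliable(self):
        # all three tests significant, one highly, in both blue-tit strata
        rows = []
        for sp, sex, pa, pb, pc in [
            ("blue tit", "female", 0.004, 0.03, 0.02),
            ("blue tit", "male", 0.0069, 0.0032, 0.0114),
            ("great tit", "female", 0.6, 0.7, 0.8),
            ("great tit", "male", 0.5, 0.6, 0.9),
        ]:
            rows.append({"species": sp, "sex": sex, "indicator": "isa", "n": 26,
                         "rho": -0.5, "p_spearman": pa, "direction": -1.0,
                         "p_median_split": pb, "p_ratio_class": pc,
                         "ratio_median_high_env": 0.47, "ratio_median_low_env": 0.53,
                         "env_median_high_ratio": 4.5, "env_median_low_ratio": 13.3})
        verdicts = reliability_verdict(TestBatteryResult(table=pd.DataFrame(rows)))
        hit = verdicts[(verdicts.indicator == "isa") & (verdicts.direction == -1.0)]
        assert bool(hit.reliable.iloc[0])
        assert hit.n_supporting_strata.iloc[0] == 2


class TestNestEnvironment:
    def test_difference_invariant_enforced(self):
        with pytest.raises(ValueError, match="difference"):
            NestEnvironment(nest_id="N1", hatching_day=38, hatchlings_initial=8,
                            hatchlings_final=5, nest_size_difference=2,
                            human_activity=1.0, isa=4.6, light=3000, ndvi=0.75,
                            path_distance=12, road_distance=100, sound=65,
                            temperature=10.9, tree_cover=25)

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError, match="isa"):
            NestEnvironment(nest_id="N1", hatching_day=38, hatchlings_initial=8,
                            hatchlings_final=5, nest_size_difference=3,
                            human_activity=1.0, isa=104.0, light=3000, ndvi=0.75,
                            path_distance=12, road_distance=100, sound=65,
                            temperature=10.9, tree_cover=25)
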