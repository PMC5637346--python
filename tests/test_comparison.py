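"""LR+ overlap statistics, reporting ratios, curves and linear models."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from degbias import (
    OverlapCounts,
    cumulative_reporting_prob,
    fit_eq1,
    fit_eq2,
    lr_plus,
    multi_disease_overlap,
    over_under_ratio,
    pairwise_disease_lr,
    popularity_correlation,
    source_lr_vs_threshold,
    zero_intercept_trend,
)
from degbias.comparison import LinearFit, _ols_fit


def lr_oracle(a: set, b: set, universe: range) -> float:
    """Conditional-frequency oracle by explicit membership enumeration."""
    in_b = [g for g in universe if g in b]
    out_b = [g for g in universe if g not in b]
    p_given_b = sum(1 for g in in_b if g in a) / len(in_b)
    p_given_not_b = sum(1 for g in out_b if g in a) / len(out_b)
    if p_given_not_b == 0:
        return math.inf if p_given_b > 0 else math.nan
    return p_given_b / p_given_not_b


class TestOverUnderRatio:
    def test_hand_count(self):
        po, pu, r = over_under_ratio({"a", "b", "c"}, {"d"})
        assert (po, pu, r) == (75.0, 25.0, 3.0)

    def test_symmetry(self):
        po, pu, r = over_under_ratio({"a", "b"}, {"c", "d"})
        assert po == pu == 50.0 and r == 1.0

    def test_no_under_reports_is_infinite(self):
        assert over_under_ratio({"a"}, set())[2] == math.inf

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            over_under_ratio(set(), set())


class TestLrPlus:
    def test_independence_gives_one(self):
        c = OverlapCounts(n_universe=100, n_a=10, n_b=10, n_ab=1)
        assert lr_plus(c) == pytest.approx(1.0)

    def test_derived_example(self):
        c = OverlapCounts(n_universe=1000, n_a=50, n_b=40, n_ab=20)
        assert lr_plus(c) == pytest.approx(16.0)
        a = set(range(50))
        b = set(range(30, 70))
        assert len(a & b) == 20
        assert lr_plus(c) == pytest.approx(lr_oracle(a, b, range(1000)))

    def test_empty_overlap_is_zero(self):
        c = OverlapCounts(n_universe=100, n_a=5, n_b=5, n_ab=0)
        assert lr_plus(c) == 0.0

    def test_full_containment_is_infinite(self):
        c = OverlapCounts(n_universe=100, n_a=5, n_b=10, n_ab=5)
        assert lr_plus(c) == math.inf

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError):
            lr_plus(OverlapCounts(n_universe=10, n_a=3, n_b=0, n_ab=0))
        with pytest.raises(ValueError):
            lr_plus(OverlapCounts(n_universe=10, n_a=3, n_b=10, n_ab=3))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            OverlapCounts(n_universe=10, n_a=3, n_b=2, n_ab=3)

    def test_exhaustive_oracle_small_universes(self):
        """Enumerated set construction agrees with the count formula for
        every margin configuration up to N=20 (full sweep at N<=50 lives in
        the acceptance suite)."""
        for n in range(2, 21):
            for na in range(0, n + 1):
                for nb in range(1, n):
                    for nab in range(max(0, na + nb - n),
                                     min(na, nb) + 1):
                        a = set(range(na))
                        b = set(range(na - nab, na - nab + nb))
                        assert len(a & b) == nab
                        got = lr_plus(
                            OverlapCounts(n, na, nb, nab)
                        )
                        want = lr_oracle(a, b, range(n))
                        if math.isnan(want):
                            assert math.isnan(got)
                        else:
                            assert got == pytest.approx(want)

    def test_strictly_increasing_in_overlap(self):
        vals = [
            lr_plus(OverlapCounts(n_universe=100, n_a=20, n_b=15, n_ab=k))
            for k in range(0, 15)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_log_lr_centred_under_independence(self):
        rng = np.random.default_rng(0)
        n, p = 4000, 0.1
        logs = []
        for _ in range(500):
            a = rng.uniform(size=n) < p
            b = rng.uniform(size=n) < p
            c = OverlapCounts(n, int(a.sum()), int(b.sum()),
                              int((a & b).sum()))
            logs.append(math.log(lr_plus(c)))
        mean = np.mean(logs)
        se = np.std(logs, ddof=1) / math.sqrt(len(logs))
        assert abs(mean) < 3 * se


class TestPairwiseDiseaseLr:
    def test_identical_sets_infinite_both_ways(self):
        s = {"g1", "g2", "g3"}
        mat = pairwise_disease_lr({"A": s, "B": set(s)}, 100)
        assert mat.loc["A", "B"] == math.inf
        assert mat.loc["B", "A"] == math.inf

    def test_three_disease_matrix_matches_oracle(self):
        universe = range(60)
        sets = {
            "X": set(range(0, 12)),
            "Y": set(range(6, 20)),
            "Z": set(range(15, 40)),
        }
        mat = pairwise_disease_lr(sets, 60)
        for y1, y2 in itertools.permutations(sets, 2):
            assert mat.loc[y1, y2] == pytest.approx(
                lr_oracle(sets[y1], sets[y2], universe)
            )
        assert all(mat.loc[d, d] == math.inf for d in sets)

    def test_independent_random_sets_average_near_one(self):
        rng = np.random.default_rng(5)
        n, p = 17126, 0.05
        vals = []
        for _ in range(100):
            a = rng.uniform(size=n) < p
            b = rng.uniform(size=n) < p
            vals.append(lr_plus(OverlapCounts(
                n, int(a.sum()), int(b.sum()), int((a & b).sum()))))
        assert 0.8 <= np.mean(vals) <= 1.25


class TestMultiDiseaseOverlap:
    def test_disjoint_sets(self):
        sets = {"A": {1, 2}, "B": {3, 4}, "C": {5}}
        out = multi_disease_overlap(sets, 100)
        assert out["exact_counts"][2] == 0
        assert out["exact_counts"][3] == 0

    def test_nested_sets_containment(self):
        a = {1, 2}
        b = a | {3, 4}
        c = b | {5, 6}
        out = multi_disease_overlap({"A": a, "B": b, "C": c}, 100)
        assert out["at_least_counts"][3] == len(a)
        assert out["exact_counts"][3] == len(a)

    def test_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        universe = list(range(200))
        sets = {
            d: set(rng.choice(universe, size=40, replace=False))
            for d in "ABCD"
        }
        out = multi_disease_overlap(sets, 200)
        for k in range(1, 5):
            exact = sum(
                1 for g in universe
                if sum(g in s for s in sets.values()) == k
            )
            at_least = sum(
                1 for g in universe
                if sum(g in s for s in sets.values()) >= k
            )
            assert out["exact_counts"][k] == exact
            assert out["at_least_counts"][k] == at_least
        # spot-check one k=4 arrangement against the oracle
        b = sets["B"] & sets["C"] & sets["D"]
        if b:
            want = lr_oracle(sets["A"], b, range(200))
            assert want in [pytest.approx(v) if not math.isinf(v) else v
                            for v in out["kwise_lr"][4]["values"]] or any(
                math.isclose(v, want) for v in out["kwise_lr"][4]["values"]
                if math.isfinite(v)
            )


class TestCumulativeReporting:
    def de_table(self, fc):
        fc = np.asarray(fc, dtype=float)
        return pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(len(fc))],
            "fc": fc,
            "log2fc": np.sign(fc) * np.log2(np.maximum(np.abs(fc), 1e-9)),
            "p_adj": 0.01,
        })

    def test_threshold_below_range_gives_overall_fraction(self):
        de = self.de_table([1.5, 2.5, 3.5, -2.0])
        curve = cumulative_reporting_prob({"g1", "g2"}, de, [-10.0])
        assert curve["probability"].iloc[0] == pytest.approx(2 / 4)

    def test_empty_literature_set_gives_zero_curve(self):
        de = self.de_table([1.0, 2.0, 3.0])
        curve = cumulative_reporting_prob(set(), de, [0.0, 1.5])
        assert (curve["probability"] == 0).all()

    def test_all_empty_denominators_rejected(self):
        de = self.de_table([1.0, 2.0])
        with pytest.raises(ValueError):
            cumulative_reporting_prob({"g0"}, de, [10.0])

    def test_unstable_points_flagged(self):
        de = self.de_table([1.0, 2.0, 3.0])
        curve = cumulative_reporting_prob({"g2"}, de, [2.5],
                                          min_denominator=10)
        assert not curve["stable"].iloc[0]

    def test_monotone_under_planted_monotone_reporting(self):
        """When reporting probability increases with fold change the curve
        rises from its lowest to its highest threshold (3 SD envelope)."""
        rng = np.random.default_rng(8)
        n = 5000
        fc = rng.uniform(1.0, 6.0, size=n)
        p = 0.05 + 0.12 * (fc - 1)
        reported = rng.uniform(size=n) < p
        de = self.de_table(fc)
        lit = set(de["feature_id"][reported])
        curve = cumulative_reporting_prob(lit, de, [1.0, 3.0, 5.0])
        lo, hi = curve.iloc[0], curve.iloc[-1]
        sd = math.sqrt(lo["probability"] * (1 - lo["probability"])
                       / hi["n"])
        assert hi["probability"] > lo["probability"] + 3 * sd


class TestPopularityCorrelation:
    def test_null_is_near_zero(self):
        rng = np.random.default_rng(1)
        n = 17126
        ind = (rng.uniform(size=n) < 0.05).astype(int)
        pop = np.floor(rng.uniform(size=n) ** (-1 / 1.5))
        r, p, _ = popularity_correlation(ind, pop)
        assert abs(r) < 3 / math.sqrt(n)

    def test_top_half_indicator_positive(self):
        pop = np.arange(1, 101)
        ind = (pop > 50).astype(int)
        r, p, sig = popularity_correlation(ind, pop)
        assert r > 0 and sig

    def test_six_gene_hand_calculation(self):
        ind = np.array([1, 0, 1, 0, 0, 1], dtype=float)
        pop = np.array([10.0, 2.0, 8.0, 3.0, 1.0, 20.0])
        r, p, _ = popularity_correlation(ind, pop)
        # textbook Pearson formula computed independently
        num = np.sum((ind - ind.mean()) * (pop - pop.mean()))
        den = math.sqrt(np.sum((ind - ind.mean()) ** 2)
                        * np.sum((pop - pop.mean()) ** 2))
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_constant_indicator_rejected(self):
        with pytest.raises(ValueError):
            popularity_correlation([1, 1, 1], [1.0, 2.0, 3.0])


class TestLinearModels:
    def table(self, fc, inc, high, log2fc=None, pop=None):
        return pd.DataFrame({
            "fc": fc, "increase_mentions": inc,
            "high_increase_mentions": high,
            "log2fc": log2fc if log2fc is not None else np.log2(
                np.abs(np.asarray(fc, float))),
            "popularity": pop if pop is not None else np.ones(len(fc)),
        })

    def test_eq1_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        fc = rng.uniform(1, 8, size=50)
        inc = rng.integers(0, 10, size=50).astype(float)
        high = 0.005 * fc + 0.2 * inc + 0.1
        fit = fit_eq1(self.table(fc, inc, high, pop=rng.uniform(size=50)))
        assert fit.alpha == pytest.approx(0.005, abs=1e-10)
        assert fit.beta == pytest.approx(0.2, abs=1e-10)
        assert fit.gamma == pytest.approx(0.1, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_eq2_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        lfc = rng.normal(size=60)
        pop = rng.integers(1, 500, size=60).astype(float)
        inc = 0.3 * lfc + 0.002 * pop + 1.0
        df = pd.DataFrame({
            "log2fc": lfc, "popularity": pop, "increase_mentions": inc,
        })
        fit = fit_eq2(df)
        assert fit.alpha == pytest.approx(0.3, abs=1e-9)
        assert fit.beta == pytest.approx(0.002, abs=1e-9)

    def test_collinear_regressors_rejected(self):
        fc = np.arange(1.0, 11.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_eq1(self.table(fc, fc, fc))

    def test_permutation_null_p_values_uniform(self):
        """Permuting the response makes both coefficient p-values null."""
        from scipy.stats import kstest

        rng = np.random.default_rng(6)
        fc = rng.uniform(1, 5, size=80)
        inc = rng.integers(0, 6, size=80).astype(float)
        high = rng.poisson(1.0, size=80).astype(float)
        ps = []
        for _ in range(200):
            fit = fit_eq1(self.table(fc, inc, rng.permutation(high)))
            ps.extend([fit.p_alpha, fit.p_beta])
        assert kstest(ps, "uniform").pvalue > 0.001

    def test_ols_matches_normal_equations(self):
        """Closed-form (X'X)^-1 X'y agrees to 1e-10 on random designs."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            y = rng.normal(size=n)
            fit = _ols_fit(y, x1, x2, ("x1", "x2"))
            X = np.column_stack([np.ones(n), x1, x2])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.gamma == pytest.approx(beta[0], abs=1e-10)
            assert fit.alpha == pytest.approx(beta[1], abs=1e-10)
            assert fit.beta == pytest.approx(beta[2], abs=1e-10)

    def test_linear_fit_r_squared_validated(self):
        with pytest.raises(ValueError):
            LinearFit(alpha=0, beta=0, gamma=0, p_alpha=0.5, p_beta=0.5,
                      r_squared=1.5)


class TestZeroInterceptTrend:
    def test_exact_proportionality(self):
        slope, r2 = zero_intercept_trend([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_hand_algebra_two_points(self):
        slope, r2 = zero_intercept_trend([1.0, 2.0], [1.0, 1.0])
        assert slope == pytest.approx(0.6)
        assert r2 == pytest.approx(0.9)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            zero_intercept_trend([0.0, 0.0], [1.0, 2.0])


class TestSourceLrVsThreshold:
    def de_table(self, log2fc, p_adj=0.01):
        log2fc = np.asarray(log2fc, dtype=float)
        return pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(len(log2fc))],
            "log2fc": log2fc,
            "fc": np.sign(log2fc) * 2 ** np.abs(log2fc),
            "p_adj": p_adj,
        })

    def test_random_literature_set_is_flat_near_one(self):
        rng = np.random.default_rng(9)
        n = 8000
        lfc = rng.normal(0, 1.5, size=n)
        de = self.de_table(lfc)
        means = {0.0: [], 1.0: []}
        for _ in range(30):
            lit = set(
                np.asarray(de["feature_id"])[rng.uniform(size=n) < 0.05]
            )
            curve = source_lr_vs_threshold(lit, de, [0.0, 1.0], n)
            for i, x in enumerate([0.0, 1.0]):
                means[x].append(curve["lr_micro_given_lit"].iloc[i])
        for x, vals in means.items():
            assert 0.8 <= np.nanmean(vals) <= 1.25

    def test_perfect_agreement_is_infinite(self):
        de = self.de_table([2.0, 2.5, -1.0, 0.5, 3.0])
        lit = {"g0", "g1", "g4"}  # exactly the up-set at threshold 1.5
        curve = source_lr_vs_threshold(lit, de, [1.5], 5)
        assert curve["lr_micro_given_lit"].iloc[0] == math.inf
        assert curve["lr_lit_given_micro"].iloc[0] == math.inf

    def test_empty_conditioning_flagged_not_raised(self):
        de = self.de_table([0.5, -0.5, 0.2])
        curve = source_lr_vs_threshold(set(), de, [0.0], 3)
        assert not curve["defined_micro_given_lit"].iloc[0]
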