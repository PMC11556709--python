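import numpy as np
import pytest

from rohbench.intervals import ROHSet
from rohbench.rohmetrics import (LengthBins, bin_error_summary, binned_froh,
                                 bootstrap_mean_ci, fit_true_vs_called,
                                 fn_fp_rates, lumping_counts)


def rs(*ivals, min_len=0):
    return ROHSet(np.array(ivals).reshape(-1, 2), min_len=min_len)


class TestFnFpRates:
    def test_perfect_calls_have_zero_error(self):
        t = rs((100, 500), (900, 1500))
        out = fn_fp_rates(t, t, L=2000)
        assert out.fn_rate == 0 and out.fp_rate == 0

    def test_empty_calls_miss_everything(self):
        out = fn_fp_rates(rs((100, 500)), ROHSet(), L=2000)
        assert out.fn_rate == 1 and out.fp_rate == 0

    def test_partial_overlap_arithmetic(self):
        t = rs((100_000, 400_000))
        c = rs((200_000, 600_000))
        out = fn_fp_rates(t, c, L=1_000_000)
        assert out.fn_rate == pytest.approx(100_000 / 300_000)
        assert out.fp_rate == pytest.approx(200_000 / 700_000)

    def test_undefined_rates_reported_as_nan(self):
        out = fn_fp_rates(ROHSet(), rs((0, 10)), L=100)
        assert np.isnan(out.fn_rate) and out.fp_rate == pytest.approx(0.1)
        out = fn_fp_rates(rs((0, 100)), rs((0, 100)), L=100)
        assert np.isnan(out.fp_rate) and out.fn_rate == 0

    def test_interval_conservation_on_random_sets(self, rng):
        from rohbench.intervals import intersect, merge, subtract, total_length
        for _ in range(200):
            L = 10_000
            t = merge(np.sort(rng.choice(L, (rng.integers(1, 8), 2)), axis=1) +
                      np.array([0, 1]))
            c = merge(np.sort(rng.choice(L, (rng.integers(0, 8), 2)), axis=1) +
                      np.array([0, 1]))
            assert (total_length(intersect(t, c)) + total_length(subtract(t, c))
                    == total_length(t))


class TestBinnedFroh:
    def test_published_bin_edges(self):
        b = LengthBins()
        L = 30_000_000
        out = binned_froh(rs((0, 200_000), (1_000_000, 1_700_000),
                             (3_000_000, 4_500_000), (10_000_000, 13_000_000),
                             min_len=100_000), b, L)
        assert out == pytest.approx([200_000 / L, 700_000 / L,
                                     1_500_000 / L, 3_000_000 / L])

    def test_exact_edge_goes_to_upper_bin(self):
        b = LengthBins()
        out = binned_froh(rs((0, 500_000)), b, 30_000_000)
        assert out[1] > 0 and out[0] == 0  # 500 kb is "intermediate"

    def test_partition_identity(self, rng):
        b = LengthBins()
        L = 30_000_000
        starts = np.sort(rng.choice(L - 3_000_000, 10, replace=False))
        ivals = [(s, s + int(le)) for s, le in zip(
            starts, rng.integers(100_000, 2_500_000, 10)) ]
        # ensure disjoint
        ivals = [(s + 3_000_000 * i, min(e + 3_000_000 * i, L))
                 for i, (s, e) in enumerate(ivals)][:5]
        roh = rs(*[iv for iv in ivals if iv[1] <= L], min_len=100_000)
        out = binned_froh(roh, b, L)
        assert out.sum() == pytest.approx(roh.total_length / L, abs=1e-15)


class TestLumping:
    def test_two_true_lumped_into_one_called(self):
        t = rs((100_000, 200_000), (300_000, 450_000))
        c = rs((0, 1_000_000))
        lr = lumping_counts(t, c)
        assert lr.true_per_called.tolist() == [2]
        assert lr.called_per_true.tolist() == [1, 1]
        assert lr.n_split == 0

    def test_disjoint_sets_count_zero(self):
        lr = lumping_counts(rs((0, 100)), rs((200, 300)))
        assert lr.true_per_called.tolist() == [0]
        assert lr.called_per_true.tolist() == [0]

    def test_identical_sets_count_one_each(self):
        t = rs((0, 150_000), (400_000, 600_000), (800_000, 1_000_000))
        lr = lumping_counts(t, t)
        assert lr.true_per_called.tolist() == [1, 1, 1]
        assert lr.called_per_true.tolist() == [1, 1, 1]
        assert lr.mean_true_per_called == 1

    def test_split_statistic_counts_true_rohs_hit_twice(self):
        t = rs((0, 1_000_000))
        c = rs((0, 200_000), (500_000, 700_000))
        lr = lumping_counts(t, c)
        assert lr.n_split == 1


class TestRegression:
    def test_exact_affine_data(self):
        pairs = [(0.1, 0.05), (0.2, 0.15), (0.3, 0.25), (0.4, 0.35)]
        fit = fit_true_vs_called(pairs)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.05, abs=1e-12)

    def test_identity_line_has_degenerate_cis(self):
        pairs = [(x, x) for x in (0.1, 0.2, 0.3, 0.5)]
        fit = fit_true_vs_called(pairs)
        assert fit.slope == pytest.approx(1) and fit.intercept == pytest.approx(0, abs=1e-14)
        assert fit.slope_ci[1] - fit.slope_ci[0] == pytest.approx(0, abs=1e-10)
        assert not fit.slope_differs_from_one

    def test_matches_normal_equations_oracle(self, rng):
        """OLS estimates and t-based CIs agree with a closed-form
        computation from the normal equations to 1e-10."""
        from scipy import stats
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0, 1, n)
            y = 0.8 * x + rng.normal(0, 0.05, n)
            fit = fit_true_vs_called(np.column_stack([x, y]))
            xm, ym = x.mean(), y.mean()
            sxx = ((x - xm) ** 2).sum()
            slope = ((x - xm) * (y - ym)).sum() / sxx
            intercept = ym - slope * xm
            resid = y - intercept - slope * x
            s2 = (resid ** 2).sum() / (n - 2)
            se_slope = np.sqrt(s2 / sxx)
            se_int = np.sqrt(s2 * (1 / n + xm ** 2 / sxx))
            tcrit = stats.t.ppf(0.975, n - 2)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.slope_ci[0] == pytest.approx(slope - tcrit * se_slope, abs=1e-10)
            assert fit.slope_ci[1] == pytest.approx(slope + tcrit * se_slope, abs=1e-10)
            assert fit.intercept_ci[0] == pytest.approx(intercept - tcrit * se_int, abs=1e-10)

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_true_vs_called([(0.2, 0.1), (0.2, 0.2), (0.2, 0.3)])


class TestBinErrorSummary:
    def test_zero_differences(self):
        out = bin_error_summary(np.zeros(10))
        assert out == {"mean": 0.0, "lo": 0.0, "hi": 0.0}

    def test_small_sample_mean_and_bounds(self):
        out = bin_error_summary(np.array([-0.02, -0.01, -0.03]))
        assert out["mean"] == pytest.approx(-0.02)
        assert -0.03 <= out["lo"] <= out["hi"] <= -0.01

    def test_percentiles_match_sort_oracle(self, rng):
        d = rng.normal(0, 1, 201)
        out = bin_error_summary(d)
        s = np.sort(d)
        # linear-interpolation percentile on sorted data
        def q(p):
            h = p * (len(s) - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
        assert out["lo"] == pytest.approx(q(0.025), abs=1e-12)
        assert out["hi"] == pytest.approx(q(0.975), abs=1e-12)


def test_bootstrap_ci_covers_mean_and_is_seeded(rng):
    v = rng.normal(1.0, 0.2, 60)
    m1 = bootstrap_mean_ci(v, seed=5)
    m2 = bootstrap_mean_ci(v, seed=5)
    assert m1 == m2
    mean, lo, hi = m1
    assert lo <= mean <= hi
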