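import numpy as np
import pytest

from rohbench.hmmroh import (HMMParams, RATE_FLOOR, _log_emissions,
                             _viterbi_core, hmm_call, viterbi_train)
from rohbench.seqemu import MISSING, VariantTable
from tests.conftest import random_variant_table


def brute_force_viterbi(log_em, dists, r01, r10, ls0, ls1):
    """Enumerate all 2^n state paths; the independent decoding oracle."""
    n = log_em.shape[0]
    best_score, best_path = -np.inf, None
    for code in range(2 ** n):
        path = [(code >> i) & 1 for i in range(n)]
        score = (ls0 if path[0] == 0 else ls1) + log_em[0, path[0]]
        for i in range(1, n):
            d = dists[i - 1]
            rate = r01 if path[i - 1] == 0 else r10
            stay = np.exp(-rate * d)
            score += np.log(stay if path[i] == path[i - 1] else 1 - stay)
            score += log_em[i, path[i]]
        if score > best_score:
            best_score, best_path = score, path
    return np.array(best_path, np.int8), best_score


def table_from_genotypes(positions, gt_row, af):
    gt = np.asarray([gt_row], np.int8)
    n = gt.shape[1]
    dp = np.full((1, n), 20, np.int32)
    pl = np.zeros((1, n, 3), np.int32)
    for j in range(n):
        for g in range(3):
            if g != gt_row[j]:
                pl[0, j, g] = 60
    return VariantTable(np.asarray(positions, np.int64), gt, dp, pl,
                        af=np.asarray(af, float))


class TestHmmCall:
    def test_all_het_sites_yield_no_roh(self):
        vt = table_from_genotypes([0, 1000, 2000, 3000], [1, 1, 1, 1],
                                  [0.5] * 4)
        assert hmm_call(vt, 0, HMMParams(mode="genotypes")) == []

    def test_three_hom_sites_form_single_roh(self):
        # AZ emission 0.5*(1-1e-4) beats HW 0.25 per site; switch costs ~1e-4
        vt = table_from_genotypes([0, 1000, 2000], [2, 2, 2], [0.5] * 3)
        calls = hmm_call(vt, 0, HMMParams(mode="genotypes"))
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.end) == (0, 2001)
        assert calls[0].n_sites == 3

    def test_missing_sites_skipped_with_distance_accumulating(self):
        vt = table_from_genotypes([0, 500, 1000], [2, MISSING, 2], [0.5] * 3)
        calls = hmm_call(vt, 0, HMMParams(mode="genotypes"))
        assert len(calls) == 1
        assert calls[0].n_sites == 2

    def test_empty_site_list_returns_no_calls(self):
        vt = table_from_genotypes([0, 500], [MISSING, MISSING], [0.5, 0.5])
        assert hmm_call(vt, 0) == []

    @pytest.mark.parametrize("mode", ["genotypes", "likelihoods"])
    def test_viterbi_matches_exhaustive_oracle(self, mode, rng):
        """1,000 random instances with <= 12 sites decode identically to
        brute-force path enumeration."""
        params = HMMParams(mode=mode)
        for _ in range(1000):
            n = int(rng.integers(1, 13))
            pos = np.sort(rng.choice(2_000_000, n, replace=False))
            gt = rng.choice([0, 1, 2], size=n).astype(np.int8)
            pl = rng.integers(0, 80, size=(1, n, 3)).astype(np.int32)
            pl[0, np.arange(n), gt] = 0
            af = rng.uniform(0.05, 0.95, size=n)
            vt = VariantTable(pos, gt[None, :], np.full((1, n), 9, np.int32),
                              pl, af=af)
            log_em = _log_emissions(gt, pl[0], af, mode, params.az_het_leak)
            dists = np.diff(pos).astype(float)
            r01, r10 = rng.uniform(1e-8, 1e-4, 2)
            ls = np.log(0.5)
            states, score = _viterbi_core(log_em, dists, r01, r10, ls, ls)
            exp_states, exp_score = brute_force_viterbi(log_em, dists, r01, r10, ls, ls)
            assert score == pytest.approx(exp_score, abs=1e-9)
            assert np.array_equal(states, exp_states)

    def test_certain_likelihoods_reduce_to_genotypes_mode(self, rng):
        """PL triples of {0, huge, huge} make likelihoods mode identical to
        genotypes mode."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 60
            pos = np.sort(r.choice(5_000_000, n, replace=False))
            gt = r.choice([0, 1, 2], size=n, p=[0.45, 0.2, 0.35]).astype(np.int8)
            pl = np.full((1, n, 3), 255, np.int32)
            pl[0, np.arange(n), gt] = 0
            af = r.uniform(0.05, 0.95, size=n)
            vt = VariantTable(pos, gt[None, :], np.full((1, n), 9, np.int32),
                              pl, af=af)
            calls_g = hmm_call(vt, 0, HMMParams(mode="genotypes"))
            calls_l = hmm_call(vt, 0, HMMParams(mode="likelihoods"))
            assert ([(c.interval, c.n_sites) for c in calls_g]
                    == [(c.interval, c.n_sites) for c in calls_l])

    def test_increasing_az_to_hw_never_lengthens_calls(self, rng):
        vt = random_variant_table(rng, 1, 150, L=5_000_000, missing_frac=0.0)
        totals = []
        for az_to_hw in (1e-9, 1e-8, 1e-7, 1e-6, 1e-5):
            calls = hmm_call(vt, 0, HMMParams(az_to_hw=az_to_hw))
            totals.append(sum(c.interval.length for c in calls))
        assert all(a >= b for a, b in zip(totals, totals[1:]))


def simulate_from_hmm(rng, n_sites, span, r01, r10, af=0.3, leak=1e-4):
    """Generate genotype data from the HMM's own generative model."""
    pos = np.sort(rng.choice(span, n_sites, replace=False))
    states = np.empty(n_sites, np.int8)
    states[0] = rng.integers(2)
    for i in range(1, n_sites):
        d = pos[i] - pos[i - 1]
        rate = r01 if states[i - 1] == 0 else r10
        p_switch = 1 - np.exp(-rate * d)
        states[i] = states[i - 1] ^ (rng.random() < p_switch)
    p = af
    gt = np.empty(n_sites, np.int8)
    hw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    az = np.array([(1 - p) * (1 - leak), leak, p * (1 - leak)])
    for i in range(n_sites):
        probs = hw if states[i] == 0 else az
        gt[i] = rng.choice(3, p=probs)
    pl = np.full((1, n_sites, 3), 80, np.int32)
    pl[0, np.arange(n_sites), gt] = 0
    return VariantTable(pos, gt[None, :], np.full((1, n_sites), 20, np.int32),
                        pl, af=np.full(n_sites, af))


class TestViterbiTraining:
    def test_parameter_recovery_within_factor_two(self):
        """Rates used to generate data from the HMM itself are recovered
        within a factor of 2 (several seeds, >= 5 Mb of sites)."""
        true_r = 1e-5
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            vt = simulate_from_hmm(rng, 4000, 6_000_000, true_r, true_r)
            tp = viterbi_train(vt, HMMParams(hw_to_az=3e-6, az_to_hw=3e-6))
            assert true_r / 2 <= tp.hw_to_az <= true_r * 2
            assert true_r / 2 <= tp.az_to_hw <= true_r * 2

    def test_score_non_decreasing_over_iterations(self):
        for seed in (5, 6, 7):
            rng = np.random.default_rng(seed)
            vt = simulate_from_hmm(rng, 2000, 5_000_000, 2e-6, 1e-5)
            tp = viterbi_train(vt, HMMParams())
            diffs = np.diff(tp.score_history)
            assert np.all(diffs >= -1e-6 * np.abs(tp.score_history[:-1]))

    def test_zero_switch_decode_hits_rate_floor(self):
        # one long run of hom calls: decode has no HW->AZ switch from AZ-only path
        vt = table_from_genotypes(
            np.arange(0, 50_000, 1000), [2] * 25 + [1] + [2] * 24, [0.5] * 50)
        tp = viterbi_train(vt, HMMParams())
        assert tp.hw_to_az >= RATE_FLOOR and tp.az_to_hw >= RATE_FLOOR

    def test_training_is_deterministic(self, rng):
        vt = random_variant_table(rng, 4, 300, L=10_000_000)
        a = viterbi_train(vt, HMMParams())
        b = viterbi_train(vt, HMMParams())
        assert a == b

    def test_all_individuals_excluded_raises(self):
        # zero heterozygosity everywhere
        gt = np.full((3, 10), 2, np.int8)
        vt = VariantTable(np.arange(10) * 100, gt,
                          np.full((3, 10), 9, np.int32),
                          np.zeros((3, 10, 3), np.int32),
                          af=np.full(10, 0.5))
        with pytest.raises(ValueError, match="heterozygosity"):
            viterbi_train(vt, HMMParams())
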