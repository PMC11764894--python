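import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bremtool.entropies import (EntropyConfig, all_entropies,
                                approximate_entropy, fuzzy_entropy,
                                permutation_entropy, sample_entropy,
                                shannon_entropy, singular_spectrum_entropy,
                                spectral_entropy)

from conftest import make_sinusoid
from oracles import (apen_bruteforce, fuzzyen_bruteforce, pe_bruteforce,
                     psde_bruteforce, sampen_bruteforce, sse_bruteforce)

RAMP10 = np.arange(1.0, 11.0)
R10 = 0.2 * RAMP10.std()


class TestShannonHelper:
    def test_one_bin_distribution_is_zero(self):
        assert abs(shannon_entropy([1.0] + [0.0] * 29)) < 1e-9

    def test_uniform_distribution_is_log_n(self):
        n = 64
        p = np.full(n, 1.0 / n)
        assert abs(shannon_entropy(p) - math.log(n)) < 1e-9

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])


class TestSpectralEntropy:
    def test_all_zero_signal_returns_zero(self, cfg):
        assert spectral_entropy(np.zeros(512), 128.0, cfg) == 0.0

    def test_noise_exceeds_sinusoid(self, rng, cfg):
        noise = rng.standard_normal(640)
        sinus = make_sinusoid(10.0)
        assert (spectral_entropy(noise, 128.0, cfg)
                > spectral_entropy(sinus, 128.0, cfg))

    def test_matches_direct_evaluation(self, rng, cfg):
        from scipy.signal import welch
        x = rng.standard_normal(640)
        _, pxx = welch(x, fs=128.0, window="hann", nperseg=256, noverlap=128)
        expected = psde_bruteforce(pxx / pxx.sum(), cfg.eps)
        assert abs(spectral_entropy(x, 128.0, cfg) - expected) < 1e-10

    def test_short_sequence_auto_shrinks_nperseg(self, rng, cfg):
        assert np.isfinite(spectral_entropy(rng.standard_normal(100),
                                            128.0, cfg))


class TestSingularSpectrumEntropy:
    def test_constant_nonzero_is_near_zero(self, cfg):
        assert abs(singular_spectrum_entropy(np.full(100, 5.0), cfg)) < 1e-6

    def test_matches_bruteforce(self, rng, cfg):
        x = rng.standard_normal(150)
        expected = sse_bruteforce(x, cfg.sse_window, cfg.eps)
        assert abs(singular_spectrum_entropy(x, cfg) - expected) < 1e-10

    def test_sinusoid_low_noise_high(self, rng, cfg):
        sinus = make_sinusoid(10.0)
        noise = rng.standard_normal(len(sinus))
        sse_sin = singular_spectrum_entropy(sinus, cfg)
        assert sse_sin < math.log(2) + 0.5  # two dominant singular values
        assert singular_spectrum_entropy(noise, cfg) > sse_sin

    def test_too_short_raises(self, cfg):
        with pytest.raises(ValueError, match="too short"):
            singular_spectrum_entropy(np.arange(10.0), cfg)


class TestSampleEntropy:
    def test_constant_is_zero(self, cfg):
        assert sample_entropy(np.full(100, 5.0), cfg) == 0.0

    def test_ramp_matches_oracle_exactly(self, cfg):
        got = sample_entropy(RAMP10, cfg)
        assert got == pytest.approx(sampen_bruteforce(RAMP10, 2, R10),
                                    abs=1e-12)
        # no template pair matches at this tolerance: capped sentinel
        assert got == pytest.approx(math.log(8 * 7), abs=1e-12)

    @pytest.mark.parametrize("n", [30, 80, 200])
    def test_matches_bruteforce_on_noise(self, rng, cfg, n):
        x = rng.standard_normal(n)
        r = cfg.r_frac * x.std()
        assert sample_entropy(x, cfg) == pytest.approx(
            sampen_bruteforce(x, cfg.m, r), abs=1e-10)

    def test_noise_exceeds_periodic(self, rng, cfg):
        template = rng.standard_normal(10)
        periodic = np.tile(template, 20)
        noise = rng.standard_normal(len(periodic))
        assert sample_entropy(noise, cfg) > sample_entropy(periodic, cfg)

    def test_too_short_raises(self, cfg):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.array([1.0, 2.0, 3.0]), cfg)


class TestFuzzyEntropy:
    def test_constant_is_zero(self, cfg):
        assert fuzzy_entropy(np.full(50, 2.5), cfg) == 0.0

    def test_ramp_matches_oracle(self, cfg):
        assert fuzzy_entropy(RAMP10, cfg) == pytest.approx(
            fuzzyen_bruteforce(RAMP10, 2, 2.0, R10), abs=1e-10)

    @pytest.mark.parametrize("n", [30, 80, 200])
    def test_matches_bruteforce_on_noise(self, rng, cfg, n):
        x = rng.standard_normal(n)
        r = cfg.r_frac * x.std()
        assert fuzzy_entropy(x, cfg) == pytest.approx(
            fuzzyen_bruteforce(x, cfg.m, cfg.n_fuzzy, r), abs=1e-10)

    def test_ramp_below_shuffled_ramp(self, cfg):
        ramp = np.arange(60.0)
        shuffled = ramp.copy()
        np.random.default_rng(7).shuffle(shuffled)
        assert fuzzy_entropy(ramp, cfg) < fuzzy_entropy(shuffled, cfg)


class TestApproximateEntropy:
    def test_constant_is_zero(self, cfg):
        assert approximate_entropy(np.full(100, -3.0), cfg) == 0.0

    def test_ramp_matches_oracle(self, cfg):
        assert approximate_entropy(RAMP10, cfg) == pytest.approx(
            apen_bruteforce(RAMP10, 2, R10), abs=1e-10)

    @pytest.mark.parametrize("n", [30, 80, 200])
    def test_matches_bruteforce_on_noise(self, rng, cfg, n):
        x = rng.standard_normal(n)
        r = cfg.r_frac * x.std()
        assert approximate_entropy(x, cfg) == pytest.approx(
            apen_bruteforce(x, cfg.m, r), abs=1e-10)

    def test_noise_exceeds_sinusoid(self, rng, cfg):
        noise = rng.standard_normal(512)
        sinus = make_sinusoid(10.0, seconds=4.0)
        assert (approximate_entropy(noise, cfg)
                > approximate_entropy(sinus, cfg))


class TestPermutationEntropy:
    def test_monotone_sequence_is_zero(self, cfg):
        assert permutation_entropy(np.arange(50.0), cfg) == 0.0

    def test_uniform_patterns_reach_log_factorial(self):
        # order 2: an alternating sequence visits both ordinal patterns
        # equally often, attaining the ln(order!) upper bound exactly
        cfg2 = EntropyConfig(pe_order=2)
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        got = permutation_entropy(x, cfg2)
        assert got == pytest.approx(math.log(math.factorial(2)), abs=1e-12)
        assert got == pytest.approx(pe_bruteforce(x, 2, 1), abs=1e-12)

    def test_hand_enumerated_example(self, cfg):
        x = [4, 7, 9, 10, 6, 11, 3]
        assert permutation_entropy(np.array(x, float), cfg) == pytest.approx(
            pe_bruteforce(x, 3, 1), abs=1e-12)
        assert permutation_entropy(np.array(x, float), cfg) == pytest.approx(
            1.0549201679861442, abs=1e-12)

    @pytest.mark.parametrize("order,delay", [(3, 1), (4, 2), (5, 1)])
    def test_matches_bruteforce_on_noise(self, rng, order, delay):
        cfg = EntropyConfig(pe_order=order, pe_delay=delay)
        x = rng.standard_normal(200)
        assert permutation_entropy(x, cfg) == pytest.approx(
            pe_bruteforce(x, order, delay), abs=1e-10)

    def test_bounded_by_log_factorial(self, rng, cfg):
        x = rng.standard_normal(1000)
        assert 0 <= permutation_entropy(x, cfg) <= math.log(6) + 1e-12

    def test_too_short_raises(self, cfg):
        with pytest.raises(ValueError, match="too short"):
            permutation_entropy(np.array([1.0, 2.0, 3.0]), cfg)


class TestSharedProperties:
    def test_all_finite_nonnegative_on_noise(self, rng, cfg):
        feats = all_entropies(rng.standard_normal(640), 128.0, cfg)
        for key, value in feats.items():
            assert np.isfinite(value), key
            assert value >= -1e-9, key

    def test_noise_exceeds_sinusoid_for_all_six(self, rng, cfg):
        noise = rng.standard_normal(640)
        sinus = make_sinusoid(10.0)
        f_noise = all_entropies(noise, 128.0, cfg)
        f_sin = all_entropies(sinus, 128.0, cfg)
        for key in f_noise:
            assert f_noise[key] > f_sin[key], key

    def test_template_entropies_affine_invariant(self, rng, cfg):
        x = rng.standard_normal(150)
        y = 3.7 * x - 11.0
        assert sample_entropy(x, cfg) == pytest.approx(
            sample_entropy(y, cfg), abs=1e-9)
        assert approximate_entropy(x, cfg) == pytest.approx(
            approximate_entropy(y, cfg), abs=1e-9)
        assert fuzzy_entropy(x, cfg) == pytest.approx(
            fuzzy_entropy(y, cfg), abs=1e-9)

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_pe_invariant_under_monotone_transform(self, seed):
        cfg = EntropyConfig()
        x = np.random.default_rng(seed).standard_normal(120)
        y = np.exp(2.0 * x) + 1.0  # strictly increasing transform
        assert permutation_entropy(x, cfg) == pytest.approx(
            permutation_entropy(y, cfg), abs=1e-12)

    def test_nonfinite_input_rejected(self, cfg):
        bad = np.array([1.0, np.inf, 2.0] * 20)
        for fn in (sample_entropy, fuzzy_entropy, approximate_entropy,
                   permutation_entropy, singular_spectrum_entropy):
            with pytest.raises(ValueError, match="non-finite"):
                fn(bad, cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EntropyConfig(m=0)
        with pytest.raises(ValueError):
            EntropyConfig(r_frac=0.0)
        with pytest.raises(ValueError):
            EntropyConfig(pe_order=1)
        with pytest.raises(ValueError):
            EntropyConfig(eps=0.0)
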