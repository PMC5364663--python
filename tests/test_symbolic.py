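"""Symbolization, word/code construction and NCSE.

The 10-point worked example anchors exact expected values; brute-force
string-matching oracles and hypothesis property tests cover the general
behaviour.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symentropy.symbolic import (
    SymbolizationParams,
    build_words,
    corrected_shannon_entropy,
    cse_max,
    decode_code,
    effective_threshold,
    encode_words,
    ncse,
    ncse_from_symbols,
    ncse_sweep,
    shannon_entropy,
    symbolize,
    word_histogram,
)

LN2 = math.log(2.0)


def se_string_oracle(symbols, L):
    """Shannon entropy of the L-word distribution by literal string matching."""
    words = ["".join(map(str, symbols[i : i + L]))
             for i in range(len(symbols) - L + 1)]
    m = len(words)
    return -sum((c / m) * math.log2(c / m) for c in Counter(words).values())


class TestWorkedExample:
    def test_mean_threshold(self, worked_series):
        assert effective_threshold(worked_series) == pytest.approx(2.3404, abs=5e-5)

    def test_threshold_with_offset(self, worked_series):
        p = SymbolizationParams(xi=1.2)
        assert effective_threshold(worked_series, p) == pytest.approx(3.5404, abs=5e-5)

    def test_symbols_at_offset(self, worked_series):
        s = symbolize(worked_series, SymbolizationParams(xi=1.2))
        assert s.symbols.tolist() == [0, 0, 1, 1, 1, 0, 0, 0, 0, 0]

    def test_symbols_at_zero_offset_include_sample_above_mean(self, worked_series):
        # 3.4433 >= 2.3404, so the sixth sample symbolizes to 1 at xi=0
        s = symbolize(worked_series, SymbolizationParams(xi=0.0))
        assert s.symbols.tolist() == [0, 0, 1, 1, 1, 1, 0, 0, 0, 0]

    def test_word_series(self, worked_series):
        s = symbolize(worked_series, SymbolizationParams(xi=1.2))
        words = build_words(s, L=3)
        expected = [[0, 0, 1], [0, 1, 1], [1, 1, 1], [1, 1, 0],
                    [1, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]
        assert words.tolist() == expected

    def test_code_series(self, worked_series):
        s = symbolize(worked_series, SymbolizationParams(xi=1.2))
        codes = encode_words(build_words(s, L=3))
        assert codes.codes.tolist() == [1, 3, 7, 6, 4, 0, 0, 0]

    def test_histogram(self, worked_series):
        s = symbolize(worked_series, SymbolizationParams(xi=1.2))
        hist = word_histogram(encode_words(build_words(s, L=3)))
        assert hist.counts == {0: 3, 1: 1, 3: 1, 4: 1, 6: 1, 7: 1}
        assert hist.M_tokens == 8
        assert hist.C_R == 6

    def test_entropy_chain(self, worked_series):
        res = ncse(worked_series, SymbolizationParams(xi=1.2), L=3)
        se = -(3 / 8) * math.log2(3 / 8) - 5 * (1 / 8) * math.log2(1 / 8)
        assert res.se == pytest.approx(se, abs=1e-12)
        assert res.cse == pytest.approx(se + 5 / (16 * LN2), abs=1e-12)
        assert res.cse_max == pytest.approx(3 + 7 / (16 * LN2), abs=1e-12)
        assert res.ncse == pytest.approx((se + 5 / (16 * LN2)) / (3 + 7 / (16 * LN2)),
                                         abs=1e-12)
        assert res.ncse == pytest.approx(0.7866, abs=1e-4)


class TestThresholdAndSymbolize:
    def test_constant_series_threshold(self):
        assert effective_threshold([5.0, 5.0, 5.0]) == 5.0

    def test_offset_adds_to_mean(self):
        assert effective_threshold([0.0, 10.0], SymbolizationParams(xi=2.0)) == 7.0

    def test_deviation_rule_threshold_is_xi(self):
        p = SymbolizationParams(xi=2.0, rule="abs_dev_ge_xi")
        assert effective_threshold([0.0, 10.0], p) == 2.0

    def test_constant_series_all_ones(self):
        s = symbolize([4.0, 4.0, 4.0, 4.0])
        assert s.symbols.tolist() == [1, 1, 1, 1]

    def test_deviation_rule(self):
        p = SymbolizationParams(xi=3.0, rule="abs_dev_ge_xi")
        s = symbolize([0.0, 10.0, 5.0, 5.1], p)  # mean 5.025
        assert s.symbols.tolist() == [1, 1, 0, 0]

    def test_psi_not_two_rejected(self):
        with pytest.raises(ValueError, match="psi"):
            symbolize([1.0, 2.0, 3.0], SymbolizationParams(psi=3))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            effective_threshold(np.array([]))

    @pytest.mark.parametrize("seed", range(5))
    def test_symbolization_monotone_in_xi(self, seed):
        """Raising the offset can only flip 1s to 0s, never the reverse."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300) * rng.uniform(1, 50)
        prev = None
        for xi in np.linspace(0, 3 * x.std(), 8):
            s = symbolize(x, SymbolizationParams(xi=float(xi))).symbols
            if prev is not None:
                assert np.all(s <= prev)
            prev = s


class TestWordsAndCodes:
    def test_single_word(self):
        assert build_words(np.array([1, 0, 1]), L=3).tolist() == [[1, 0, 1]]

    def test_word_count_is_n_minus_l_plus_1(self):
        rng = np.random.default_rng(0)
        for n in (5, 17, 100):
            s = rng.integers(0, 2, n)
            for L in range(1, 6):
                assert build_words(s, L).shape == (n - L + 1, L)

    def test_word_length_errors(self):
        with pytest.raises(ValueError):
            build_words(np.array([0, 1]), L=3)
        with pytest.raises(ValueError):
            build_words(np.array([0, 1, 1]), L=0)

    def test_encode_examples(self):
        assert encode_words(np.array([[0, 0, 0]]), psi=2).codes.tolist() == [0]
        assert encode_words(np.array([[2, 1, 0]]), psi=3).codes.tolist() == [21]

    def test_encode_rejects_out_of_alphabet(self):
        with pytest.raises(ValueError):
            encode_words(np.array([[0, 2]]), psi=2)

    @pytest.mark.parametrize("psi", [2, 3])
    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5])
    def test_encode_decode_roundtrip_exhaustive(self, psi, L):
        for code in range(psi**L):
            word = decode_code(code, L, psi)
            assert encode_words(word, psi).codes[0] == code

    def test_histogram_examples(self):
        hist = word_histogram(np.array([5, 5, 5]), L=3, psi=2)
        assert hist.C_R == 1 and hist.M_tokens == 3
        with pytest.raises(ValueError):
            word_histogram(np.array([], dtype=int), L=3, psi=2)


class TestEntropy:
    def test_uniform_eight_codes(self):
        hist = word_histogram(np.arange(8), L=3, psi=2)
        assert shannon_entropy(hist) == pytest.approx(3.0, abs=1e-12)
        assert corrected_shannon_entropy(hist) == pytest.approx(
            3.0 + 7 / (16 * LN2), abs=1e-12)

    def test_single_code_zero_entropy(self):
        hist = word_histogram(np.zeros(10, dtype=int), L=3, psi=2)
        assert shannon_entropy(hist) == 0.0
        # C_R = 1: the correction term vanishes under both conventions
        assert corrected_shannon_entropy(hist, "cardinality") == 0.0
        assert corrected_shannon_entropy(hist, "tokens") == 0.0

    def test_tokens_convention_denominator(self):
        hist = word_histogram(np.array([0, 1, 2, 3]), L=3, psi=2)
        se = shannon_entropy(hist)
        assert corrected_shannon_entropy(hist, "tokens") == pytest.approx(
            se + 3 / (2 * 4 * LN2), abs=1e-12)
        assert corrected_shannon_entropy(hist, "cardinality") == pytest.approx(
            se + 3 / (2 * 8 * LN2), abs=1e-12)

    def test_cse_max_values(self):
        assert cse_max(3, 2) == pytest.approx(3 + 7 / (16 * LN2), abs=1e-12)
        assert cse_max(1, 2) == pytest.approx(1 + 1 / (4 * LN2), abs=1e-12)

    def test_cse_max_increasing_in_word_length(self):
        for psi in (2, 3):
            values = [cse_max(L, psi) for L in range(1, 8)]
            assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("seed", range(200))
    def test_se_matches_string_matching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        L = int(rng.integers(1, 6))
        x = rng.normal(size=n)
        s = symbolize(x, SymbolizationParams(xi=float(rng.uniform(0, 2))))
        hist = word_histogram(encode_words(build_words(s, L)))
        assert shannon_entropy(hist) == pytest.approx(
            se_string_oracle(s.symbols.tolist(), L), abs=1e-12)


class TestNCSE:
    def test_constant_series_is_zero_not_error(self):
        res = ncse(np.full(50, 3.3), SymbolizationParams())
        assert res.se == 0.0 and res.ncse == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="L\\+1"):
            ncse(np.array([1.0, 2.0, 3.0]), L=3)

    def test_equiprobable_symbols_approach_one(self):
        rng = np.random.default_rng(7)
        symbols = rng.integers(0, 2, 200_000)
        res = ncse_from_symbols(symbols, L=3, psi=2, convention="cardinality")
        assert res.ncse > 0.999

    def test_white_noise_ncse_decreases_with_word_length(self):
        """Longer words weigh the per-symbol entropy deficit more heavily."""
        means = {3: [], 5: []}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=4097)
            params = SymbolizationParams(xi=0.5 * float(x.std()))
            for L in (3, 5):
                means[L].append(ncse(x, params, L=L).ncse)
        assert np.mean(means[3]) > np.mean(means[5])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(8, 300),
        L=st.integers(1, 6),
        xi_frac=st.floats(0, 3),
        heavy=st.booleans(),
        convention=st.sampled_from(["cardinality", "tokens"]),
        rule=st.sampled_from(["ge_mean_plus_xi", "abs_dev_ge_xi"]),
    )
    def test_ncse_bounded(self, seed, n, L, xi_frac, heavy, convention, rule):
        """NCSE lies in [0, 1] for arbitrary series, offsets and settings."""
        rng = np.random.default_rng(seed)
        x = rng.standard_cauchy(n) if heavy else rng.normal(size=n)
        if n < L + 1:
            return
        scale = float(np.median(np.abs(x))) or 1.0
        params = SymbolizationParams(xi=xi_frac * scale, rule=rule)
        res = ncse(x, params, L=L, convention=convention)
        assert 0.0 <= res.ncse <= 1.0
        assert res.cse >= res.se >= 0.0


class TestSweep:
    def test_constant_segment_all_zero(self):
        profile = ncse_sweep([np.full(40, 1.0)], xis=[0.0, 1.0, 2.0])
        assert np.all(profile.values == 0.0)

    def test_single_point_grid_matches_direct_call(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        profile = ncse_sweep([x], xis=[0.7])
        direct = ncse(x, SymbolizationParams(xi=0.7))
        assert profile.values[0, 0] == pytest.approx(direct.ncse, abs=1e-15)

    def test_mean_sd_shapes(self):
        rng = np.random.default_rng(4)
        segs = [rng.normal(size=200) for _ in range(5)]
        profile = ncse_sweep(segs, xis=[0.0, 0.5, 1.0])
        assert profile.values.shape == (5, 3)
        assert profile.mean.shape == (3,) and profile.sd.shape == (3,)
        assert np.allclose(profile.mean, profile.values.mean(axis=0))

    def test_grid_validation(self):
        x = np.random.default_rng(0).normal(size=50)
        with pytest.raises(ValueError):
            ncse_sweep([x], xis=[])
        with pytest.raises(ValueError):
            ncse_sweep([x], xis=[2.0, 1.0])
        with pytest.raises(ValueError):
            ncse_sweep([x], xis=[-1.0, 0.0])

    def test_short_segment_named_in_error(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="segment 1"):
            ncse_sweep([rng.normal(size=50), rng.normal(size=3)], xis=[0.0])
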