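"""KS, Mann-Whitney, binomial sub-threshold test, cumulative curves."""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cultepi import (
    SampleSet,
    binomial_tail,
    compare_distributions,
    cumulative_curves,
    ks_two_sample,
    mann_whitney,
    subthreshold_binomial,
)


def brute_ks(a, b):
    """sup |F_a - F_b| over the union of sample points."""
    pts = sorted(set(a) | set(b))
    return max(
        abs(sum(x <= t for x in a) / len(a) - sum(y <= t for y in b) / len(b))
        for t in pts
    )


def brute_u(a, b):
    """Pairs where a > b, ties counting one half."""
    return sum((x > y) + 0.5 * (x == y) for x, y in product(a, b))


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1.0, 2.0], [10.0, 11.0])
        assert d == 1.0
        assert p < 0.5

    def test_staircase_example(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    @given(
        a=st.lists(st.integers(0, 9), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_enumeration(self, a, b):
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(brute_ks(a, b))


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_tied_singletons(self):
        u, _ = mann_whitney([5.0], [5.0])
        assert u == 0.5

    def test_interleaved(self):
        u, _ = mann_whitney([1, 3, 5], [2, 4, 6])
        assert u == 3.0

    @given(
        a=st.lists(st.integers(0, 9), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_bruteforce_enumeration(self, a, b):
        u, _ = mann_whitney(a, b)
        assert u == pytest.approx(brute_u(a, b))


class TestBinomialTail:
    def test_printed_triples(self):
        """Tail probabilities recomputed from printed (k, n, p) rows.

        p values are printed rounded to 2 decimals, so tiny tails are only
        reproducible to order of magnitude; the 0.02 case survives rounding.
        """
        assert round(binomial_tail(1, 28, 0.19), 2) == 0.02
        t = binomial_tail(5, 74, 0.39)
        assert abs(np.log10(t) - np.log10(2.87e-10)) < 0.5

    def test_k_equals_n(self):
        assert binomial_tail(30, 30, 0.37) == pytest.approx(1.0)

    def test_exact_rational_oracle(self):
        """Log-space accumulation agrees with exact Fraction arithmetic."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(1, 31))
            k = int(rng.integers(0, n + 1))
            num, den = int(rng.integers(1, 100)), 100
            p = Fraction(num, den)
            exact = sum(
                Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j)
                for j in range(k + 1)
            )
            got = binomial_tail(k, n, num / den)
            assert got == pytest.approx(float(exact), rel=1e-10)

    def test_monotone_in_k_and_p(self):
        """Tail nondecreasing in k (fixed n, p) and nonincreasing in p
        (fixed k, n); cross-checked against a simulation oracle at n=40."""
        n = 40
        tails_k = [binomial_tail(k, n, 0.3) for k in range(n + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(tails_k, tails_k[1:]))
        tails_p = [binomial_tail(8, n, p) for p in np.linspace(0.01, 0.99, 25)]
        assert all(a >= b - 1e-15 for a, b in zip(tails_p, tails_p[1:]))
        rng = np.random.default_rng(5)
        sim = (rng.binomial(n, 0.3, 200_000) <= 8).mean()
        assert binomial_tail(8, n, 0.3) == pytest.approx(sim, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_tail(0, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(5, 3, 0.5)


class TestSubthreshold:
    def test_counts_and_proportion(self):
        s = SampleSet(density=np.array([1.0, 5.0, 20.0, 2.0, 8.0, 30.0]),
                      is_site=np.array([True, True, True, False, False, False]))
        res = subthreshold_binomial(s, 10.0)
        assert (res.k, res.n) == (2, 3)
        assert res.p == pytest.approx(2 / 3)

    def test_strict_vs_inclusive_convention(self):
        s = SampleSet(density=np.array([10.0, 20.0, 10.0, 30.0]),
                      is_site=np.array([True, True, False, False]))
        strict = subthreshold_binomial(s, 10.0)
        inclusive = subthreshold_binomial(s, 10.0, inclusive=True)
        assert strict.k == 0 and inclusive.k == 1

    def test_requires_sites(self):
        s = SampleSet(density=np.array([1.0]), is_site=np.array([False]))
        with pytest.raises(ValueError):
            subthreshold_binomial(s, 10.0)


class TestCurvesAndSummary:
    def test_cdf_properties(self, epi_samples):
        support, f_s, f_n = cumulative_curves(epi_samples)
        for f in (f_s, f_n):
            assert f[-1] == pytest.approx(1.0)
            assert np.all(np.diff(f) >= 0)
        assert np.all(np.diff(support) > 0)

    def test_site_cdf_consistent_with_subthreshold_count(self, epi_samples):
        threshold = 12.25
        res = subthreshold_binomial(epi_samples, threshold, inclusive=True)
        support, f_s, _ = cumulative_curves(epi_samples)
        idx = np.searchsorted(support, threshold, side="right") - 1
        cdf_at = f_s[idx] if idx >= 0 else 0.0
        assert cdf_at == pytest.approx(res.k / res.n)

    def test_compare_distributions_fields(self, epi_samples):
        cmp = compare_distributions(epi_samples)
        assert cmp.median_sites > cmp.median_nonsites
        assert 0 <= cmp.ks_d <= 1
        assert 0 <= cmp.ks_p <= 1
        assert cmp.n_cells == len(epi_samples)
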