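"""Tests for linear measures, DFA, entropies, coarse-graining, MSE and CI.

The entropy implementations are checked against slow, exhaustive
double-loop template-counting oracles on short series.
"""

import math

import numpy as np
import pytest

from gaitcx.measures import (EntropyParams, apen, coarse_grain,
                             complexity_index, dfa, linear_measures, mse,
                             saen)
from gaitcx.synthetic import fractional_gaussian_noise


# ---------------------------------------------------------------- oracles
def cheb(x, i, j, m):
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def saen_brute(x, m, r):
    n = len(x)
    nt = n - m
    b = sum(cheb(x, i, j, m) <= r
            for i in range(nt) for j in range(i + 1, nt))
    a = sum(cheb(x, i, j, m + 1) <= r
            for i in range(nt) for j in range(i + 1, nt))
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def apen_brute(x, m, r):
    n = len(x)

    def phi(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            c = sum(cheb(x, i, j, mm) <= r for j in range(nt))
            total += math.log(c / nt)
        return total / nt

    return phi(m) - phi(m + 1)


# ------------------------------------------------------------------ tests
class TestLinearMeasures:
    def test_zero_variance(self):
        xisi, sd, cov = linear_measures(np.full(20, 1.12))
        assert xisi == pytest.approx(1.12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert cov == pytest.approx(0.0, abs=1e-10)

    def test_cov_definition(self):
        rng = np.random.default_rng(0)
        x = 1.0 + 0.04 * rng.standard_normal(100)
        xisi, sd, cov = linear_measures(x)
        assert cov == pytest.approx(100 * sd / xisi)

    def test_alternating_series_hand_value(self):
        x = np.tile([1.0, 1.2], 10)
        xisi, sd, cov = linear_measures(x)
        assert xisi == pytest.approx(1.1)
        assert sd == pytest.approx(np.std(x, ddof=1))

    def test_short_bout_rejected(self):
        with pytest.raises(ValueError):
            linear_measures(np.full(19, 1.1))


class TestDfa:
    def test_white_noise_alpha_near_half(self):
        alphas = [dfa(np.random.default_rng(100 + s).standard_normal(1000)).alpha
                  for s in range(20)]
        assert 0.45 < np.mean(alphas) < 0.55

    def test_fgn_alpha_tracks_hurst(self):
        means = []
        for hurst in (0.5, 0.7, 0.9):
            alphas = []
            for s in range(20):
                rng = np.random.default_rng(200 + s)
                alphas.append(dfa(fractional_gaussian_noise(1000, hurst, rng)).alpha)
            means.append(np.mean(alphas))
            assert abs(means[-1] - hurst) < 0.10
        assert means[0] < means[1] < means[2]

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = 1.12 + 0.04 * rng.standard_normal(500)
        a1 = dfa(x).alpha
        a2 = dfa(3.7 * x - 11.0).alpha
        assert a1 == pytest.approx(a2, abs=1e-10)

    def test_fluctuation_positive_at_every_box_size(self):
        x = np.random.default_rng(1).standard_normal(400)
        res = dfa(x)
        assert res.box_sizes[0] == 10 and res.box_sizes[-1] == 40
        assert np.all(res.fluctuation > 0)

    def test_short_or_constant_series_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.random.default_rng(0).standard_normal(100))
        with pytest.raises(ValueError):
            dfa(np.full(400, 1.0))


class TestEntropies:
    @pytest.mark.parametrize("seed", range(10))
    def test_saen_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(1.12, 0.05, rng.integers(20, 51))
        params = EntropyParams.from_series(x)
        expected = saen_brute(list(x), params.m, params.r)
        got = saen(x, params)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_apen_equals_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(1.12, 0.05, rng.integers(20, 51))
        params = EntropyParams.from_series(x)
        assert apen(x, params) == pytest.approx(
            apen_brute(list(x), params.m, params.r), abs=1e-12)

    def test_saen_periodic_exactly_zero(self):
        x = np.tile([1.1, 1.2], 150)
        params = EntropyParams(m=2, r_fraction=0.15, r=0.05 * 0.1)
        assert saen(x, params) == 0.0

    def test_saen_hand_enumerable_series(self):
        # templates of [1,2,1,2,1,3]: B=2 m-matches, A=1 extension
        x = [1.0, 2.0, 1.0, 2.0, 1.0, 3.0]
        params = EntropyParams(m=2, r_fraction=0.15, r=0.5)
        assert saen(x, params) == pytest.approx(math.log(2.0), abs=1e-12)
        assert saen_brute(x, 2, 0.5) == pytest.approx(math.log(2.0))

    def test_apen_periodic_near_zero(self):
        x = np.tile([1.1, 1.2], 200)
        params = EntropyParams(m=2, r_fraction=0.15, r=0.05 * 0.1)
        assert apen(x, params) < 0.05

    def test_apen_stable_under_permutation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.12, 0.04, 600)
        params = EntropyParams.from_series(x)
        a1 = apen(rng.permutation(x), params)
        a2 = apen(rng.permutation(x), params)
        assert abs(a1 - a2) < 0.1

    def test_saen_undefined_returns_none_with_warning(self):
        x = np.arange(30, dtype=float)  # strictly increasing, no matches
        params = EntropyParams(m=2, r_fraction=0.15, r=0.01)
        with pytest.warns(UserWarning):
            assert saen(x, params) is None

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            apen(np.ones(50), EntropyParams(m=2, r_fraction=0.15, r=0.0))
        with pytest.raises(ValueError):
            EntropyParams.from_series(np.ones(50))


class TestCoarseGrainMse:
    def test_scale_one_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_hand_arithmetic(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])

    def test_output_length_floor(self):
        rng = np.random.default_rng(0)
        for n, tau in [(800, 3), (801, 4), (17, 5)]:
            assert coarse_grain(rng.normal(size=n), tau).size == n // tau

    def test_mse_scale1_equals_saen(self):
        rng = np.random.default_rng(4)
        x = 1.12 + 0.04 * rng.standard_normal(800)
        params = EntropyParams.from_series(x)
        res = mse(x, params=params)
        assert res.values[1] == pytest.approx(saen(x, params), abs=1e-12)

    def test_mse_lengths_800_400_266_200(self):
        x = 1.12 + 0.04 * np.random.default_rng(5).standard_normal(800)
        res = mse(x)
        assert [res.lengths[tau] for tau in (1, 2, 3, 4)] == [800, 400, 266, 200]

    def test_mse_requires_800_by_default(self):
        with pytest.raises(ValueError):
            mse(np.random.default_rng(0).normal(size=500))

    def test_white_noise_entropy_decreases_with_scale(self):
        curves = []
        for s in range(5):
            rng = np.random.default_rng(300 + s)
            x = 1.12 + 0.04 * rng.standard_normal(800)
            res = mse(x)
            curves.append([res.values[tau] for tau in (1, 2, 3, 4)])
        mean = np.mean(curves, axis=0)
        assert mean[0] > mean[-1]


class TestComplexityIndex:
    def test_hand_trapezoid(self):
        assert complexity_index([2.0, 3.0, 2.0, 2.0]) == pytest.approx(7.0)

    def test_constant_curve(self):
        assert complexity_index([1.5] * 4) == pytest.approx(4.5)

    def test_zero_curve(self):
        assert complexity_index([0.0] * 4) == 0.0

    def test_null_scale_rejected(self):
        with pytest.raises(ValueError):
            complexity_index([1.0, None, 1.0, 1.0])
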