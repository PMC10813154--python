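"""Feature-math checks against independent brute-force and analytic oracles."""

import numpy as np
import pytest

from ecgdyn import (FEATURE_NAMES, FeatureParams, approximate_entropy,
                    correlation_dimension, detrended_fluctuation, energy,
                    extract_all, higuchi_fd, hurst_exponent, katz_fd,
                    log_energy_entropy, lyapunov_exponent,
                    shannon_energy_entropy)


# --- independent oracles ----------------------------------------------------

def apen_bruteforce(x, m, r):
    """Naive O(n^2) double-loop template counting (Pincus definition)."""
    n = len(x)

    def phi(mm):
        templates = [x[i: i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            c = sum(1 for b in templates if np.max(np.abs(a - b)) <= r)
            total += np.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def corr_sum_bruteforce(emb, radii, k):
    """Naive double-loop Grassberger-Procaccia correlation sum."""
    M = len(emb)
    out = np.zeros(len(radii))
    n_pairs = 0
    for i in range(M):
        for j in range(i + k, M):
            d = np.linalg.norm(emb[i] - emb[j])
            n_pairs += 1
            out += d <= radii
    return out / n_pairs


def logistic_series(n, x0=0.3, burn=500):
    x = x0
    out = []
    for _ in range(n + burn):
        x = 4.0 * x * (1.0 - x)
        out.append(x)
    return np.array(out[burn:])


class TestApEn:
    def test_matches_bruteforce(self, rng):
        for n in (50, 120, 200):
            x = rng.uniform(size=n)
            p = FeatureParams()
            r = p.apen_r_factor * np.std(x)
            assert abs(approximate_entropy(x, p)
                       - apen_bruteforce(x, p.apen_m, r)) < 1e-12

    def test_constant_is_zero(self):
        assert approximate_entropy(np.full(100, 5.0)) == 0.0

    def test_periodic_below_noise(self, rng):
        periodic = np.tile([1.0, 2.0], 100)
        noise = rng.standard_normal(200)
        assert approximate_entropy(periodic) < approximate_entropy(noise)


class TestCorrDim:
    def test_correlation_sum_matches_bruteforce(self, rng):
        from ecgdyn.features import _delay_embed
        x = rng.uniform(size=80)
        p = FeatureParams()
        emb = _delay_embed(x, p.corrdim_embed, p.corrdim_delay)
        from scipy.spatial.distance import pdist
        d = pdist(emb)
        radii = np.quantile(d[d > 0], [0.1, 0.3, 0.6])
        brute = corr_sum_bruteforce(emb, radii, k=1)
        fast = np.searchsorted(np.sort(d), radii, side="right") / d.size
        np.testing.assert_allclose(fast, brute, atol=1e-12)

    def test_sine_is_one_dimensional(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 100.0)
        p = FeatureParams(corrdim_delay=25)  # quarter period
        assert abs(correlation_dimension(x, p) - 1.0) <= 0.15

    def test_noise_fills_the_plane(self, rng):
        x = rng.uniform(size=2000)
        assert abs(correlation_dimension(x) - 2.0) <= 0.3

    def test_constant_is_zero(self):
        assert correlation_dimension(np.ones(100)) == 0.0


class TestDFA:
    def test_white_noise_exponent(self, rng):
        assert abs(detrended_fluctuation(rng.standard_normal(2000)) - 0.5) <= 0.1

    def test_random_walk_exponent(self, rng):
        walk = np.cumsum(rng.standard_normal(2000))
        assert abs(detrended_fluctuation(walk) - 1.5) <= 0.15

    def test_fluctuations_nonnegative(self, rng):
        from ecgdyn.features import _dfa_fluctuations, dfa_scale_grid
        x = rng.standard_normal(1000)
        f = _dfa_fluctuations(x, dfa_scale_grid(1000, 12), order=1)
        assert np.all(f >= 0)

    def test_zero_variance_sentinel(self):
        assert detrended_fluctuation(np.full(500, 2.0)) == 0.0


class TestEnergy:
    def test_direct_value(self):
        assert energy([1.0, 2.0, 3.0]) == 14.0
        assert energy(np.zeros(10)) == 0.0

    def test_quadratic_homogeneity(self, rng):
        x = rng.normal(size=64)
        np.testing.assert_allclose(energy(3.0 * x), 9.0 * energy(x))


class TestHiguchi:
    def test_line_has_dimension_one(self):
        assert abs(higuchi_fd(np.arange(1000.0)) - 1.0) <= 0.02

    def test_white_noise_near_two(self, rng):
        assert abs(higuchi_fd(rng.standard_normal(2000)) - 2.0) <= 0.1

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        np.testing.assert_allclose(higuchi_fd(3.5 * x + 2.0), higuchi_fd(x),
                                   rtol=1e-9)

    def test_constant_convention(self):
        assert higuchi_fd(np.full(500, 1.0)) == 1.0


class TestHurst:
    def test_gaussian_increments_give_half(self, rng):
        assert abs(hurst_exponent(rng.standard_normal(4000)) - 0.5) <= 0.1

    def test_trend_is_persistent(self, rng):
        x = np.arange(2000, dtype=float) + 0.1 * rng.standard_normal(2000)
        assert hurst_exponent(x) > 0.8

    def test_monofractal_q1_q2_agreement(self, rng):
        x = rng.standard_normal(4000)
        h1 = hurst_exponent(x, FeatureParams(hurst_q=1))
        h2 = hurst_exponent(x, FeatureParams(hurst_q=2))
        assert abs(h1 - h2) <= 0.05

    def test_zero_variance_sentinel(self):
        assert hurst_exponent(np.full(500, 3.0)) == 0.5


class TestKatz:
    def test_straight_line_exactly_one(self):
        assert katz_fd(np.arange(100.0) * 0.7 + 2.0) == 1.0

    def test_alternating_exceeds_one(self):
        x = np.array([0.0, 1.0] * 50)
        # direct formula evaluation: L and d with unit abscissa steps
        L = np.sum(np.sqrt(1.0 + np.diff(x) ** 2))
        i = np.arange(len(x), dtype=float)
        d = np.max(np.sqrt(i ** 2 + (x - x[0]) ** 2)[1:])
        n = len(x) - 1
        expected = np.log10(n) / (np.log10(n) + np.log10(d / L))
        assert katz_fd(x) == pytest.approx(expected)
        assert katz_fd(x) > 1.0

    def test_constant_convention(self):
        assert katz_fd(np.full(10, 4.2)) == 1.0


class TestEntropies:
    def test_log_energy_examples(self):
        assert log_energy_entropy([1.0, 1.0]) == 0.0
        assert log_energy_entropy([2.0]) == 2.0

    def test_log_energy_zero_sample_floored(self):
        p = FeatureParams()
        val = log_energy_entropy([1.0, 0.0], p)
        assert np.isfinite(val)
        assert val == pytest.approx(np.log2(p.eps))

    def test_shannon_examples(self):
        assert shannon_energy_entropy([1.0, 0.0, 0.0]) == 0.0
        assert shannon_energy_entropy([1.0, 1.0], normalized=True) == \
            pytest.approx(1.0)

    def test_shannon_modes_agree_at_unit_energy(self, rng):
        x = rng.normal(size=64)
        x = x / np.linalg.norm(x)
        assert shannon_energy_entropy(x) == pytest.approx(
            shannon_energy_entropy(x, normalized=True))


class TestLyapunov:
    def test_logistic_map_matches_analytic(self):
        x = logistic_series(2000)
        # analytic oracle: lambda = mean ln |f'(x)| with f'(x) = 4 - 8x
        analytic = np.mean(np.log(np.abs(4.0 - 8.0 * x)))
        assert analytic == pytest.approx(np.log(2.0), abs=0.02)
        assert abs(lyapunov_exponent(x) - np.log(2.0)) <= 0.1

    def test_sine_is_regular(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 100.0)
        assert lyapunov_exponent(x) <= 0.05

    def test_white_noise_diverges(self, rng):
        assert lyapunov_exponent(rng.standard_normal(1000)) > 0.0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            lyapunov_exponent(np.zeros(100))


class TestExtractAll:
    def test_ten_finite_values_in_order(self, rng):
        out = extract_all(rng.standard_normal(1000))
        assert tuple(out) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in out.values())

    def test_deterministic(self, rng):
        x = rng.standard_normal(600)
        a = extract_all(x)
        b = extract_all(x.copy())
        assert a == b  # bitwise

    def test_constant_segment_sentinels(self):
        out = extract_all(np.full(1000, 2.0))
        assert out["ApEn"] == 0.0
        assert out["CorrDim"] == 0.0
        assert out["DFA"] == 0.0
        assert out["En"] == pytest.approx(4000.0)
        assert out["H"] == 1.0
        assert out["EH"] == 0.5
        assert out["K"] == 1.0
        assert out["ELay"] == 0.0
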