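"""Estimators: DFA, spectral exponent, sample/multiscale entropy, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boldcomplexity import (
    DegenerateSeriesError,
    RoiTimeSeries,
    ValidationError,
    coarse_grain,
    complexity_index,
    complexity_map,
    dfa_hurst,
    gen_colored_noise,
    gen_fgn,
    map_correlation,
    mse_curve,
    rsn_summary,
    sample_entropy,
    spectral_exponent,
    welch_psd,
)
from boldcomplexity.complexity import MseCurve, dfa_hurst_batch

from conftest import sampen_bruteforce


class TestDfa:
    def test_recovers_fgn_hurst(self):
        estimates = [dfa_hurst(gen_fgn(0.8, 4096, seed=s))[0]
                     for s in range(30)]
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.05)

    @pytest.mark.parametrize("series,order", [
        (np.full(512, 3.0), 1),              # constant
        (np.arange(512, dtype=float), 1),    # pure ramp, linear detrend
        (np.arange(512, dtype=float) ** 2, 2),
    ])
    def test_polynomial_input_is_degenerate(self, series, order):
        with pytest.raises(DegenerateSeriesError):
            dfa_hurst(series, detrend_order=order)

    def test_window_preconditions(self):
        with pytest.raises(ValidationError):
            dfa_hurst(np.random.default_rng(0).standard_normal(32))
        with pytest.raises(ValidationError):
            dfa_hurst(np.random.default_rng(0).standard_normal(256),
                      window_range=(10, 100))  # window_max > n/4

    def test_batch_matches_single(self, rng):
        values = rng.standard_normal((512, 4))
        batch = dfa_hurst_batch(values)
        singles = [dfa_hurst(values[:, j])[0] for j in range(4)]
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_fluctuation_curve_is_increasing(self, rng):
        _, (sizes, fluct) = dfa_hurst(rng.standard_normal(2048))
        assert np.all(np.diff(sizes) > 0)
        assert fluct[-1] > fluct[0]


class TestWelchPsd:
    def test_sinusoid_peak_location(self):
        tr = 0.72
        t = np.arange(512) * tr
        x = np.sin(2 * np.pi * 0.05 * t)
        freqs, power = welch_psd(x, tr)
        f_peak = freqs[np.argmax(power)]
        df = freqs[1] - freqs[0]
        assert abs(f_peak - 0.05) <= df

    def test_white_noise_flat(self):
        slopes = [spectral_exponent(*welch_psd(
            np.random.default_rng(s).standard_normal(4096), 0.72))
            for s in range(10)]
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.1)

    def test_normalization(self, rng):
        _, power = welch_psd(rng.standard_normal(512), 0.72, normalize=True)
        assert power.max() == 1.0

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValidationError):
            welch_psd(rng.standard_normal(16), 0.72)


class TestSpectralExponent:
    def test_exact_power_law(self):
        f = np.linspace(0.01, 0.2, 40)
        assert spectral_exponent(f, f ** -1.0) == pytest.approx(1.0, abs=1e-12)
        assert spectral_exponent(f, f ** -2.5) == pytest.approx(2.5, abs=1e-12)

    def test_zero_power_bins_dropped(self):
        f = np.linspace(0.01, 0.2, 40)
        p = f ** -1.0
        p[3] = 0.0
        assert spectral_exponent(f, p) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_bins_rejected(self):
        f = np.array([0.02, 0.05, 0.1, 0.15])
        with pytest.raises(ValidationError):
            spectral_exponent(f, f ** -1.0)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(50, 2.5), m=2, r_abs=0.5) == 0.0

    def test_fixture_matches_bruteforce(self):
        # strict < 1.0 leaves no length-2 template matches here, so both
        # implementations must agree the entropy is undefined
        x = [1.0, 3.0, 2.0, 4.0, 3.0, 5.0]
        got = sample_entropy(np.array(x), m=2, r_abs=1.0)
        want = sampen_bruteforce(x, 2, 1.0)
        assert math.isnan(got) == math.isnan(want)
        # a tolerance with matches must agree exactly
        got = sample_entropy(np.array(x), m=2, r_abs=1.5)
        want = sampen_bruteforce(x, 2, 1.5)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)

    def test_bruteforce_equality_random_series(self):
        rng = np.random.default_rng(77)
        for n in range(5, 13):
            for m in (1, 2):
                for r_scale in (0.3, 1.0):
                    x = rng.standard_normal(n)
                    if n <= m + 1:
                        continue
                    r = r_scale * x.std()
                    got = sample_entropy(x, m=m, r_abs=r)
                    want = sampen_bruteforce(x, m, r)
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)

    def test_gaussian_closed_form(self):
        # for i.i.d. Gaussians SampEn → −ln(2Φ(r/σ√2) − 1), independent of m
        from scipy.stats import norm

        x = np.random.default_rng(5).standard_normal(10000)
        expected = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
        assert sample_entropy(x, m=2, r_abs=0.2 * x.std()) == pytest.approx(
            expected, abs=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            sample_entropy(np.arange(3.0), m=2, r_abs=1.0)
        with pytest.raises(ValidationError):
            sample_entropy(np.arange(10.0), m=2, r_abs=0.0)


class TestCoarseGrainAndMse:
    @pytest.mark.parametrize("x,tau,expected", [
        ([1.0, 2.0, 3.0, 4.0], 1, [1.0, 2.0, 3.0, 4.0]),
        ([1.0, 2.0, 3.0, 4.0], 2, [1.5, 3.5]),
        ([1.0, 2.0, 3.0, 4.0, 5.0], 2, [1.5, 3.5]),
    ])
    def test_coarse_grain(self, x, tau, expected):
        np.testing.assert_array_equal(coarse_grain(np.array(x), tau), expected)

    def test_scale_one_equals_plain_sample_entropy(self, rng):
        x = rng.standard_normal(512)
        curve = mse_curve(x, scales=range(1, 6))
        direct = sample_entropy(x, m=2, r_abs=0.15 * x.std())
        assert curve.entropy[0] == direct

    def test_short_scales_marked_undefined(self, rng):
        x = rng.standard_normal(100)
        curve = mse_curve(x, scales=(1, 2, 5))  # scale 5 → 20 < 30 samples
        assert curve.defined[0] and curve.defined[1]
        assert not curve.defined[2]

    def test_constant_series_all_zero(self):
        curve = mse_curve(np.full(200, 1.0), scales=range(1, 6))
        np.testing.assert_array_equal(curve.entropy, np.zeros(5))

    def test_white_noise_entropy_decreases(self):
        x = gen_colored_noise(0.0, 4096, seed=8)
        curve = mse_curve(x, scales=range(1, 6))
        assert np.all(np.diff(curve.entropy) < 0)

    def test_pink_flatter_than_white(self):
        white = mse_curve(gen_colored_noise(0.0, 4096, seed=9),
                          scales=range(1, 6))
        pink = mse_curve(gen_colored_noise(1.0, 4096, seed=9),
                         scales=range(1, 6))
        drop_white = white.entropy[0] - white.entropy[4]
        assert abs(pink.entropy[4] - pink.entropy[0]) < drop_white


class TestComplexityIndex:
    def test_flat_curve_closed_form(self):
        curve = MseCurve(scales=np.arange(1, 7), entropy=np.full(6, 1.3),
                         m=2, r_frac=0.15, r_abs=0.2)
        assert complexity_index(curve) == pytest.approx(1.3 * 5)

    def test_single_defined_scale_undefined(self):
        curve = MseCurve(scales=np.arange(1, 4),
                         entropy=np.array([1.0, np.nan, np.nan]),
                         m=2, r_frac=0.15, r_abs=0.2)
        assert math.isnan(complexity_index(curve))

    def test_integrates_leading_run_only(self):
        curve = MseCurve(scales=np.arange(1, 6),
                         entropy=np.array([1.0, 1.0, np.nan, 5.0, 5.0]),
                         m=2, r_frac=0.15, r_abs=0.2)
        assert complexity_index(curve) == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(512)
        a = complexity_index(mse_curve(x))
        b = complexity_index(mse_curve(x + 100.0))
        assert a == pytest.approx(b, abs=1e-2)


class TestComplexityMap:
    def test_white_vs_pink_ordering(self):
        values = np.column_stack([gen_colored_noise(0.0, 4096, seed=1),
                                  gen_colored_noise(1.0, 4096, seed=2)])
        data = RoiTimeSeries(values, tr=0.72, roi_labels=["white", "pink"])
        cmap = complexity_map(data)
        assert cmap.n_roi == 2
        assert cmap.hurst[1] > cmap.hurst[0]
        assert cmap.complexity_index[1] > cmap.complexity_index[0]

    def test_identical_columns_identical_values(self, rng):
        col = rng.standard_normal(256)
        data = RoiTimeSeries(np.column_stack([col, col]), tr=0.72)
        cmap = complexity_map(data)
        assert cmap.hurst[0] == cmap.hurst[1]
        assert cmap.spectral_exponent[0] == cmap.spectral_exponent[1]
        assert cmap.complexity_index[0] == cmap.complexity_index[1]

    def test_metadata_records_parameters(self, rng):
        data = RoiTimeSeries(rng.standard_normal((256, 3)), tr=0.72)
        cmap = complexity_map(data, m=3, r_frac=0.2)
        assert cmap.metadata["mse"]["m"] == 3
        assert cmap.metadata["mse"]["r_frac"] == 0.2
        assert len(cmap.mse_frame()) == 3 * 10


class TestMapSummaries:
    def test_correlation_identities(self, rng):
        a = rng.standard_normal(50)
        assert map_correlation(a, a) == pytest.approx(1.0)
        assert map_correlation(a, -a) == pytest.approx(-1.0)

    def test_correlation_pairwise_complete(self, rng):
        a = rng.standard_normal(50)
        b = 2 * a.copy()
        a[3] = np.nan
        b[7] = np.nan
        assert map_correlation(a, b) == pytest.approx(1.0)

    def test_rsn_summary_manual_fixture(self):
        values = np.array([1.0, 3.0, 10.0, 20.0])
        labels = ["r0", "r1", "r2", "r3"]
        partition = {"r0": "A", "r1": "A", "r2": "B", "r3": "B"}
        out = rsn_summary(values, labels, partition).set_index("network")
        assert out.loc["A", "mean"] == pytest.approx(2.0)
        assert out.loc["A", "std"] == pytest.approx(np.std([1, 3], ddof=1))
        assert out.loc["B", "mean"] == pytest.approx(15.0)
        assert out.loc["B", "n_roi"] == 2

    def test_rsn_summary_permutation_invariant(self, rng):
        values = rng.standard_normal(6)
        labels = [f"r{i}" for i in range(6)]
        partition = {l: ("X" if i % 2 else "Y") for i, l in enumerate(labels)}
        base = rsn_summary(values, labels, partition)
        perm = rng.permutation(6)
        permuted = rsn_summary(values[perm], [labels[i] for i in perm],
                               partition)
        assert base.equals(permuted)

    def test_single_network_is_overall(self, rng):
        values = rng.standard_normal(5)
        labels = [f"r{i}" for i in range(5)]
        out = rsn_summary(values, labels, {l: "all" for l in labels})
        assert len(out) == 1
        assert out.loc[0, "mean"] == pytest.approx(values.mean())


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(2, 6), st.integers(20, 60))
def test_coarse_grain_properties(tau, n):
    """Length floor(n/τ) and mean preservation over the used prefix."""
    x = np.random.default_rng(n * 7 + tau).standard_normal(n)
    out = coarse_grain(x, tau)
    assert out.size == n // tau
    used = x[: out.size * tau]
    assert np.mean(out) == pytest.approx(np.mean(used), abs=1e-12)
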