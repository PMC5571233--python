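"""The 131-feature extractor: registry, family oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from kafohar.features import (
    FAMILY_SIZES,
    FEATURE_NAMES,
    N_FEATURES,
    extract_features,
    extract_features_batch,
    family_slices,
    periodogram,
)
from kafohar.io import ValidationError
from kafohar.windowing import Window


def _window(a, rate=30.0, activity="walk"):
    return Window(
        a=np.asarray(a, float),
        activity=activity,
        subject_id="P01",
        group="patient",
        device="novel",
        session_id="S1",
        start_s=0.0,
        sample_rate_hz=rate,
    )


def _features(a, rate=30.0):
    return dict(zip(FEATURE_NAMES, extract_features(_window(a, rate=rate))))


RNG = np.random.default_rng(2024)
SLICES = family_slices()


class TestRegistry:
    def test_131_features_partitioned_into_11_families(self):
        assert N_FEATURES == 131
        assert FAMILY_SIZES == (9, 9, 12, 12, 1, 1, 3, 6, 6, 12, 60)
        assert sum(FAMILY_SIZES) == 131
        assert len(set(FEATURE_NAMES)) == 131

    def test_any_valid_window_yields_131(self):
        vec = extract_features(_window(RNG.normal(size=(3, 180))))
        assert vec.shape == (131,)
        assert np.all(np.isfinite(vec))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValidationError):
            extract_features(_window(np.zeros((3, 4))))


class TestDegenerateWindows:
    def test_all_zero_window(self):
        f = _features(np.zeros((3, 180)))
        for name in ("mean_x", "range_y", "iqr_z", "sd_x", "skew_y", "kurt_z",
                     "sq_norm_mean", "sd_sum", "pearson_r_xy", "cp_raw_xz", "cp_norm_yz"):
            assert f[name] == 0.0
        assert all(f[n] == 0.0 for n in FEATURE_NAMES if n.startswith(("zhist", "band")))

    def test_constant_gravity_window(self):
        a = np.tile(np.array([[0.0], [0.0], [1.0]]), (1, 180))
        f = _features(a)
        assert f["sq_norm_mean"] == pytest.approx(1.0)
        assert f["sd_sum"] == 0.0
        assert f["cp_raw_yz"] == pytest.approx(0.0)  # product of means, one mean is 0
        assert f["cp_raw_xy"] == pytest.approx(0.0)
        assert all(f[n] == 0.0 for n in FEATURE_NAMES if n.startswith("band"))

    def test_collinear_axes_have_unit_correlation(self):
        x = RNG.normal(size=180)
        f = _features(np.vstack([x, 2 * x, x]))
        assert f["pearson_r_xy"] == pytest.approx(1.0)
        assert f["pearson_r_xz"] == pytest.approx(1.0)
        assert f["pearson_r_yz"] == pytest.approx(1.0)


class TestBasicStats:
    def test_constant_axis(self):
        f = _features(np.vstack([np.ones(8), np.zeros(8), np.zeros(8)]))
        assert (f["mean_x"], f["range_x"], f["iqr_x"]) == (1.0, 0.0, 0.0)

    def test_ramp_axis(self):
        a = np.vstack([np.tile([0.0, 1.0, 2.0, 3.0], 2), np.zeros(8), np.zeros(8)])
        f = _features(a)
        assert f["mean_x"] == pytest.approx(1.5)
        assert f["range_x"] == pytest.approx(3.0)

    def test_iqr_linear_interpolation_oracle(self):
        # sorted axis (0,0,1,1,2,2,3,3); linear-interpolated quantiles sit at
        # position p*(n-1): Q1 = 0 + 0.75*(1-0) = 0.75, Q3 = 2 + 0.25*(3-2) = 2.25
        a = np.vstack([[0.0, 1.0, 2.0, 3.0] * 2, np.zeros(8), np.zeros(8)])
        f = _features(a)
        assert f["iqr_x"] == pytest.approx(2.25 - 0.75)


class TestMoments:
    def test_symmetric_axis_has_zero_skew(self):
        a = np.vstack([np.tile([-1.0, 1.0], 90), np.zeros(180), np.zeros(180)])
        f = _features(a)
        assert f["skew_x"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_population_moments(self):
        # axis (0,0,0,1): population sd = sqrt(3)/4, skew = 2/sqrt(3), excess kurt = -2/3
        a = np.vstack([[0.0, 0.0, 0.0, 1.0] * 2, np.zeros(8), np.zeros(8)])
        x = a[0]
        m2 = np.mean((x - x.mean()) ** 2)
        m3 = np.mean((x - x.mean()) ** 3)
        m4 = np.mean((x - x.mean()) ** 4)
        f = _features(a)
        assert f["sd_x"] == pytest.approx(np.sqrt(3) / 4)
        assert f["skew_x"] == pytest.approx(m3 / m2**1.5) == pytest.approx(2 / np.sqrt(3))
        assert f["kurt_x"] == pytest.approx(m4 / m2**2 - 3) == pytest.approx(-2 / 3)


class TestZScoreHistogram:
    def test_counts_bounded_by_samples(self):
        a = RNG.normal(size=(3, 180))
        f = _features(a)
        for ax in "xyz":
            total = sum(f[f"zhist_{ax}_bin{i}"] for i in range(4))
            assert 0 <= total <= 180

    def test_standard_normal_bin_frequencies(self):
        # Monte-Carlo: average count in bin [-2, -1.25) over many windows
        rng = np.random.default_rng(77)
        counts = []
        for _ in range(300):
            f = _features(rng.normal(size=(3, 180)))
            counts.append(f["zhist_x_bin0"])
        expected = 180 * (norm.cdf(-1.25) - norm.cdf(-2.0))
        assert np.mean(counts) == pytest.approx(expected, rel=0.08)


class TestDerivativeMoments:
    def test_linear_ramp_has_constant_derivative(self):
        # step 0.25 is exactly representable, so the difference is bit-constant
        a = np.vstack([np.arange(180) * 0.25, np.zeros(180), np.zeros(180)])
        f = _features(a)
        assert f["diff_mean_x"] == pytest.approx(0.25)
        assert f["diff_sd_x"] == 0.0
        assert f["diff_skew_x"] == 0.0 and f["diff_kurt_x"] == 0.0

    def test_whole_period_sinusoid_derivative_mean_is_zero(self):
        # 181 samples at 30 Hz span exactly 6 s = 12 periods of a 2 Hz tone,
        # so the telescoping first-difference mean vanishes
        t = np.arange(181) / 30.0
        a = np.vstack([np.sin(2 * np.pi * 2.0 * t), np.zeros(181), np.zeros(181)])
        f = _features(a)
        assert abs(f["diff_mean_x"]) < 1e-6


class TestNormAndCrossProducts:
    def test_white_noise_squared_norm_expectation(self):
        sigma = 0.3
        rng = np.random.default_rng(88)
        vals = [
            _features(rng.normal(0, sigma, size=(3, 180)))["sq_norm_mean"] for _ in range(200)
        ]
        assert np.mean(vals) == pytest.approx(3 * sigma**2, rel=0.05)

    def test_anticorrelated_axes(self):
        x = RNG.normal(size=180)
        x -= x.mean()
        f = _features(np.vstack([x, -x, RNG.normal(size=180)]))
        assert f["pearson_r_xy"] == pytest.approx(-1.0)
        assert f["cp_norm_xy"] == pytest.approx(-1.0)
        assert f["abs_cp_norm_xy"] == pytest.approx(1.0)

    def test_independent_axes_have_small_raw_cross_product(self):
        rng = np.random.default_rng(99)
        vals = [_features(rng.normal(size=(3, 180)))["cp_raw_xy"] for _ in range(200)]
        assert abs(np.mean(vals)) < 0.02


class TestSpectral:
    def test_pure_tone_lands_in_its_band(self):
        t = np.arange(180) / 30.0
        tone = np.sin(2 * np.pi * 2.0 * t)
        f = _features(np.vstack([tone, np.zeros(180), np.zeros(180)]))
        band_powers = {n: f[n] for n in FEATURE_NAMES if n.startswith("band_x")}
        assert max(band_powers, key=band_powers.get) == "band_x_2.0_2.5"
        high = [v for n, v in band_powers.items() if float(n.split("_")[2]) >= 3.0]
        assert all(v < 1e-12 for v in high)

    def test_parseval_identity(self):
        x = RNG.normal(size=180)
        p = periodogram(x)
        assert p.sum() == pytest.approx(np.var(x), rel=1e-10)

    def test_odd_length_parseval(self):
        x = RNG.normal(size=181)
        assert periodogram(x).sum() == pytest.approx(np.var(x), rel=1e-10)


# families allowed to respond to adding a constant to one axis: means,
# histogram z-scores are shift-invariant so zhist must NOT change; cross
# products and the squared norm do change.
_SHIFT_SENSITIVE_PREFIXES = ("mean_", "sq_norm_mean", "cp_raw", "abs_cp_raw")


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_determinism_and_finiteness(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=rng.uniform(1e-6, 2.0), size=(3, 180))
        w = _window(a)
        v1, v2 = extract_features(w), extract_features(w)
        np.testing.assert_array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_translation_touches_only_shift_sensitive_features(self):
        a = RNG.normal(size=(3, 180))
        shifted = a.copy()
        shifted[1] += 5.0
        f0, f1 = _features(a), _features(shifted)
        for name in FEATURE_NAMES:
            if not name.startswith(_SHIFT_SENSITIVE_PREFIXES):
                assert f0[name] == pytest.approx(f1[name], abs=1e-9), name

    def test_scaling_acts_as_expected(self):
        a = RNG.normal(size=(3, 180))
        c = 2.5
        f0, f1 = _features(a), _features(c * a)
        for ax in "xyz":
            assert f1[f"sd_{ax}"] == pytest.approx(c * f0[f"sd_{ax}"])
        for name in FEATURE_NAMES:
            if name.startswith(("pearson_r", "cp_norm", "abs_cp_norm", "skew", "kurt")):
                assert f1[name] == pytest.approx(f0[name], abs=1e-9), name
            if name.startswith("band"):
                assert f1[name] == pytest.approx(c**2 * f0[name], rel=1e-9), name

    def test_batch_matches_per_window_reference(self):
        stack = RNG.normal(size=(16, 3, 180))
        stack[0] = 0.0  # include a degenerate window
        stack[1, 2] = 1.0
        batch = extract_features_batch(stack, 30.0)
        ref = np.vstack([extract_features(_window(a)) for a in stack])
        np.testing.assert_allclose(batch, ref, atol=1e-12)
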