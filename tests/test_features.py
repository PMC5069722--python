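"""Feature kernels: hand-computed examples, closed forms, parameter
recovery, scaling laws, and finiteness on generated data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emgsel.dataset import segment_windows
from emgsel.evaluation import EvalConfig, build_feature_matrix
from emgsel.features import (
    FEATURE_NAMES,
    amplitude_features,
    ar_features,
    extract_feature_matrix,
    named_feature_set,
    psd_descriptors,
    spectral_features,
    td_features,
)
from emgsel.synth import default_layout, generate_dataset, preset


class TestTimeDomain:
    def test_alternating_square(self):
        assert td_features([1, -1, 1, -1]) == (1.0, 3.0, 2.0, 6.0)

    def test_constant_signal(self):
        mav, zc, ssc, wl = td_features([3.5] * 10)
        assert (mav, zc, ssc, wl) == (3.5, 0.0, 0.0, 0.0)

    def test_sine_zero_crossings_match_brute_force(self):
        """ZC of a sampled 10 Hz sine equals a direct sign-product count."""
        t = np.arange(200) / 1000.0
        x = np.sin(2 * np.pi * 10 * t + 0.1)
        brute = sum(
            1 for i in range(len(x) - 1) if x[i] * x[i + 1] < 0
        )
        _, zc, _, _ = td_features(x)
        assert zc == brute == 4

    def test_threshold_suppresses_small_crossings(self):
        x = [0.001, -0.001, 0.001, -0.001]
        assert td_features(x, eps_zc=0.01)[1] == 0
        assert td_features(x, eps_zc=0.0)[1] == 3

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            td_features([1.0, 2.0])


class TestAmplitude:
    def test_constant_signal(self):
        wamp, rms, var, vord, _ = amplitude_features([2.0] * 8)
        assert (wamp, rms, var, vord) == (0.0, 2.0, 0.0, 2.0)

    def test_wamp_hand_count(self):
        assert amplitude_features([0, 1, 0, 1], eps_wamp=0.5)[0] == 3

    def test_sine_rms_closed_form(self):
        t = np.arange(100_000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t)
        rms = amplitude_features(x)[1]
        assert rms == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_vord_is_cubic_mean_root(self):
        x = np.array([1.0, -2.0, 3.0])
        expected = (np.mean(np.abs(x) ** 3)) ** (1 / 3)
        assert amplitude_features(x)[3] == pytest.approx(expected)


class TestAutoregressive:
    def test_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(0).standard_normal(20_000)
        assert np.all(np.abs(ar_features(x)) < 0.05)

    def test_ar2_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = np.zeros(n + 500)
        e = rng.standard_normal(n + 500)
        for t in range(2, n + 500):
            x[t] = 0.5 * x[t - 1] - 0.3 * x[t - 2] + e[t]
        a = ar_features(x[500:])
        assert a[0] == pytest.approx(0.5, abs=0.02)
        assert a[1] == pytest.approx(-0.3, abs=0.02)
        assert np.all(np.abs(a[2:]) < 0.02)

    def test_ar6_full_recovery(self):
        """All six coefficients of a known stable AR(6) within 0.05."""
        rng = np.random.default_rng(2)
        true = np.array([0.4, -0.3, 0.2, -0.15, 0.1, -0.05])
        n = 100_000
        x = np.zeros(n + 1000)
        e = rng.standard_normal(n + 1000)
        for t in range(6, n + 1000):
            x[t] = true @ x[t - 6 : t][::-1] + e[t]
        a = ar_features(x[1000:])
        assert np.all(np.abs(a - true) < 0.05)

    def test_matches_reference_burg(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal(200)
            ref, _ = sm_burg(x - x.mean(), order=6)
            assert np.allclose(ar_features(x), ref, atol=1e-12)

    def test_constant_input_falls_back_to_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            a = ar_features(np.full(50, 1.25))
        assert np.all(a == 0)

    def test_deterministic(self):
        x = np.random.default_rng(4).standard_normal(300)
        assert np.array_equal(ar_features(x), ar_features(x))


class TestSpectral:
    def test_pure_tone_frequencies(self):
        fs, n = 1000.0, 1024
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 100 * t)
        mnf, mdf, pf, _ = spectral_features(x, fs)
        bin_width = fs / 1024
        assert abs(pf - 100) <= bin_width
        assert abs(mnf - 100) <= bin_width
        assert abs(mdf - 100) <= bin_width

    def test_white_noise_mean_frequency(self):
        x = np.random.default_rng(5).standard_normal(8192)
        mnf = spectral_features(x, 1000.0)[0]
        assert mnf == pytest.approx(250.0, rel=0.1)

    def test_scaling_homogeneity(self):
        x = np.random.default_rng(6).standard_normal(512)
        base = spectral_features(x, 1000.0)
        doubled = spectral_features(2 * x, 1000.0)
        assert doubled[:3] == base[:3]  # MnF, MdF, PF scale-invariant
        assert doubled[3] == pytest.approx(4 * base[3])  # MP ~ power

    def test_zero_window_fallback(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert spectral_features(np.zeros(64), 1000.0) == (0, 0, 0, 0)


class TestPsdDescriptors:
    def test_six_bounded_entries(self):
        x = np.random.default_rng(7).standard_normal(200)
        d = psd_descriptors(x)
        assert d.shape == (6,)
        assert np.all(d >= -1) and np.all(d <= 1)

    def test_minus_one_iff_moment_logs_equal(self):
        # a record whose squared mapping has identical moment logs is
        # impossible in practice, but the bound -2ab/(a^2+b^2) >= -1 with
        # equality iff a == b != 0 holds algebraically
        a = np.array([0.5, -1.0, 2.0])
        val = -2 * a * a / (a**2 + a**2)
        assert np.allclose(val, -1.0)

    def test_stable_under_scaling_grid(self):
        x = np.random.default_rng(8).standard_normal(200)
        vals = np.array([psd_descriptors(s * x) for s in np.logspace(-2, 2, 9)])
        assert np.all(vals >= -1) and np.all(vals <= 1)
        # descriptors vary continuously: adjacent scales stay close
        assert np.max(np.abs(np.diff(vals, axis=0))) < 0.8

    @settings(max_examples=100, deadline=None)
    @given(
        arrays(
            float,
            st.integers(3, 64),
            elements=st.floats(-1e4, 1e4, allow_nan=False),
        )
    )
    def test_bounded_for_arbitrary_input(self, x):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = psd_descriptors(x)
        assert np.all(np.isfinite(d))
        assert np.all(d >= -1.0) and np.all(d <= 1.0)


class TestExtraction:
    def test_full_catalog_column_count(self):
        layout = default_layout(9, 4)
        cfg = preset("intact-like", layout=layout, repetitions=1, seed=9)
        from emgsel.synth import synth_trial

        windows = segment_windows(
            synth_trial(cfg, "open", "neutral", 1), 200, 500
        )
        fm = extract_feature_matrix(windows)
        assert fm.n_columns == 13 * 25
        fm_tdar = extract_feature_matrix(windows, named_feature_set("TDAR"))
        assert fm_tdar.n_columns == 13 * 10

    def test_row_order_follows_window_order(self, intact_trials):
        windows = segment_windows(intact_trials[0], 200, 400)
        fm = extract_feature_matrix(windows)
        fm_rev = extract_feature_matrix(
            windows[::-1], thresholds=fm.thresholds
        )
        assert np.allclose(fm.values, fm_rev.values[::-1])

    def test_all_features_finite_on_synthetic_presets(self):
        """Fuzz: every feature finite on >= 10^4 windows from both presets."""
        total = 0
        for name, seed in (("intact-like", 10), ("amputee-like", 11)):
            layout = default_layout(2, 1)
            trials = generate_dataset(
                preset(name, layout=layout, repetitions=2, seed=seed),
                verify=False,
            )
            fm = build_feature_matrix(
                trials, "combined", "ALL", EvalConfig(increment_ms=20.0)
            )
            assert np.all(np.isfinite(fm.values))
            total += fm.n_rows
        assert total >= 10_000

    def test_scaling_laws_across_catalog(self, intact_trials):
        """Homogeneity degrees under x -> 2x for every feature family."""
        windows = segment_windows(intact_trials[0], 200, 400)
        scaled = [
            type(w)(
                data=2 * w.data,
                subject_id=w.subject_id,
                motion_class=w.motion_class,
                wrist_position=w.wrist_position,
                repetition=w.repetition,
                start_offset=w.start_offset,
                layout=w.layout,
            )
            for w in windows
        ]
        zero_eps = {ch: 0.0 for ch in windows[0].layout.channel_ids}
        fm = extract_feature_matrix(windows, thresholds=zero_eps)
        fm2 = extract_feature_matrix(scaled, thresholds=zero_eps)
        degree = {
            "MAV": 1, "WL": 1, "RMS": 1, "Vord": 1, "VAR": 2, "MP": 2,
            "ZC": 0, "SSC": 0, "WAMP": 0, "MnF": 0, "MdF": 0, "PF": 0,
        }
        for j, (_, feat) in enumerate(fm.columns):
            if feat not in degree:
                continue
            expect = fm.values[:, j] * 2.0 ** degree[feat]
            assert np.allclose(fm2.values[:, j], expect, rtol=1e-9), feat

    def test_catalog_has_25_names(self):
        assert len(FEATURE_NAMES) == 25
        assert len(named_feature_set("TD")) == 4
        assert len(named_feature_set("TDAR")) == 10
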