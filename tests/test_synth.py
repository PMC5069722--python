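"""Synthetic EMG generator: spectral shaping, protocol structure, and the
statistical structure the downstream analysis relies on."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import binomtest

from emgsel.classifiers import classification_error
from emgsel.dataset import MOTION_CLASSES, WRIST_POSITIONS
from emgsel.evaluation import EvalConfig, build_feature_matrix, evaluate_feature_matrix
from emgsel.synth import (
    SynthConfig,
    _class_gain_matrix,
    default_layout,
    generate_dataset,
    make_bandlimited_noise,
    preset,
    synth_trial,
)


class TestBandlimitedNoise:
    def test_in_band_power_dominates(self):
        x = make_bandlimited_noise(8192, rng=np.random.default_rng(1))
        f, P = sps.periodogram(x, fs=1000)
        in_band = (f >= 30) & (f <= 350)
        assert P[in_band].sum() / P[~in_band].sum() >= 100

    def test_unit_rms_and_zero_mean(self):
        x = make_bandlimited_noise(65536, rng=np.random.default_rng(2))
        assert abs(np.sqrt(np.mean(x**2)) - 1.0) < 0.05
        assert abs(np.mean(x)) < 0.02

    def test_spectrum_flat_in_band(self):
        """No unintended spectral structure: in-band PSD within +-6 dB."""
        x = make_bandlimited_noise(65536, rng=np.random.default_rng(3))
        f, W = sps.welch(x, fs=1000, nperseg=2048)
        band = (f >= 40) & (f <= 340)
        db = 10 * np.log10(W[band] / np.median(W[band]))
        assert db.max() < 6 and db.min() > -6

    def test_deterministic_under_seed(self):
        a = make_bandlimited_noise(512, rng=np.random.default_rng(7))
        b = make_bandlimited_noise(512, rng=np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_empty_and_invalid_band(self):
        assert make_bandlimited_noise(0).size == 0
        with pytest.raises(ValueError, match="band"):
            make_bandlimited_noise(100, fs=1000, band=(30, 600))


class TestSynthTrial:
    def test_rest_rms_is_floor_and_position_independent(self, tiny_layout):
        cfg = preset("intact-like", layout=tiny_layout, repetitions=3, seed=4)
        rms_by_pos = {}
        for pos in WRIST_POSITIONS:
            vals = [
                np.sqrt(np.mean(synth_trial(cfg, "rest", pos, r).signal ** 2))
                for r in range(1, 4)
            ]
            rms_by_pos[pos] = np.mean(vals)
        for pos, rms in rms_by_pos.items():
            assert rms == pytest.approx(cfg.noise_floor, rel=0.05), pos

    def test_zero_gain_zero_floor_gives_silence(self, tiny_layout):
        cfg = SynthConfig(
            layout=tiny_layout,
            activation_gain=np.zeros((4, 3)),
            noise_floor=0.0,
            seed=0,
        )
        t = synth_trial(cfg, "open", "neutral", 1)
        assert np.all(t.signal == 0)

    def test_deterministic_per_trial(self, tiny_layout):
        cfg = preset("amputee-like", layout=tiny_layout, seed=9)
        a = synth_trial(cfg, "chuck", "flexion", 2)
        b = synth_trial(cfg, "chuck", "flexion", 2)
        assert np.array_equal(a.signal, b.signal)

    def test_unknown_labels_rejected(self, tiny_layout):
        cfg = preset("intact-like", layout=tiny_layout)
        with pytest.raises(ValueError):
            synth_trial(cfg, "pinch", "neutral", 1)
        with pytest.raises(ValueError):
            synth_trial(cfg, "open", "sideways", 1)


class TestSpectralTilt:
    def test_configured_tilt_shifts_class_spectra(self, tiny_layout):
        """With per-class tilt exponents, mean frequency orders with the
        tilt while channel RMS (the amplitude code) is preserved."""
        from emgsel.features import spectral_features

        cfg = preset(
            "intact-like",
            layout=tiny_layout,
            seed=21,
            spectral_tilt=np.array([0.0, 0.5, -0.5, 0.0]),
        )
        flat = preset("intact-like", layout=tiny_layout, seed=21)
        mnf = {}
        for mc in ("open", "key", "chuck"):
            t = synth_trial(cfg, mc, "neutral", 1)
            mnf[mc] = spectral_features(t.signal[0], 1000.0)[0]
            t_flat = synth_trial(flat, mc, "neutral", 1)
            rms, rms_flat = (
                np.sqrt(np.mean(t.signal[0] ** 2)),
                np.sqrt(np.mean(t_flat.signal[0] ** 2)),
            )
            assert rms == pytest.approx(rms_flat, rel=0.05)
        assert mnf["key"] < mnf["chuck"] < mnf["open"]

    def test_default_presets_have_no_spectral_class_cue(self, tiny_layout):
        cfg = preset("amputee-like", layout=tiny_layout)
        assert cfg.spectral_tilt is None


class TestGenerateDataset:
    def test_protocol_counts(self, tiny_layout):
        cfg = preset("intact-like", layout=tiny_layout, repetitions=4, seed=1)
        trials = generate_dataset(cfg)
        assert len(trials) == 4 * 7 * 4  # classes x positions x repetitions
        combos = {(t.motion_class, t.wrist_position, t.repetition) for t in trials}
        assert len(combos) == len(trials)

    def test_default_repetitions_yield_280(self):
        cfg = preset("intact-like", layout=default_layout(1, 1), repetitions=10, seed=2)
        assert len(generate_dataset(cfg, verify=False)) == 280

    def test_order_independent_determinism(self, tiny_layout):
        cfg = preset("amputee-like", layout=tiny_layout, repetitions=2, seed=3)
        t1 = generate_dataset(cfg, verify=False)
        t2 = generate_dataset(cfg, verify=False)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.signal, b.signal)

    def test_zero_spread_makes_extrinsic_rms_position_invariant(self, tiny_layout):
        cfg = preset(
            "intact-like",
            layout=tiny_layout,
            repetitions=3,
            seed=5,
            extrinsic_position_spread=0.0,
            intrinsic_position_spread=0.0,
            repetition_jitter=0.0,
        )
        trials = generate_dataset(cfg)
        rms = {}
        for t in trials:
            if t.motion_class == "open":
                rms.setdefault(t.wrist_position, []).append(
                    np.sqrt(np.mean(t.signal[0] ** 2))
                )
        means = [np.mean(v) for v in rms.values()]
        assert max(means) / min(means) < 1.05


class TestLearnability:
    def test_separable_config_is_learnable_by_lda(self, tiny_layout):
        """Well-separated gains, no position effect: TD features + LDA < 2%."""
        cfg = preset(
            "intact-like",
            layout=tiny_layout,
            repetitions=2,
            seed=6,
            activation_gain=_class_gain_matrix(3, class_sep=0.8),
            extrinsic_position_spread=0.0,
            intrinsic_position_spread=0.0,
        )
        trials = generate_dataset(cfg)
        ec = EvalConfig(seed=6, increment_ms=100.0)
        fm = build_feature_matrix(trials, "combined", "TD", ec)
        rep = evaluate_feature_matrix(fm, "LDA", ec)
        assert rep.error < 0.02

    def test_position_spread_degrades_single_position_training(self):
        """More extrinsic position spread -> worse neutral-trained /
        all-position-tested performance (sign test over 10 seeds)."""
        layout = default_layout(3, 0)
        wins = 0
        n_valid = 0
        for seed in range(10):
            errs = []
            for spread in (0.05, 0.9):
                cfg = preset(
                    "amputee-like",
                    layout=layout,
                    repetitions=2,
                    seed=seed,
                    extrinsic_position_spread=spread,
                    intrinsic_position_spread=0.0,
                )
                trials = generate_dataset(cfg, verify=False)
                ec = EvalConfig(seed=seed, increment_ms=200.0)
                fm = build_feature_matrix(trials, "extrinsic", "TD", ec)
                rep = evaluate_feature_matrix(
                    fm, "LDA", ec, train_position_subset=("neutral",)
                )
                errs.append(rep.error)
            if errs[1] != errs[0]:
                n_valid += 1
                wins += errs[1] > errs[0]
        assert binomtest(wins, n_valid, 0.5).pvalue < 0.05
        assert wins > n_valid / 2
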