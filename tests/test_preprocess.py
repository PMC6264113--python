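"""Filtering and spatial-projection contracts: zero phase, frequency response,
decimation fidelity and the SNR-optimal zero-sum weights."""

import numpy as np
import pytest
from scipy import signal

from mrcploop.errors import (
    InsufficientDataError, InvalidArgumentError, InvalidConfigError, MissingChannelError,
)
from mrcploop.preprocess import (
    FilterSpec, SpatialFilter, apply_spatial_filter, bandpass_zero_phase,
    downsample, large_laplacian, optimize_spatial_weights, spatial_filter_objective,
)
from mrcploop.synthetic import generate_background_eeg, inject_mrcp
from mrcploop.types import EEG_CHANNELS, EEGRecording, SyntheticConfig


def _rec(data, rate=2048.0):
    return EEGRecording(data=np.atleast_2d(data), rate=rate,
                        channels=EEG_CHANNELS[: np.atleast_2d(data).shape[0]])


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = _rec(np.zeros((10, 4096)))
        out = bandpass_zero_phase(rec)
        assert np.all(out.data == 0) and out.rate == rec.rate
        assert out.n_samples == rec.n_samples

    def test_impulse_response_symmetric(self):
        # Forward-backward filtering has zero phase: the response to a
        # mid-record impulse is symmetric about the impulse sample.
        n = 2 ** 15
        x = np.zeros(n)
        x[n // 2] = 1.0
        out = bandpass_zero_phase(_rec(x)).data[0]
        m, K = n // 2, n // 2 - 1
        left = out[m - K: m][::-1]
        right = out[m + 1: m + K + 1]
        np.testing.assert_allclose(left, right, atol=1e-6)

    def test_sinusoid_gains_match_designed_response(self):
        # RMS ratio of filtered 1 Hz vs 50 Hz tones must match the designed
        # squared-magnitude response within 5%.
        spec = FilterSpec()
        rate = 2048.0
        t = np.arange(int(120 * rate)) / rate
        sos = spec.sos(rate)
        keep = slice(int(40 * rate), int(80 * rate))  # let edge transients decay
        gains = {}
        for f in (1.0, 50.0):
            out = bandpass_zero_phase(_rec(np.sin(2 * np.pi * f * t)), spec).data[0]
            gains[f] = np.sqrt(np.mean(out[keep] ** 2)) / np.sqrt(0.5)
        _, h1 = signal.sosfreqz(sos, worN=[2 * np.pi * 1.0 / rate])
        _, h50 = signal.sosfreqz(sos, worN=[2 * np.pi * 50.0 / rate])
        # forward-backward filtering applies |H|^2
        assert gains[1.0] / gains[50.0] == pytest.approx(
            (np.abs(h1[0]) / np.abs(h50[0])) ** 2, rel=0.05)

    def test_high_corner_at_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            bandpass_zero_phase(_rec(np.zeros(1000), rate=16.0), FilterSpec(high=10.0))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 8192))
        fa = bandpass_zero_phase(_rec(2.0 * x - 3.0 * y)).data[0]
        fb = 2.0 * bandpass_zero_phase(_rec(x)).data[0] \
            - 3.0 * bandpass_zero_phase(_rec(y)).data[0]
        np.testing.assert_allclose(fa, fb, atol=1e-9)

    def test_zero_phase_cross_correlation_peaks_at_zero_lag(self):
        cfg = SyntheticConfig(duration=20.0, seed=21)
        rec = generate_background_eeg(cfg)
        out = bandpass_zero_phase(rec)
        x = rec.channel("Cz") - rec.channel("Cz").mean()
        y = out.channel("Cz") - out.channel("Cz").mean()
        lags = np.arange(-64, 65)
        cc = [np.dot(x[64: -64], y[64 + k: y.size - 64 + k]) for k in lags]
        assert lags[int(np.argmax(cc))] == 0


class TestDownsample:
    def test_constant_preserved_and_length_contract(self):
        rec = _rec(np.full((1, int(60 * 2048)), 3.14))
        out = downsample(rec, 32.0)
        assert out.rate == 32.0
        assert out.n_samples == 60 * 32
        assert np.all(out.data == 3.14)

    def test_sinusoid_matches_analytic_resampling(self):
        rate = 2048.0
        t = np.arange(int(10 * rate)) / rate
        out = downsample(_rec(np.sin(2 * np.pi * 5.0 * t)), 32.0).data[0]
        t32 = np.arange(out.size) / 32.0
        ref = np.sin(2 * np.pi * 5.0 * t32)
        assert np.corrcoef(out, ref)[0, 1] > 0.999

    def test_invalid_targets_rejected(self):
        rec = _rec(np.zeros(1000))
        with pytest.raises(InvalidArgumentError):
            downsample(rec, 4096.0)
        with pytest.raises(InvalidArgumentError):
            downsample(rec, 1000.0)  # 2048/1000 is not an integer

    def test_down_up_roundtrip_on_bandlimited_signal(self):
        # Decimate then polyphase-upsample: identity within 1% RMS for
        # content far below the decimated Nyquist.
        rate = 2048.0
        t = np.arange(int(20 * rate)) / rate
        x = np.sin(2 * np.pi * 2.0 * t) + 0.5 * np.sin(2 * np.pi * 5.0 * t + 1.0)
        down = downsample(_rec(x), 32.0).data[0]
        up = signal.resample_poly(down, 64, 1)
        core = slice(int(2 * rate), int(18 * rate))
        err = np.sqrt(np.mean((up[core] - x[core]) ** 2)) / np.sqrt(np.mean(x[core] ** 2))
        assert err < 0.01


class TestSpatialFilter:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidConfigError):
            SpatialFilter(weights={"Cz": 1.0, "C3": -0.5}, center="Cz")  # not zero-sum
        with pytest.raises(InvalidConfigError):
            SpatialFilter(weights={"Cz": 1.0, "FP1": -1.0}, center="Cz")  # FP1 mixed in
        with pytest.raises(InvalidConfigError):
            SpatialFilter(weights={"Cz": 0.2, "C3": 1.0, "C4": -1.2}, center="Cz")

    def test_common_waveform_cancels(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=4096)
        data = np.tile(w, (10, 1))
        out = apply_spatial_filter(_rec(data), large_laplacian())
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_center_only_signal_passes_unchanged(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=4096)
        data = np.zeros((10, 4096))
        data[EEG_CHANNELS.index("Cz")] = w
        out = apply_spatial_filter(_rec(data), large_laplacian())
        np.testing.assert_allclose(out, w, atol=1e-12)

    def test_missing_channel_rejected(self):
        rec = EEGRecording(data=np.zeros((2, 100)), channels=("F3", "F4"))
        with pytest.raises(MissingChannelError):
            apply_spatial_filter(rec, large_laplacian())


def _mrcp_epochs(seed, n_epochs=40):
    """Onset-locked 32 Hz epoch stacks from a default synthetic session."""
    from mrcploop.preprocess import bandpass_zero_phase as bp
    cfg = SyntheticConfig(duration=n_epochs * 11.0 + 20.0, seed=seed)
    onsets = 10.0 + np.arange(n_epochs) * 11.0
    eeg = inject_mrcp(generate_background_eeg(cfg), onsets, cfg)
    low = downsample(bp(eeg), 32.0)
    stacks = [low.data[:, int(t * 32) - 64: int(t * 32)] for t in onsets]
    return np.asarray(stacks), low.channels


class TestOptimizeWeights:
    def test_too_few_epochs_rejected(self):
        with pytest.raises(InsufficientDataError):
            optimize_spatial_weights(np.zeros((1, 10, 64)), EEG_CHANNELS)

    def test_white_noise_returns_laplacian_fallback(self):
        rng = np.random.default_rng(3)
        epochs = rng.normal(size=(30, 10, 64))
        filt = optimize_spatial_weights(epochs, EEG_CHANNELS)
        assert filt.weights == large_laplacian().weights

    def test_optimized_beats_fallback_objective(self):
        epochs, channels = _mrcp_epochs(seed=17)
        filt = optimize_spatial_weights(epochs, channels)
        obj_opt = spatial_filter_objective(epochs, filt, channels)
        obj_lap = spatial_filter_objective(epochs, large_laplacian(), channels)
        assert obj_opt >= obj_lap

    def test_surrogate_snr_beats_cz_alone(self):
        # The whole point of spatial filtering: correlated background noise is
        # cancelled, so the filtered surrogate beats the raw centre channel.
        epochs, channels = _mrcp_epochs(seed=19)
        filt = optimize_spatial_weights(epochs, channels)
        obj_opt = spatial_filter_objective(epochs, filt, channels)
        cz_only = SpatialFilter.__new__(SpatialFilter)  # bypass zero-sum check
        object.__setattr__(cz_only, "weights", {"Cz": 1.0})
        object.__setattr__(cz_only, "center", "Cz")
        obj_cz = spatial_filter_objective(epochs, cz_only, channels)
        assert obj_opt >= obj_cz

    def test_signal_only_on_center_prefers_laplacian_like_solution(self):
        # With signal confined to Cz and independent noise elsewhere the
        # optimizer cannot beat spreading the negative weights; its objective
        # must be at least the Laplacian's.
        rng = np.random.default_rng(4)
        kernel = -np.hanning(64)
        epochs = 0.3 * rng.normal(size=(40, 10, 64))
        epochs[:, EEG_CHANNELS.index("Cz"), :] += kernel
        filt = optimize_spatial_weights(epochs, EEG_CHANNELS)
        obj = spatial_filter_objective(epochs, filt, EEG_CHANNELS)
        obj_lap = spatial_filter_objective(epochs, large_laplacian(), EEG_CHANNELS)
        assert obj >= obj_lap
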