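"""Detector core: template extraction, matched filtering vs a brute-force
oracle, ROC calibration on a hand-enumerated fixture, threshold policy and the
online lockout/artifact-gate semantics."""

import numpy as np
import pytest

from mrcploop import synthetic
from mrcploop.detector import (
    DetectorConfig, MRCPTemplate, ROCCurve, compute_roc, extract_template,
    match_events, match_template, run_online_detection, select_threshold,
)
from mrcploop.errors import InsufficientDataError, InvalidArgumentError
from mrcploop.types import SyntheticConfig
from tests.conftest import make_session

RATE = 32.0


def brute_force_similarity(x, template):
    """Per-window Pearson correlation loop — the independent oracle."""
    t = template - template.mean()
    L = t.size
    out = np.zeros(x.size)
    for i in range(L - 1, x.size):
        w = x[i - L + 1: i + 1]
        wc = w - w.mean()
        den = np.sqrt(np.sum(wc ** 2) * np.sum(t ** 2))
        out[i] = np.dot(wc, t) / den if den > 1e-12 * np.sqrt(np.sum(t ** 2)) else 0.0
    return out


class TestTemplate:
    def test_single_epoch_is_identity_mean_subtracted(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=320)
        tmpl = extract_template(x, RATE, [5.0], window=(-2.0, 0.0))
        epoch = x[int(3.0 * RATE): int(5.0 * RATE)]
        np.testing.assert_allclose(tmpl.samples, epoch - epoch.mean(), atol=1e-12)
        assert tmpl.n_train == 1

    def test_identical_epochs_average_to_common_epoch(self):
        kernel = -np.hanning(64)
        x = np.zeros(int(RATE * 300))
        onsets = 10.0 + np.arange(20) * 11.0
        for t in onsets:
            c = int(t * RATE)
            x[c - 64: c] = kernel
        tmpl = extract_template(x, RATE, onsets)
        np.testing.assert_allclose(tmpl.samples, kernel - kernel.mean(), atol=1e-12)

    def test_no_complete_epoch_rejected(self):
        with pytest.raises(InsufficientDataError):
            extract_template(np.zeros(32), RATE, [0.5])

    def test_template_error_shrinks_like_sqrt_n(self):
        # Epoch-average noise scales as sigma/sqrt(n): compare n=10 vs n=90.
        kernel = -np.hanning(64)
        k0 = kernel - kernel.mean()
        rng = np.random.default_rng(7)

        def err(n):
            epochs = kernel + rng.normal(0, 1.0, size=(n, 64))
            m = epochs.mean(axis=0)
            return np.linalg.norm((m - m.mean()) - k0)

        r = np.mean([err(10) / err(90) for _ in range(40)])
        assert r == pytest.approx(3.0, rel=0.35)

    def test_template_window_must_end_at_or_before_onset(self):
        with pytest.raises(InvalidArgumentError):
            MRCPTemplate(samples=np.zeros(8), window=(-1.0, 0.5))


class TestMatchTemplate:
    def test_self_match_is_one_at_final_sample(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=64)
        tmpl = MRCPTemplate(samples=t - t.mean())
        sim = match_template(t, tmpl)
        assert sim[-1] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_signal_scores_zero(self):
        n = 64
        tmpl_wave = np.sin(2 * np.pi * 4 * np.arange(n) / n)
        quad = np.cos(2 * np.pi * 4 * np.arange(n) / n)  # Hilbert quadrature
        tmpl = MRCPTemplate(samples=tmpl_wave - tmpl_wave.mean())
        sim = match_template(quad, tmpl)
        assert abs(sim[-1]) < 1e-8

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        tmpl_wave = rng.normal(size=64)
        tmpl = MRCPTemplate(samples=tmpl_wave - tmpl_wave.mean())
        x = rng.normal(size=int(30 * RATE))
        np.testing.assert_allclose(match_template(x, tmpl),
                                   brute_force_similarity(x, tmpl.samples),
                                   atol=1e-10)

    def test_zero_variance_window_scores_zero(self):
        tmpl = MRCPTemplate(samples=np.hanning(16) - np.hanning(16).mean())
        x = np.concatenate([np.full(40, 2.5), np.random.default_rng(3).normal(size=40)])
        sim = match_template(x, tmpl)
        assert sim[20] == 0.0

    def test_signal_shorter_than_template_rejected(self):
        tmpl = MRCPTemplate(samples=np.arange(64.0) - 31.5)
        with pytest.raises(InvalidArgumentError):
            match_template(np.zeros(10), tmpl)


def toy_similarity_trace():
    """Flat trace with five isolated triangular peaks of known heights.

    Signal peaks at 10/20/30 s (heights .9/.7/.5) sit on true onsets; noise
    peaks at 40/50 s (heights .6/.3) do not. All peaks are > lockout apart.
    """
    n = int(60 * RATE)
    sim = np.zeros(n)
    bump = np.concatenate([np.linspace(0, 1, 16), np.linspace(1, 0, 16)[1:]])
    for t, h in [(10, 0.9), (20, 0.7), (30, 0.5), (40, 0.6), (50, 0.3)]:
        c = int(t * RATE)
        sim[c - 15: c + 16] = h * bump
    return sim, [10.0, 20.0, 30.0]


class TestROC:
    #: threshold -> (tpr, fp/10min) enumerated by hand from the toy fixture.
    TOY_EXPECTED = {
        0.20: (3 / 3, 20.0),
        0.40: (3 / 3, 10.0),
        0.55: (2 / 3, 10.0),
        0.65: (2 / 3, 0.0),
        0.80: (1 / 3, 0.0),
    }

    def test_toy_fixture_reproduced_exactly(self):
        sim, onsets = toy_similarity_trace()
        cfg = DetectorConfig(threshold=0.5)
        roc = compute_roc(sim, RATE, onsets, cfg, sorted(self.TOY_EXPECTED))
        for th, tpr, fp10 in zip(roc.thresholds, roc.tpr, roc.fp_per_10min):
            exp_tpr, exp_fp = self.TOY_EXPECTED[round(float(th), 2)]
            assert tpr == pytest.approx(exp_tpr, abs=1e-12)
            assert fp10 == pytest.approx(exp_fp, abs=1e-12)

    def test_limiting_thresholds(self):
        sim, onsets = toy_similarity_trace()
        cfg = DetectorConfig(threshold=0.5)
        roc = compute_roc(sim, RATE, onsets, cfg, [-1.0, 2.0])
        assert roc.tpr[0] == 1.0
        assert roc.tpr[-1] == 0.0 and roc.fp_per_10min[-1] == 0.0

    def test_empty_threshold_vector_rejected(self):
        sim, onsets = toy_similarity_trace()
        with pytest.raises(InvalidArgumentError):
            compute_roc(sim, RATE, onsets, DetectorConfig(threshold=0.5), [])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_in_threshold_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(size=int(120 * RATE)))  # smooth random walk
        x = (x - x.mean()) / x.std()
        tmpl = MRCPTemplate(samples=-np.hanning(64) + np.hanning(64).mean())
        sim = match_template(x, tmpl)
        onsets = rng.uniform(10, 110, size=8)
        roc = compute_roc(sim, RATE, np.sort(onsets), DetectorConfig(threshold=0.5),
                          np.linspace(-1, 1, 201))
        assert np.all(np.diff(roc.tpr) <= 1e-12)
        assert np.all(np.diff(roc.fp_per_10min) <= 1e-12)


class TestSelectThreshold:
    def test_toy_constrained_maximizer(self):
        sim, onsets = toy_similarity_trace()
        roc = compute_roc(sim, RATE, onsets, DetectorConfig(threshold=0.5),
                          sorted(TestROC.TOY_EXPECTED))
        # Hand enumeration: TPR 1 is attainable at threshold .40 with
        # fp/10min = 10 <= ceiling; .20 is infeasible (20 > 10).
        assert select_threshold(roc, min_fp10=10.0) == pytest.approx(0.40)
        # Tighter ceiling: only the fp=0 thresholds are feasible; max TPR
        # there is 2/3, attained first at .65.
        assert select_threshold(roc, min_fp10=5.0) == pytest.approx(0.65)

    def test_perfectly_separable_gap(self):
        roc = ROCCurve(thresholds=[0.1, 0.5, 0.9],
                       tpr=[1.0, 1.0, 0.0], fp_per_10min=[30.0, 0.0, 0.0])
        assert select_threshold(roc, min_fp10=10.0) == pytest.approx(0.5)

    def test_infeasible_falls_back_to_distance_rule(self):
        roc = ROCCurve(thresholds=[0.1, 0.5, 0.9],
                       tpr=[1.0, 0.6, 0.1], fp_per_10min=[80.0, 20.0, 15.0])
        d = np.hypot(1 - roc.tpr, roc.fp_per_10min / 10.0)
        assert select_threshold(roc, min_fp10=10.0) == roc.thresholds[np.argmin(d)]


class TestMatchEvents:
    def test_one_to_one_within_tolerance(self):
        det = [1.0, 5.0, 5.4, 9.0]
        ons = [5.2, 9.5, 20.0]
        md, mo = match_events(det, ons, tolerance=1.0)
        assert len(md) == len(mo) == 2
        assert mo == [0, 1]

    def test_superset_of_detections_never_shrinks_matching(self):
        rng = np.random.default_rng(5)
        ons = np.sort(rng.uniform(0, 100, 12))
        det = np.sort(rng.uniform(0, 100, 30))
        full, _ = match_events(det, ons, 1.0)
        sub, _ = match_events(det[::2], ons, 1.0)
        assert len(full) >= len(sub)


class TestOnlineDetection:
    def test_lockout_suppresses_second_event(self):
        # Two supra-threshold MRCPs 3 s apart -> exactly one detection.
        cfg = SyntheticConfig(duration=30.0, noise_rms=0.0, seed=0)
        onsets = [10.0, 13.0]
        eeg = synthetic.inject_mrcp(synthetic.generate_background_eeg(cfg), onsets, cfg)
        kernel, _ = synthetic.mrcp_waveform(cfg, rate=RATE)
        tmpl = extract_template(
            np.concatenate([np.zeros(int(8 * RATE)), kernel[: int(2 * RATE)]]),
            RATE, [10.0])
        from mrcploop.preprocess import FilterSpec, large_laplacian
        log = run_online_detection(eeg, tmpl, large_laplacian(), FilterSpec(),
                                   DetectorConfig(threshold=0.8), onsets)
        # The first event fires; the second falls inside the 5 s lockout and
        # cannot produce a detection (it is logged as a miss instead).
        assert [lab for _, lab in log.detections].count("TP") == 1
        assert log.misses == [13.0]
        times = [t for t, _ in log.detections]
        assert all(b - a >= 5.0 for a, b in zip(times, times[1:]))

    def test_blink_gate_suppresses_coincident_detection(self, calibration):
        cfg = SyntheticConfig(duration=40.0, noise_rms=0.0, seed=0)
        onsets = [20.0]
        eeg = synthetic.inject_mrcp(synthetic.generate_background_eeg(cfg), onsets, cfg)
        clean_log = run_online_detection(
            eeg, calibration.template, calibration.spatial,
            calibration.filter_spec, calibration.config, onsets)
        assert clean_log.tp == 1  # detector does fire without the blink
        # A blink train covering the whole detection window: the gate must
        # suppress the event entirely.
        blinked = synthetic.inject_blinks(eeg, [18.8, 19.4, 20.0, 20.6], cfg)
        log = run_online_detection(
            blinked, calibration.template, calibration.spatial,
            calibration.filter_spec, calibration.config, onsets)
        assert log.tp == 0
        assert log.misses == [20.0]
        fp1 = np.abs(blinked.channel("FP1"))
        exceed = np.flatnonzero(fp1 > calibration.config.artifact_limit) / blinked.rate
        for t, _ in log.detections:
            assert not np.any((exceed <= t)
                              & (t <= exceed + calibration.config.artifact_guard))

    def test_end_to_end_accounting_matches_oracle_replay(self, calibration):
        _, eeg, _, onsets = make_session(seed=61, n_events=40)
        log = run_online_detection(eeg, calibration.template, calibration.spatial,
                                   calibration.filter_spec, calibration.config,
                                   onsets)
        assert log.tp + log.fn == len(onsets)
        # Oracle replay: greedily re-match the detection times to onsets.
        det_times = [t for t, _ in log.detections]
        used = set()
        labels = []
        for t in det_times:
            cand = [i for i, o in enumerate(onsets)
                    if abs(t - o) <= calibration.config.tp_tolerance and i not in used]
            if cand:
                used.add(cand[0])
                labels.append("TP")
            else:
                labels.append("FP")
        assert [lab for _, lab in log.detections] == labels
        # Lockout invariant on the detection stream.
        gaps = np.diff(det_times)
        assert np.all(gaps >= calibration.config.lockout - 1e-9)

    def test_no_detection_during_artifact_guard(self, calibration):
        blinks = np.arange(15.0, 430.0, 23.0)
        _, eeg, _, onsets = make_session(seed=67, n_events=40, blink_times=blinks)
        log = run_online_detection(eeg, calibration.template, calibration.spatial,
                                   calibration.filter_spec, calibration.config,
                                   onsets)
        fp1 = np.abs(eeg.channel("FP1"))
        limit = calibration.config.artifact_limit
        guard = calibration.config.artifact_guard
        exceed = np.flatnonzero(fp1 > limit) / eeg.rate
        for t, _ in log.detections:
            assert not np.any((exceed <= t) & (t <= exceed + guard))
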