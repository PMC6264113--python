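"""Synthetic study data: background EEG, planted MRCPs, blinks, EMG bursts and MEP trials.

The generators are pure functions of ``(config, seed)``: the same inputs give
bit-identical output. Background EEG is Gaussian 1/f^alpha noise with a
common-mode component shared across channels (a crude stand-in for volume
conduction — real scalp noise is strongly spatially correlated, which is what
makes zero-sum spatial filtering pay off). The planted movement-related
cortical potential is a smooth negative half-cosine ramp that reaches its most
negative value at the movement onset, strongest over Cz.

MEP trial tables are drawn from the same generative model the analysis fits:
log mean = baseline + session-by-time effect + subject-by-session random
intercept, with Gamma-distributed single-trial amplitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, OutOfRangeError
from .types import (
    EEG_CHANNELS, SESSIONS, TIMES,
    EEGRecording, EMGRecording, GroundTruth, SyntheticConfig,
)

__all__ = [
    "generate_background_eeg", "mrcp_waveform", "inject_mrcp", "inject_blinks",
    "generate_emg", "generate_mep_trials", "COVARIATE_RANGES", "COVARIATE_CENTERS",
]

#: Simulated BCI performance covariates are drawn uniformly from the observed
#: study envelopes (TPR %, false positives/min, task time min, repetitions).
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "tpr": (58.82, 96.15),
    "fp_m": (0.22, 4.62),
    "t_t": (7.0, 23.0),
    "m_r": (52.0, 85.0),
}

#: Fixed centering constants (range midpoints) used when planting covariate
#: slopes, so the implied regression truth does not depend on the sample.
COVARIATE_CENTERS: dict[str, float] = {
    k: 0.5 * (lo + hi) for k, (lo, hi) in COVARIATE_RANGES.items()
}


def _one_over_f(n: int, rate: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectral density ~ f^-exponent."""
    white = rng.standard_normal(n)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / rate)
        gain = np.zeros_like(f)
        gain[1:] = f[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * gain, n=n)
    s = x.std()
    return x / s if s > 0 else x


def generate_background_eeg(config: SyntheticConfig) -> EEGRecording:
    """Resting-state surrogate EEG: spatially correlated 1/f^alpha noise.

    Each channel is ``sqrt(rho) * common + sqrt(1 - rho) * own`` where both
    components are unit-RMS 1/f^alpha processes and ``rho`` is
    ``config.noise_spatial_corr``; the result is scaled to ``noise_rms``.
    """
    if config.duration <= 0:
        raise InvalidConfigError("duration must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.rate))
    channels = EEG_CHANNELS[: config.n_channels]
    data = np.empty((len(channels), n))
    rho = config.noise_spatial_corr
    common = _one_over_f(n, config.rate, config.noise_exponent, rng)
    for i in range(len(channels)):
        own = _one_over_f(n, config.rate, config.noise_exponent, rng)
        data[i] = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
    data *= config.noise_rms
    return EEGRecording(data=data, rate=config.rate, channels=channels)


def mrcp_waveform(config: SyntheticConfig, rate: float | None = None) -> tuple[np.ndarray, int]:
    """The planted MRCP kernel and the index of its (most negative) peak.

    A half-cosine negative ramp over ``mrcp_rise`` seconds reaching
    ``-mrcp_amplitude`` at the movement onset, then a linear return to zero
    over ``mrcp_return`` seconds.
    """
    rate = config.rate if rate is None else rate
    n_rise = int(round(config.mrcp_rise * rate))
    n_ret = int(round(config.mrcp_return * rate))
    t_rise = np.arange(n_rise) / max(n_rise, 1)
    ramp = -config.mrcp_amplitude * 0.5 * (1.0 - np.cos(np.pi * t_rise))
    t_ret = np.arange(1, n_ret + 1) / max(n_ret, 1)
    ret = -config.mrcp_amplitude * (1.0 - t_ret)
    kernel = np.concatenate([ramp, [-config.mrcp_amplitude], ret])
    return kernel, n_rise


def inject_mrcp(eeg: EEGRecording, onsets, config: SyntheticConfig) -> EEGRecording:
    """Add the MRCP kernel at each onset, scaled per channel.

    Onsets are times (s) of the negative peak; each must leave room for the
    full rise inside the recording.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        return eeg.copy()
    if np.any(onsets < config.mrcp_rise) or np.any(onsets > eeg.duration):
        raise OutOfRangeError("onset outside recording (needs mrcp_rise of lead-in)")
    out = eeg.copy()
    kernel, peak_idx = mrcp_waveform(config, eeg.rate)
    gains = np.array([config.mrcp_channel_gains.get(c, 0.0) for c in eeg.channels])
    n = out.n_samples
    for t in onsets:
        center = int(round(t * eeg.rate))
        start = center - peak_idx
        stop = min(start + kernel.size, n)
        seg = kernel[: stop - start]
        out.data[:, start:stop] += gains[:, None] * seg[None, :]
    return out


def inject_blinks(eeg: EEGRecording, blink_times, config: SyntheticConfig) -> EEGRecording:
    """Add raised-cosine blink transients: full amplitude on FP1, a small
    fixed fraction elsewhere."""
    blink_times = np.asarray(blink_times, dtype=float)
    if blink_times.size == 0 or config.blink_amplitude == 0:
        return eeg.copy()
    if np.any(blink_times < 0) or np.any(blink_times > eeg.duration):
        raise OutOfRangeError("blink time outside recording")
    out = eeg.copy()
    n_k = max(int(round(config.blink_duration * eeg.rate)), 3)
    kernel = config.blink_amplitude * np.hanning(n_k)
    gains = np.array([
        1.0 if c == "FP1" else config.blink_leak for c in eeg.channels
    ])
    n = out.n_samples
    for t in blink_times:
        center = int(round(t * eeg.rate))
        start = max(center - n_k // 2, 0)
        stop = min(start + n_k, n)
        seg = kernel[: stop - start]
        out.data[:, start:stop] += gains[:, None] * seg[None, :]
    return out


def generate_emg(onsets, config: SyntheticConfig) -> EMGRecording:
    """Baseline EMG noise plus band-limited bursts starting at each onset.

    Both baseline and bursts are white noise shaped to the 20-1000 Hz
    recording passband; burst RMS rides on top of the baseline for
    ``emg_burst_duration`` seconds.
    """
    from scipy.signal import butter, sosfiltfilt

    onsets = np.sort(np.asarray(onsets, dtype=float))
    if onsets.size > 1 and np.any(np.diff(onsets) <= config.emg_burst_duration):
        raise InvalidConfigError("EMG bursts overlap: onsets closer than emg_burst_duration")
    if onsets.size and (onsets[0] < 0 or onsets[-1] > config.duration):
        raise OutOfRangeError("EMG onset outside recording")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE36]))
    n = int(round(config.duration * config.emg_rate))
    sos = butter(4, (20.0, 1000.0), btype="bandpass", fs=config.emg_rate, output="sos")

    def shaped(size: int, rms: float) -> np.ndarray:
        x = sosfiltfilt(sos, rng.standard_normal(size))
        s = x.std()
        return x * (rms / s) if s > 0 else x

    data = shaped(n, config.emg_baseline_rms) if config.emg_baseline_rms > 0 else np.zeros(n)
    n_burst = int(round(config.emg_burst_duration * config.emg_rate))
    for t in onsets:
        start = int(round(t * config.emg_rate))
        stop = min(start + n_burst, n)
        if config.emg_burst_rms > 0:
            data[start:stop] += shaped(stop - start, config.emg_burst_rms)
    return EMGRecording(data=data, rate=config.emg_rate, passband=(20.0, 1000.0))


def _validate_effects(effects: GroundTruth) -> None:
    missing = [
        (s, t) for s in SESSIONS for t in TIMES if (s, t) not in effects.mep_effects
    ]
    if missing:
        raise InvalidConfigError(f"mep_effects missing cells: {missing}")


def generate_mep_trials(
    effects: GroundTruth,
    n_subjects: int,
    n_trials_per_block: int = 15,
    seed: int = 0,
    baseline_mean: float = 0.12,
    covariate_slopes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the study-level trial table, one row per subject x session x time.

    Generative model (the mirror of the Gamma mixed model the analysis fits):
    ``log mean = log(baseline_mean) + effect(session, time) + b`` with
    ``b ~ N(0, subject_session_sd^2)`` per subject-by-session, and each block
    value the mean of ``n_trials_per_block`` Gamma(shape=gamma_shape) draws.
    With ``n_trials_per_block=1`` a row is a single Gamma(shape) observation,
    i.e. the exact observation model of the fitted GLMM.

    The pre block is drawn at the baseline mean *without* the random intercept
    so that MEPpre enters downstream models as an exogenous covariate whose
    true slope is zero. BCI performance covariates are uniform over the
    observed study envelopes and independent of the MEPs unless
    ``covariate_slopes`` plants log-scale slopes on (covariate - center).

    Parameters
    ----------
    baseline_mean : float
        Pre-intervention mean MEP peak-peak amplitude in mV.
    """
    if n_subjects < 2:
        raise InvalidConfigError("n_subjects must be >= 2")
    if n_trials_per_block < 1:
        raise InvalidConfigError("n_trials_per_block must be >= 1")
    _validate_effects(effects)
    slopes = dict(covariate_slopes or {})
    unknown = set(slopes) - set(COVARIATE_RANGES)
    if unknown:
        raise InvalidConfigError(f"unknown covariates in covariate_slopes: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3E9]))
    shape = effects.gamma_shape

    def block_mean(mu: float, size: int) -> float:
        return rng.gamma(shape, mu / shape, size=size).mean()

    rows = []
    for subj in range(1, n_subjects + 1):
        for sess in SESSIONS:
            b = rng.normal(0.0, effects.subject_session_sd)
            covs = {
                k: rng.uniform(lo, hi) for k, (lo, hi) in COVARIATE_RANGES.items()
            }
            covs["m_r"] = float(np.round(covs["m_r"]))
            shift = sum(
                s * (covs[k] - COVARIATE_CENTERS[k]) for k, s in slopes.items()
            )
            mep_pre = block_mean(baseline_mean, n_trials_per_block)
            for time in TIMES:
                mu = baseline_mean * np.exp(effects.mep_effects[(sess, time)] + b + shift)
                mep_abs = block_mean(mu, n_trials_per_block)
                rows.append({
                    "subject": f"S{subj:03d}", "session": sess, "time": time,
                    "mep_abs": mep_abs, "mep_pre": mep_pre,
                    "mep_pct": (mep_abs - mep_pre) / mep_pre * 100.0,
                    **covs,
                })
    return pd.DataFrame(rows)
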