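"""Core in-memory containers: recordings, ground truth and generator configuration.

Amplitude conventions follow clinical practice: EEG in microvolts, surface EMG
(and MEP peak-peak amplitudes) in millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidConfigError, MissingChannelError

#: Standard 10-channel montage used throughout (10-20 positions).
EEG_CHANNELS: tuple[str, ...] = (
    "FP1", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4",
)

SESSIONS: tuple[str, ...] = ("ES", "PM", "Comb")
TIMES: tuple[str, ...] = ("post", "post30")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in microvolts.
    rate : float
        Sampling rate in samples per second.
    channels : tuple of str
        Ordered channel labels, one per row of ``data``.
    start_time : float
        Time of the first sample in seconds.
    """

    data: np.ndarray
    rate: float = 2048.0
    channels: tuple[str, ...] = EEG_CHANNELS
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.rate <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InvalidConfigError(
                f"data has {self.data.shape[0] if self.data.ndim == 2 else '?'} rows "
                f"but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("EEG samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise MissingChannelError(label) from None

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy())


@dataclass
class EMGRecording:
    """Single-channel bipolar surface EMG in millivolts."""

    data: np.ndarray
    rate: float = 4000.0
    passband: tuple[float, float] = (20.0, 1000.0)
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float).ravel()
        if self.rate <= 0:
            raise InvalidConfigError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate


@dataclass
class GroundTruth:
    """Planted truth used to generate and afterwards score synthetic data.

    ``mep_effects`` maps (session, time) to a multiplicative effect on the log
    scale of the mean MEP amplitude; the pre-intervention block has effect 0 by
    definition. ``subject_session_sd`` is the SD of the per subject-by-session
    random intercept (log scale) and ``gamma_shape`` the shape of the Gamma
    observation model for a single MEP trial.
    """

    onsets: list[float] = field(default_factory=list)
    blink_times: list[float] = field(default_factory=list)
    mep_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    subject_session_sd: float = 0.3
    gamma_shape: float = 5.0

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise InvalidConfigError("onsets must be strictly increasing")
        if self.gamma_shape <= 0:
            raise InvalidConfigError("gamma_shape must be positive")
        if self.subject_session_sd < 0:
            raise InvalidConfigError("subject_session_sd must be non-negative")


#: Relative MRCP amplitude per channel: strongest over the foot motor area (Cz),
#: attenuated on its neighbours, absent on the frontopolar artifact channel.
MRCP_CHANNEL_GAINS: dict[str, float] = {
    "Cz": 1.0, "C3": 0.6, "C4": 0.6, "Fz": 0.6, "Pz": 0.6,
    "F3": 0.3, "F4": 0.3, "P3": 0.3, "P4": 0.3, "FP1": 0.0,
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-data generator.

    All amplitudes are magnitudes (non-negative); the planted MRCP deflection
    itself is negative-going. ``seed`` fixes every random draw.
    """

    n_channels: int = len(EEG_CHANNELS)
    duration: float = 60.0
    rate: float = 2048.0
    noise_exponent: float = 1.0          # 1/f^alpha spectral slope
    noise_rms: float = 5.0               # microvolts per channel
    noise_spatial_corr: float = 0.9      # shared-variance fraction across channels
    mrcp_amplitude: float = 10.0         # microvolts, magnitude of the negative peak
    mrcp_rise: float = 2.0               # seconds of negative ramp before onset
    mrcp_return: float = 1.0             # seconds of linear return after onset
    mrcp_channel_gains: dict[str, float] = field(
        default_factory=lambda: dict(MRCP_CHANNEL_GAINS))
    blink_amplitude: float = 200.0       # microvolts, FP1 peak
    blink_duration: float = 0.3          # seconds
    blink_leak: float = 0.05             # fraction reaching non-FP1 channels
    emg_rate: float = 4000.0
    emg_baseline_rms: float = 0.05       # millivolts
    emg_burst_rms: float = 0.5           # millivolts
    emg_burst_duration: float = 1.0      # seconds
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.rate <= 0 or self.emg_rate <= 0:
            raise InvalidConfigError("sampling rates must be positive")
        for name in ("noise_rms", "mrcp_amplitude", "blink_amplitude",
                     "emg_baseline_rms", "emg_burst_rms"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be a non-negative magnitude")
        if not 0.0 <= self.noise_spatial_corr < 1.0:
            raise InvalidConfigError("noise_spatial_corr must be in [0, 1)")


@dataclass
class MovementEvent:
    """A movement-onset landmark on a recording's time axis."""

    time: float
    kind: str = "detected_onset"  # or "true_movement"
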