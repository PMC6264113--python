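"""MEP quantification: peak-peak amplitude, block averaging, percent change and
the resting motor-threshold scan.

MEPs are TMS-evoked EMG responses; their peak-peak amplitude within a short
post-stimulus window indexes corticospinal excitability. The resting threshold
follows the standard clinical rule: the lowest stimulator output at which at
least 5 of 10 MEPs exceed 50 uV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, ThresholdNotFoundError

__all__ = [
    "MEPTrial", "MEPBlock", "peak_to_peak", "average_block", "percent_change",
    "SigmoidResponseModel", "estimate_resting_threshold",
]


@dataclass
class MEPTrial:
    """One stimulus-locked EMG epoch (mV) with the peak-search window (s)."""

    epoch: np.ndarray
    rate: float = 4000.0
    window: tuple[float, float] = (0.020, 0.060)  # typical tibialis anterior latency band

    def __post_init__(self):
        self.epoch = np.asarray(self.epoch, dtype=float)
        if not np.all(np.isfinite(self.epoch)):
            raise InvalidArgumentError("epoch must be finite")
        i0, i1 = self._indices()
        if i1 <= i0 or i0 < 0 or i1 > self.epoch.size:
            raise InvalidArgumentError("peak-search window must lie inside the epoch")

    def _indices(self) -> tuple[int, int]:
        return (int(round(self.window[0] * self.rate)),
                int(round(self.window[1] * self.rate)))


@dataclass
class MEPBlock:
    """A block of MEP trials summarized by the mean peak-peak amplitude (mV)."""

    trials: list
    mean_pp: float


def peak_to_peak(trial: MEPTrial) -> float:
    """Max minus min inside the search window; DC-offset invariant, >= 0."""
    i0, i1 = trial._indices()
    seg = trial.epoch[i0:i1]
    if seg.size == 0:
        raise InvalidArgumentError("empty peak-search window")
    return float(seg.max() - seg.min())


def average_block(trials) -> MEPBlock:
    """Arithmetic mean of per-trial peak-peak amplitudes (the study averaged 15)."""
    trials = list(trials)
    if not trials:
        raise InsufficientDataError("a block needs at least one trial")
    values = [peak_to_peak(t) if isinstance(t, MEPTrial) else float(t) for t in trials]
    return MEPBlock(trials=trials, mean_pp=float(np.mean(values)))


def percent_change(pre_mean: float, post_mean: float) -> float:
    """Signed percent change (post - pre) / pre * 100."""
    if pre_mean <= 0:
        raise InvalidArgumentError("pre_mean must be positive")
    return (post_mean - pre_mean) / pre_mean * 100.0


@dataclass
class SigmoidResponseModel:
    """Stochastic stimulator-output -> MEP amplitude model (amplitudes in uV).

    The median amplitude rises exponentially through the 50 uV criterion at
    ``p50`` percent stimulator output, with lognormal trial-to-trial
    variability, so the exceedance probability is
    ``Phi(slope * (output - p50) / noise_sd)`` — 0.5 exactly at ``p50``.
    """

    p50: float = 47.0
    slope: float = 0.3       # log-amplitude gain per % stimulator output
    noise_sd: float = 0.3    # lognormal sigma
    criterion_uv: float = 50.0

    def __call__(self, output: float, n: int, rng: np.random.Generator) -> np.ndarray:
        log_med = np.log(self.criterion_uv) + self.slope * (output - self.p50)
        return np.exp(log_med + self.noise_sd * rng.standard_normal(n))

    def exceedance_probability(self, output: float) -> float:
        from scipy.stats import norm
        return float(norm.cdf(self.slope * (output - self.p50) / self.noise_sd))


def estimate_resting_threshold(
    response_model,
    outputs,
    seed: int = 0,
    n_stimuli: int = 10,
    n_required: int = 5,
    criterion_uv: float = 50.0,
) -> float:
    """Ascending-staircase resting-threshold estimate.

    Scans stimulator outputs in ascending order; at each, draws ``n_stimuli``
    MEPs from ``response_model(output, n, rng)`` and returns the first output
    where at least ``n_required`` exceed ``criterion_uv``. Raises if no grid
    point satisfies the rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x47]))
    outputs = np.sort(np.asarray(outputs, dtype=float))
    if outputs.size == 0:
        raise InvalidArgumentError("empty stimulator-output grid")
    for out in outputs:
        meps = np.asarray(response_model(float(out), n_stimuli, rng))
        if int(np.sum(meps > criterion_uv)) >= n_required:
            return float(out)
    raise ThresholdNotFoundError(
        f"no output in [{outputs[0]}, {outputs[-1]}] met the {n_required}/{n_stimuli} rule")
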