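"""Synthetic support-surface (platform) displacement traces.

The platform waveform is a smoothed trapezoid: a raised-cosine ramp of the
configured duration to the full excursion, a plateau, and (optionally) a
raised-cosine return to baseline.  Posterior translations are negative by
convention; anterior positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidParameterError


@dataclass(frozen=True)
class PlatformParams:
    """Parameters of a single horizontal surface translation.

    amplitude_cm / duration_ms define the primary ramp; measured velocity is
    a derived quantity (amplitude / rise time) and is reported, not imposed.
    """

    amplitude_cm: float = 3.0
    duration_ms: float = 210.0
    direction: str = "posterior"
    inter_trial_interval_s: tuple[float, float] = (4.0, 8.0)
    onset_jitter_sd_ms: float = 0.0
    noise_sd_cm: float = 0.01
    plateau_ms: float = 800.0

    def __post_init__(self):
        if self.amplitude_cm <= 0:
            raise InvalidParameterError("amplitude_cm must be > 0")
        if self.duration_ms <= 0:
            raise InvalidParameterError("duration_ms must be > 0")
        if self.direction not in ("anterior", "posterior"):
            raise InvalidParameterError(f"unknown direction {self.direction!r}")
        lo, hi = self.inter_trial_interval_s
        if not (0 < lo <= hi):
            raise InvalidParameterError("inter_trial_interval_s must be ordered and positive")
        if self.noise_sd_cm < 0 or self.onset_jitter_sd_ms < 0:
            raise InvalidParameterError("noise/jitter SDs must be >= 0")

    @property
    def signed_amplitude_cm(self) -> float:
        return -self.amplitude_cm if self.direction == "posterior" else self.amplitude_cm


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0->1 ramp over n samples (raised cosine)."""
    t = np.arange(n) / max(n - 1, 1)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def generate_platform_trajectory(
    params: PlatformParams,
    sample_rate: float = 1000.0,
    seed=None,
    pre_s: float = 0.5,
    post_s: float = 1.5,
    return_to_baseline: bool = True,
):
    """Generate one displacement trace (cm) plus its true onset sample index.

    Returns (trace, onset_index).  The trace covers pre_s of baseline before
    the ramp and post_s after the ramp start; measurement noise of
    ``params.noise_sd_cm`` is added when a seed/rng is supplied or noise > 0.
    """
    if sample_rate < 100:
        raise InvalidParameterError("sample_rate must be >= 100 Hz")
    rng = np.random.default_rng(seed)

    n_pre = int(round(pre_s * sample_rate))
    n_post = int(round(post_s * sample_rate))
    n_ramp = int(round(params.duration_ms / 1000.0 * sample_rate))
    n = n_pre + n_post
    trace = np.zeros(n)

    amp = params.signed_amplitude_cm
    onset = n_pre
    ramp = amp * _raised_cosine(n_ramp)
    end_ramp = min(onset + n_ramp, n)
    trace[onset:end_ramp] = ramp[: end_ramp - onset]
    trace[end_ramp:] = amp

    if return_to_baseline:
        n_plateau = int(round(params.plateau_ms / 1000.0 * sample_rate))
        ret_start = min(onset + n_ramp + n_plateau, n)
        ret_end = min(ret_start + n_ramp, n)
        if ret_end > ret_start:
            back = amp * (1.0 - _raised_cosine(n_ramp))
            trace[ret_start:ret_end] = back[: ret_end - ret_start]
            trace[ret_end:] = 0.0

    if params.noise_sd_cm > 0:
        trace = trace + rng.normal(0.0, params.noise_sd_cm, size=n)
    return trace, onset


def generate_platform_recording(
    params: PlatformParams,
    n_trials: int,
    duration_s: float | None = None,
    sample_rate: float = 1000.0,
    seed=None,
):
    """Continuous recording with ``n_trials`` perturbations at 4-8 s intervals.

    Returns (trace, onset_indices).  Onsets are spaced by draws from the
    configured inter-trial interval; an optional total duration pads the tail.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = params.inter_trial_interval_s
    intervals = rng.uniform(lo, hi, size=n_trials)
    onset_times = 1.0 + np.cumsum(intervals) - intervals[0]  # first onset at 1 s
    total_s = duration_s if duration_s is not None else onset_times[-1] + 3.0
    n = int(round(total_s * sample_rate))
    trace = np.zeros(n)

    n_ramp = int(round(params.duration_ms / 1000.0 * sample_rate))
    n_plateau = int(round(params.plateau_ms / 1000.0 * sample_rate))
    amp = params.signed_amplitude_cm
    up = amp * _raised_cosine(n_ramp)
    down = amp * (1.0 - _raised_cosine(n_ramp))

    onsets = []
    for t0 in onset_times:
        if params.onset_jitter_sd_ms > 0:
            t0 = t0 + rng.normal(0.0, params.onset_jitter_sd_ms) / 1000.0
        i0 = int(round(t0 * sample_rate))
        if i0 + 2 * n_ramp + n_plateau >= n:
            break
        trace[i0:i0 + n_ramp] = up
        trace[i0 + n_ramp:i0 + n_ramp + n_plateau] = amp
        j0 = i0 + n_ramp + n_plateau
        trace[j0:j0 + n_ramp] = down
        onsets.append(i0)

    if params.noise_sd_cm > 0:
        trace = trace + rng.normal(0.0, params.noise_sd_cm, size=n)
    return trace, np.asarray(onsets, dtype=int)
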