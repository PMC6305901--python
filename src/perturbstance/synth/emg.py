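"""Synthetic surface-EMG epochs with reflex bursts and evoked responses.

Background EMG is band-limited (10-450 Hz at 1 kHz) Gaussian noise whose
amplitude is modulated by a piecewise phase envelope; reflex bursts are
Gaussian-envelope amplitude bumps.  For stimulated trials a stimulation
artifact, an M-wave and a biphasic H-reflex wavelet are inserted in
physiological order (artifact < M < H) after the stimulus.

For zero-mean Gaussian noise of SD sigma the mean rectified amplitude is
sigma * sqrt(2/pi); envelopes are specified as target mean rectified
amplitudes and divided by that factor internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sg

from ..constants import (
    BMR_START_MS,
    EMG_CHANNELS,
    EPOCH_PRE_MS,
    PHASE_BOUNDS,
    STIM_PHASES,
)
from ..errors import InvalidParameterError

RECTIFIED_MEAN_FACTOR = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class ReflexBurstSpec:
    """Gaussian amplitude bump centred inside one reflex window."""

    phase_label: str
    center_latency_ms: float
    width_ms: float
    gain: float

    def __post_init__(self):
        if self.phase_label not in ("SLR", "MLR", "LLR", "BMR"):
            raise InvalidParameterError(f"unknown phase {self.phase_label!r}")
        if self.width_ms <= 0:
            raise InvalidParameterError("width_ms must be > 0")
        if self.gain < 0:
            raise InvalidParameterError("gain must be >= 0")
        if self.phase_label != "BMR":
            a, b = PHASE_BOUNDS[self.phase_label]
            if not a <= self.center_latency_ms < b:
                raise InvalidParameterError(
                    f"burst centre {self.center_latency_ms} ms outside "
                    f"{self.phase_label} window [{a}, {b})"
                )
        elif self.center_latency_ms < BMR_START_MS:
            raise InvalidParameterError("BMR burst centre before 120 ms")


@lru_cache(maxsize=8)
def _bandpass_sos(fs: float, lo: float = 10.0, hi: float = 450.0):
    return sg.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_limited_noise(n: int, rng, fs: float = 1000.0) -> np.ndarray:
    """Unit-RMS band-passed Gaussian noise (10-450 Hz)."""
    white = rng.standard_normal(n + 200)
    x = sg.sosfilt(_bandpass_sos(fs), white)[200:]  # drop filter transient
    sd = np.std(x)
    return x / sd if sd > 0 else x


def phase_envelope(t_ms: np.ndarray, levels: dict, bmr_end_ms: float = 400.0,
                   transition_ms: float = 2.0) -> np.ndarray:
    """Target mean-rectified-amplitude envelope over the epoch.

    ``levels`` maps phase -> amplitude (mV).  Levels are constant inside each
    window; the 0-30 ms gap and inter-window edges are linearly blended over
    ``transition_ms`` to avoid discontinuities.
    """
    knots_t = [t_ms[0]]
    knots_v = [max(levels.get("PRE", 0.0), 0.0)]
    segs = [("PRE", *PHASE_BOUNDS["PRE"]),
            ("SLR", *PHASE_BOUNDS["SLR"]),
            ("MLR", *PHASE_BOUNDS["MLR"]),
            ("LLR", *PHASE_BOUNDS["LLR"]),
            ("BMR", BMR_START_MS, bmr_end_ms)]
    for name, a, b in segs:
        v = max(levels.get(name, 0.0), 0.0)
        knots_t += [a + (transition_ms if a > t_ms[0] else 0.0), b - 1e-9]
        knots_v += [v, v]
    knots_t += [min(bmr_end_ms + 50.0, t_ms[-1]), t_ms[-1]]
    tail = max(levels.get("PRE", 0.0), 0.0)
    knots_v += [tail, tail]
    order = np.argsort(knots_t)
    return np.interp(t_ms, np.asarray(knots_t)[order], np.asarray(knots_v)[order])


def biphasic_wavelet(t_ms: np.ndarray, center_ms: float, p2p_mv: float,
                     half_period_ms: float = 4.0, width_ms: float = 4.0) -> np.ndarray:
    """Gabor-like biphasic wave scaled to an exact peak-to-peak amplitude."""
    phase = np.sin(np.pi * (t_ms - center_ms) / half_period_ms)
    env = np.exp(-0.5 * ((t_ms - center_ms) / width_ms) ** 2)
    w = phase * env
    ptp = np.ptp(w)
    return w / ptp * p2p_mv if ptp > 0 else w


def generate_emg_trial(
    condition: str,
    direction: str,
    stim_phase: str,
    bursts: dict | None,
    background_level: dict,
    seed=None,
    *,
    fs: float = 1000.0,
    pre_ms: float = 500.0,
    post_ms: float = 1500.0,
    onset_ms: float = 0.0,
    bmr_end_ms: float = 400.0,
    stim_time_ms: float | None = None,
    h_p2p_mv: float = 0.0,
    m_p2p_mv: float = 0.0,
    artifact_mv: float = 5.0,
    m_latency_ms: float = 14.0,
    h_latency_ms: float = 35.0,
):
    """Six EMG channels plus a bookkeeping record of the inserted truth.

    ``background_level`` maps muscle -> phase -> mean rectified amplitude in
    mV (a plain float applies one level to all phases).  ``bursts`` maps
    muscle -> list of ReflexBurstSpec.  Times are relative to perturbation
    onset; the returned arrays span [-pre_ms, post_ms).
    """
    if condition not in ("predicted", "unpredicted", "cheated"):
        raise InvalidParameterError(f"unknown condition {condition!r}")
    if stim_phase not in STIM_PHASES:
        raise InvalidParameterError(f"unknown stimulation phase {stim_phase!r}")
    if stim_phase != "none" and stim_time_ms is None:
        raise InvalidParameterError("stimulated trials need a stim_time_ms")

    rng = np.random.default_rng(seed)
    n = int(round((pre_ms + post_ms) * fs / 1000.0))
    t_ms = np.arange(n) * 1000.0 / fs - pre_ms

    channels = {}
    truth = {"condition": condition, "direction": direction,
             "stim_phase": stim_phase, "envelopes": {}, "bursts": {}}

    for muscle in EMG_CHANNELS:
        lv = background_level.get(muscle, 0.0)
        levels = dict(lv) if isinstance(lv, dict) else {p: lv for p in
                                                        ("PRE", "SLR", "MLR", "LLR", "BMR")}
        env = phase_envelope(t_ms, levels, bmr_end_ms=bmr_end_ms)
        mbursts = (bursts or {}).get(muscle, [])
        if mbursts:
            factor = np.ones_like(t_ms)
            for b in mbursts:
                factor += b.gain * np.exp(
                    -0.5 * ((t_ms - b.center_latency_ms) / b.width_ms) ** 2)
            # renormalize inside each analysis window so the window-mean
            # envelope still equals the configured level
            for a, bb in [PHASE_BOUNDS["SLR"], PHASE_BOUNDS["MLR"],
                          PHASE_BOUNDS["LLR"], (BMR_START_MS, bmr_end_ms)]:
                sel = (t_ms >= a) & (t_ms < bb)
                if np.any(sel):
                    factor[sel] /= np.mean(factor[sel])
            env = env * factor
        sigma = env / RECTIFIED_MEAN_FACTOR
        x = band_limited_noise(n, rng, fs=fs) * sigma
        channels[muscle] = x
        truth["envelopes"][muscle] = levels
        truth["bursts"][muscle] = [(b.phase_label, b.center_latency_ms, b.gain)
                                   for b in (bursts or {}).get(muscle, [])]

    if stim_phase != "none":
        st = float(stim_time_ms)
        sol = channels["SOL"]
        # stimulation artifact: 1 ms biphasic pulse
        art = biphasic_wavelet(t_ms, st, artifact_mv, half_period_ms=1.0, width_ms=0.7)
        m_wave = biphasic_wavelet(t_ms, st + m_latency_ms, m_p2p_mv)
        h_wave = biphasic_wavelet(t_ms, st + h_latency_ms, h_p2p_mv)
        channels["SOL"] = sol + art + m_wave + h_wave
        truth.update(stim_time_ms=st, h_p2p_mv=h_p2p_mv, m_p2p_mv=m_p2p_mv,
                     m_latency_ms=m_latency_ms, h_latency_ms=h_latency_ms)

    return channels, truth
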