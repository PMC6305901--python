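"""Analytic COP and joint-angle trace builders.

Traces are built through control points with shape-preserving (PCHIP)
interpolation so that the analysis stage recovers the configured summary
values exactly: the value at onset, the fixed-latency samples, and a signed
peak excursion of the configured size at the configured latency.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from ..constants import EPOCH_POST_MS, EPOCH_PRE_MS, FS_COP, FS_FAST


def _round_to_grid(t_ms: float, fs: float) -> float:
    step = 1000.0 / fs
    return round(t_ms / step) * step


def build_cop_epoch(
    cop_onset_cm: float,
    cop_peak_delta_cm: float,
    peak_index_ms: float,
    cop_90_cm: float | None = None,
    cop_120_cm: float | None = None,
    fs: float = FS_COP,
    recovery_fraction: float = 0.6,
    noise_sd_cm: float = 0.0,
    rng=None,
) -> np.ndarray:
    """One COP epoch over [-100, +500) ms realizing the given summary values.

    The peak latency is rounded to the sampling grid and clamped to
    [140, 480] ms; intermediate fixed-latency values are clamped to at most
    95 % of the peak excursion so the configured peak remains the extremum.
    """
    peak_ms = float(np.clip(_round_to_grid(peak_index_ms, fs), 140.0, 480.0))
    peak_val = cop_onset_cm + cop_peak_delta_cm

    def _clamp(v):
        if v is None:
            return None
        delta = v - cop_onset_cm
        lim = 0.95 * abs(cop_peak_delta_cm)
        delta = np.clip(delta, -lim, lim) if cop_peak_delta_cm < 0 else np.clip(delta, -lim, lim)
        # keep the intermediate point on the path towards the peak
        if cop_peak_delta_cm != 0 and np.sign(delta) != np.sign(cop_peak_delta_cm):
            delta = 0.05 * cop_peak_delta_cm
        return cop_onset_cm + delta

    knots_t = [-EPOCH_PRE_MS, 0.0]
    knots_v = [cop_onset_cm, cop_onset_cm]
    for t, v in ((90.0, _clamp(cop_90_cm)), (120.0, _clamp(cop_120_cm))):
        if v is not None and t < peak_ms:
            knots_t.append(t)
            knots_v.append(v)
    knots_t += [peak_ms, EPOCH_POST_MS]
    knots_v += [peak_val, cop_onset_cm + recovery_fraction * cop_peak_delta_cm]

    interp = PchipInterpolator(knots_t, knots_v)
    t = np.arange(int(round((EPOCH_PRE_MS + EPOCH_POST_MS) * fs / 1000.0))) \
        * 1000.0 / fs - EPOCH_PRE_MS
    x = interp(t)
    if noise_sd_cm > 0 and rng is not None:
        x = x + rng.normal(0.0, noise_sd_cm, x.size)
    return x


def build_joint_epoch(
    onset_angle_deg: float,
    excursion_deg: float,
    peak_index_ms: float,
    fs: float = FS_FAST,
    recovery_fraction: float = 0.6,
    noise_sd_deg: float = 0.0,
    rng=None,
) -> np.ndarray:
    """One goniometer epoch: flat pre-phase, raised-cosine rise to the peak
    deviation at the configured latency, then partial recovery."""
    peak_ms = float(np.clip(peak_index_ms, 140.0, 480.0))
    n = int(round((EPOCH_PRE_MS + EPOCH_POST_MS) * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs - EPOCH_PRE_MS
    x = np.full(n, onset_angle_deg, dtype=float)

    rise = (t > 0) & (t <= peak_ms)
    x[rise] += excursion_deg * 0.5 * (1.0 - np.cos(np.pi * t[rise] / peak_ms))
    fall = t > peak_ms
    span = EPOCH_POST_MS - peak_ms
    if span > 0:
        frac = (t[fall] - peak_ms) / span
        x[fall] += excursion_deg * (1.0 - (1.0 - recovery_fraction) * frac)
    if noise_sd_deg > 0 and rng is not None:
        x = x + rng.normal(0.0, noise_sd_deg, n)
    return x
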