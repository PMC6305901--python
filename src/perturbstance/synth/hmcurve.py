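"""Synthetic H-reflex / M-wave recruitment curves.

The M-wave follows a logistic recruitment that saturates at ``m_max``.  The
H-reflex is unimodal: zero below threshold, a raised-cosine rise to ``h_max``
at ``h_peak_intensity`` and a raised-cosine fall back to zero as the direct
motor response occludes the reflex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError
from ..hreflex import RecruitmentCurve


@dataclass(frozen=True)
class HMCurveParams:
    m_max_mv: float = 8.0
    h_max_mv: float = 4.0
    h_threshold_intensity: float = 10.0
    h_peak_intensity: float = 25.0
    h_end_intensity: float = 45.0
    m_half_intensity: float = 35.0
    m_slope: float = 5.0

    def __post_init__(self):
        if self.m_max_mv <= 0 or self.h_max_mv <= 0:
            raise InvalidParameterError("m_max_mv and h_max_mv must be > 0")
        if not (self.h_threshold_intensity < self.h_peak_intensity < self.h_end_intensity):
            raise InvalidParameterError(
                "require h_threshold_intensity < h_peak_intensity < h_end_intensity"
            )
        if self.m_slope <= 0:
            raise InvalidParameterError("m_slope must be > 0")


def m_response(params: HMCurveParams, intensity) -> np.ndarray:
    i = np.asarray(intensity, dtype=float)
    return params.m_max_mv / (1.0 + np.exp(-(i - params.m_half_intensity) / params.m_slope))


def h_response(params: HMCurveParams, intensity) -> np.ndarray:
    i = np.asarray(intensity, dtype=float)
    h = np.zeros_like(i)
    up = (i >= params.h_threshold_intensity) & (i <= params.h_peak_intensity)
    frac = (i[up] - params.h_threshold_intensity) / (
        params.h_peak_intensity - params.h_threshold_intensity
    )
    h[up] = params.h_max_mv * 0.5 * (1.0 - np.cos(np.pi * frac))
    down = (i > params.h_peak_intensity) & (i < params.h_end_intensity)
    frac = (i[down] - params.h_peak_intensity) / (
        params.h_end_intensity - params.h_peak_intensity
    )
    h[down] = params.h_max_mv * 0.5 * (1.0 + np.cos(np.pi * frac))
    return h


def generate_hm_curve_samples(
    params: HMCurveParams,
    intensities,
    noise_sd_mv: float = 0.0,
    seed=None,
) -> RecruitmentCurve:
    """Sample the recruitment model on a strictly increasing intensity grid."""
    i = np.asarray(intensities, dtype=float)
    if i.size == 0:
        raise InvalidParameterError("intensity grid is empty")
    if i.size > 1 and not np.all(np.diff(i) > 0):
        raise InvalidParameterError("intensity grid must be strictly increasing")
    h = h_response(params, i)
    m = m_response(params, i)
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        h = np.clip(h + rng.normal(0.0, noise_sd_mv, i.size), 0.0, None)
        m = np.clip(m + rng.normal(0.0, noise_sd_mv, i.size), 0.0, None)
    return RecruitmentCurve(intensity=i, h_mv=h, m_mv=m)
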