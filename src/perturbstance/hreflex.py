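"""Recruitment-curve processing and per-trial H-reflex / M-wave extraction.

Calibration follows the standard procedure of setting the stimulation
intensity on the ascending limb of the H recruitment curve where the H
amplitude equals a target fraction (default 25 %) of the maximal M-wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import EPOCH_PRE_MS, FS_FAST
from .errors import (
    InvalidParameterError,
    UnreachableTargetError,
    WindowBoundsError,
)

#: default peak-to-peak search windows, ms after the stimulus artifact
DEFAULT_M_WINDOW_MS = (5.0, 25.0)
DEFAULT_H_WINDOW_MS = (25.0, 55.0)


@dataclass
class RecruitmentCurve:
    """H and M peak-to-peak amplitudes sampled over a stimulation-intensity grid."""

    intensity: np.ndarray
    h_mv: np.ndarray
    m_mv: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.h_mv = np.asarray(self.h_mv, dtype=float)
        self.m_mv = np.asarray(self.m_mv, dtype=float)
        if not (self.intensity.shape == self.h_mv.shape == self.m_mv.shape):
            raise InvalidParameterError("intensity, H and M grids must be aligned")
        if np.any(self.h_mv < 0) or np.any(self.m_mv < 0):
            raise InvalidParameterError("peak-to-peak amplitudes must be >= 0")

    @property
    def m_max_mv(self) -> float:
        return float(np.max(self.m_mv))


@dataclass
class HMResult:
    trial_id: str
    stim_phase: str
    h_mv: float
    m_mv: float
    subject: str = ""
    condition: str = ""
    flagged: bool = False


def calibrate_intensity(curve: RecruitmentCurve, target_fraction: float = 0.25) -> float:
    """Intensity on the ascending H limb where H = target_fraction * M-max.

    Linear interpolation between grid points; if several crossings exist the
    lowest intensity is returned.
    """
    if curve.intensity.size < 5:
        raise InvalidParameterError("recruitment curve needs >= 5 points")
    if not 0 <= target_fraction <= 1:
        raise InvalidParameterError("target_fraction must be in [0, 1]")

    peak_idx = int(np.argmax(curve.h_mv))
    asc_i = curve.intensity[: peak_idx + 1]
    asc_h = curve.h_mv[: peak_idx + 1]
    target = target_fraction * curve.m_max_mv

    max_frac = float(np.max(asc_h) / curve.m_max_mv) if curve.m_max_mv > 0 else 0.0
    if asc_h.size == 0 or np.max(asc_h) < target:
        raise UnreachableTargetError(target_fraction, max_frac)

    for k in range(asc_h.size):
        if asc_h[k] >= target:
            if k == 0 or asc_h[k] == target:
                return float(asc_i[k])
            h0, h1 = asc_h[k - 1], asc_h[k]
            i0, i1 = asc_i[k - 1], asc_i[k]
            return float(i0 + (target - h0) / (h1 - h0) * (i1 - i0))
    raise UnreachableTargetError(target_fraction, max_frac)  # pragma: no cover


def peak_to_peak(epoch: np.ndarray, window_ms, fs: float = FS_FAST,
                 epoch_pre_ms: float = EPOCH_PRE_MS) -> float:
    """max - min of the raw signal within a half-open window [a, b) ms.

    The window is expressed relative to perturbation onset, matching the
    epoch convention (t = 0 at sample ``epoch_pre_ms`` ms).
    """
    a, b = window_ms
    i0 = int(round((a + epoch_pre_ms) * fs / 1000.0))
    i1 = int(round((b + epoch_pre_ms) * fs / 1000.0))
    if i1 <= i0:
        raise WindowBoundsError(f"empty peak-to-peak window [{a}, {b}) ms")
    if i0 < 0 or i1 > epoch.size:
        raise WindowBoundsError(f"window [{a}, {b}) ms outside epoch")
    seg = epoch[i0:i1]
    return float(np.max(seg) - np.min(seg))


def extract_hm(trial, stim_time_ms: float,
               m_window_ms=DEFAULT_M_WINDOW_MS,
               h_window_ms=DEFAULT_H_WINDOW_MS,
               saturation_mv: float = 50.0) -> HMResult:
    """Per-trial H and M peak-to-peak amplitudes from the SOL channel.

    ``stim_time_ms`` is the stimulus time relative to perturbation onset;
    search windows are offset from it.  Trials whose search windows are
    saturated by the stimulation artifact are flagged.
    """
    if trial.stim_phase == "none":
        raise InvalidParameterError("extract_hm requires a stimulated trial")
    sol = trial.channels["SOL"]
    fs = trial.rates["SOL"]
    m = peak_to_peak(sol, (stim_time_ms + m_window_ms[0], stim_time_ms + m_window_ms[1]), fs=fs)
    h = peak_to_peak(sol, (stim_time_ms + h_window_ms[0], stim_time_ms + h_window_ms[1]), fs=fs)
    flagged = (m > saturation_mv) or (h > saturation_mv)
    return HMResult(
        trial_id=str(trial.meta.get("trial_id", "")),
        stim_phase=trial.stim_phase,
        h_mv=h,
        m_mv=m,
        subject=trial.subject,
        condition=trial.condition,
        flagged=flagged,
    )


def hm_table(trials, stim_times: dict | None = None, **kwargs) -> pd.DataFrame:
    """Tidy table of HMResults for all stimulated trials.

    ``stim_times`` maps (subject, stim_phase) -> stimulus time in ms; when
    absent the trial metadata field ``stim_time_ms`` is used.
    """
    rows = []
    for t in trials:
        if t.stim_phase == "none":
            continue
        if stim_times is not None and (t.subject, t.stim_phase) in stim_times:
            st = stim_times[(t.subject, t.stim_phase)]
        else:
            st = t.meta.get("stim_time_ms")
        if st is None:
            raise InvalidParameterError(
                f"no stimulus time for trial {t.meta.get('trial_id')!r}"
            )
        r = extract_hm(t, float(st), **kwargs)
        rows.append(
            dict(subject=r.subject, condition=r.condition, phase=r.stim_phase,
                 trial_id=r.trial_id, h_mv=r.h_mv, m_mv=r.m_mv, flagged=r.flagged)
        )
    return pd.DataFrame(rows)


def normalize_hm_to_predicted(table: pd.DataFrame) -> pd.DataFrame:
    """Express subject-mean H and M per phase as % of the predicted condition."""
    out = table[~table["flagged"]].groupby(
        ["subject", "condition", "phase"], as_index=False
    )[["h_mv", "m_mv"]].mean()
    ref = out[out["condition"] == "predicted"].set_index(["subject", "phase"])
    for col, pct in (("h_mv", "h_pct_predicted"), ("m_mv", "m_pct_predicted")):
        denom = out.set_index(["subject", "phase"]).index.map(ref[col])
        out[pct] = np.where(np.asarray(denom, float) > 0,
                            out[col].to_numpy() / np.asarray(denom, float) * 100.0,
                            np.nan)
    return out
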