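"""COP displacement metrics and joint-kinematic summaries per trial.

Peak excursion is the largest-magnitude signed deviation from the onset
value within [0, 500) ms (not a fixed-direction maximum), so trials that
start with an anterior lean still yield the posterior peak with its sign.
The peak latency is reported positive, in ms after onset; ties break to the
earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COP_CHANNEL, EPOCH_POST_MS, EPOCH_PRE_MS, FS_COP, FS_FAST
from .errors import InvalidParameterError


@dataclass(frozen=True)
class CopMetrics:
    cop_onset_cm: float        # value at the sample nearest -1 ms
    cop_90_cm: float           # absolute position at +90 ms
    cop_120_cm: float          # absolute position at +120 ms
    cop_90_delta_cm: float     # onset-referenced variants (both are emitted)
    cop_120_delta_cm: float
    cop_peak_cm: float         # signed peak excursion minus onset value
    peak_index_ms: float       # latency of the peak, ms after onset


@dataclass(frozen=True)
class JointKinematics:
    joint: str
    onset_angle_deg: float
    excursion_deg: float       # |peak deviation from onset| within [0, 500) ms
    peak_index_ms: float
    quality_flag: bool = False # True when angles leave [0, 360] degrees


def _nearest(idx_onset: int, t_ms: float, fs: float) -> int:
    return idx_onset + int(round(t_ms * fs / 1000.0))


def _peak_deviation(x: np.ndarray, onset_idx: int, fs: float, ref: float | None = None):
    """Signed extremum of (x - onset value) in [0, 500) ms and its latency."""
    if ref is None:
        ref = float(x[onset_idx])
    n_post = int(round(EPOCH_POST_MS * fs / 1000.0))
    dev = x[onset_idx:onset_idx + n_post] - ref
    k = int(np.argmax(np.abs(dev)))  # argmax returns the first (earliest) tie
    return float(dev[k]), k * 1000.0 / fs


def cop_metrics(cop_epoch, fs: float = FS_COP, onset_index: int | None = None) -> CopMetrics:
    """COP summary for one epoch covering [-100, +500) ms at ``fs``."""
    x = np.asarray(cop_epoch, dtype=float)
    if onset_index is None:
        onset_index = int(round(EPOCH_PRE_MS * fs / 1000.0))
    n_post = int(round(EPOCH_POST_MS * fs / 1000.0))
    if x.size < onset_index + n_post:
        raise InvalidParameterError("COP epoch does not cover [-100, +500) ms")

    onset = float(x[_nearest(onset_index, -1.0, fs)])
    c90 = float(x[_nearest(onset_index, 90.0, fs)])
    c120 = float(x[_nearest(onset_index, 120.0, fs)])
    peak, peak_ms = _peak_deviation(x, onset_index, fs, ref=onset)
    return CopMetrics(
        cop_onset_cm=onset,
        cop_90_cm=c90,
        cop_120_cm=c120,
        cop_90_delta_cm=c90 - onset,
        cop_120_delta_cm=c120 - onset,
        cop_peak_cm=peak,
        peak_index_ms=peak_ms,
    )


def joint_kinematics(angle_epoch, joint: str, fs: float = FS_FAST,
                     onset_index: int | None = None) -> JointKinematics:
    """Joint summary for one goniometer epoch covering [-100, +500) ms."""
    x = np.asarray(angle_epoch, dtype=float)
    if onset_index is None:
        onset_index = int(round(EPOCH_PRE_MS * fs / 1000.0))
    n_post = int(round(EPOCH_POST_MS * fs / 1000.0))
    if x.size < onset_index + n_post:
        raise InvalidParameterError("joint epoch does not cover [-100, +500) ms")

    onset = float(x[onset_index])
    peak, peak_ms = _peak_deviation(x, onset_index, fs)
    flag = bool(np.any(x < 0.0) or np.any(x > 360.0))
    return JointKinematics(
        joint=joint,
        onset_angle_deg=onset,
        excursion_deg=abs(peak),
        peak_index_ms=peak_ms,
        quality_flag=flag,
    )


def kinematics_table(trials, joints=("ANKLE", "KNEE", "HIP")) -> pd.DataFrame:
    """Tidy per-trial COP and joint rows for a list of TrialRecordings."""
    rows = []
    for t in trials:
        base = dict(subject=t.subject, condition=t.condition,
                    direction=t.direction, trial_id=t.meta.get("trial_id", ""))
        if COP_CHANNEL in t.channels:
            cm = cop_metrics(t.channels[COP_CHANNEL], fs=t.rates[COP_CHANNEL])
            rows.append({**base, "measure": "cop",
                         "cop_onset_cm": cm.cop_onset_cm,
                         "cop_90_cm": cm.cop_90_cm,
                         "cop_120_cm": cm.cop_120_cm,
                         "cop_90_delta_cm": cm.cop_90_delta_cm,
                         "cop_120_delta_cm": cm.cop_120_delta_cm,
                         "cop_peak_cm": cm.cop_peak_cm,
                         "cop_peak_index_ms": cm.peak_index_ms})
        for j in joints:
            if j in t.channels:
                jk = joint_kinematics(t.channels[j], j, fs=t.rates[j])
                rows.append({**base, "measure": f"joint_{j.lower()}",
                             "onset_angle_deg": jk.onset_angle_deg,
                             "excursion_deg": jk.excursion_deg,
                             "joint_peak_index_ms": jk.peak_index_ms,
                             "quality_flag": jk.quality_flag})
    return pd.DataFrame(rows)
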