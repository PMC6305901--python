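"""Continuous recordings, onset detection and fixed 600 ms epoching.

Epoch convention: sample index ``EPOCH_PRE_MS * fs / 1000`` (100 at 1 kHz,
10 at 100 Hz) corresponds to t = 0 (perturbation onset); all windows are
half-open [start, end) in ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    COP_CHANNEL,
    EPOCH_POST_MS,
    EPOCH_PRE_MS,
    FS_COP,
    FS_FAST,
    PLATFORM_CHANNEL,
)
from .errors import InvalidParameterError, NoPerturbationError, ReconciliationError

log = logging.getLogger(__name__)


@dataclass
class ContinuousRecording:
    """Multichannel recording with per-channel sample rates."""

    channels: dict
    rates: dict
    subject: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in self.channels:
            if name not in self.rates:
                raise InvalidParameterError(f"channel {name!r} has no declared rate")
            if self.rates[name] <= 0:
                raise InvalidParameterError(f"channel {name!r} has non-positive rate")
            self.channels[name] = np.asarray(self.channels[name], dtype=float)


@dataclass
class TrialRecording:
    """One 600 ms analysis epoch ([-100, +500) ms around onset)."""

    channels: dict
    rates: dict
    subject: str = ""
    condition: str = ""
    direction: str = ""
    stim_phase: str = "none"
    onset_sample: int = 0  # onset index in the source recording, master rate
    meta: dict = field(default_factory=dict)

    def time_ms(self, channel: str) -> np.ndarray:
        fs = self.rates[channel]
        n = self.channels[channel].size
        return np.arange(n) * 1000.0 / fs - EPOCH_PRE_MS

    def onset_index(self, channel: str) -> int:
        return int(round(EPOCH_PRE_MS * self.rates[channel] / 1000.0))


def _refine_onset(x: np.ndarray, baseline: float, crossing: int, fs: float) -> int:
    """Back-extrapolate a threshold crossing to the true movement onset.

    For a smooth ramp the square root of |displacement| grows almost linearly
    from the onset, so a linear fit to sqrt|x - baseline| over the stretch
    following the crossing extrapolates to the zero-displacement time.
    """
    k = max(int(round(0.020 * fs)), 4)  # 20 ms of rising signal
    seg = np.abs(x[crossing:crossing + k] - baseline)
    if seg.size < 4:
        return crossing
    s = np.sqrt(seg)
    t = np.arange(seg.size, dtype=float)
    slope, intercept = np.polyfit(t, s, 1)
    if slope <= 0:
        return crossing
    t0 = crossing - intercept / slope
    return int(round(np.clip(t0, crossing - int(0.05 * fs), crossing)))


def detect_onsets(
    platform: np.ndarray,
    threshold_fraction: float = 0.05,
    fs: float = FS_FAST,
    refractory_s: float = 1.0,
    refine: bool = True,
) -> np.ndarray:
    """Onset sample indices where the trace first leaves its baseline band.

    The baseline band is the trace median +/- threshold_fraction * full
    excursion.  Detections closer than ``refractory_s`` are merged; onsets
    too close to either edge for a full epoch are dropped with a warning.
    """
    x = np.asarray(platform, dtype=float)
    n_epoch_pre = int(round(EPOCH_PRE_MS * fs / 1000.0))
    n_epoch_post = int(round(EPOCH_POST_MS * fs / 1000.0))
    if x.size <= n_epoch_pre + n_epoch_post:
        raise InvalidParameterError("recording shorter than one epoch")
    if not 0 < threshold_fraction < 1:
        raise InvalidParameterError("threshold_fraction must be in (0, 1)")

    # baseline from the leading stretch of the recording (guaranteed to
    # precede the first perturbation by one epoch pre-window); a global
    # median is biased when the platform stays displaced for most of a
    # short snippet
    n_base = max(int(round(0.3 * fs)), n_epoch_pre)
    baseline = float(np.median(x[:n_base]))
    excursion = float(np.max(np.abs(x - baseline)))
    if excursion <= 0:
        raise NoPerturbationError("flat platform channel: no perturbation found")

    out_of_band = np.abs(x - baseline) > threshold_fraction * excursion
    crossings = np.flatnonzero(out_of_band & ~np.roll(out_of_band, 1))
    crossings = crossings[crossings > 0]

    refractory = int(round(refractory_s * fs))
    sustain = int(round(0.05 * fs))  # a real ramp stays out of band for >= 50 ms
    onsets = []
    last = -refractory - 1
    for c in crossings:
        if c - last < refractory:
            continue
        seg = out_of_band[c:c + sustain]
        if seg.size and np.mean(seg) < 0.9:
            continue
        last = c
        idx = _refine_onset(x, baseline, int(c), fs) if refine else int(c)
        if idx < n_epoch_pre or idx + n_epoch_post > x.size:
            log.warning("onset at sample %d too close to recording edge; dropped", idx)
            continue
        onsets.append(idx)
    return np.asarray(onsets, dtype=int)


def segment(
    recording: ContinuousRecording,
    onsets,
    metadata: list[dict] | None = None,
    master_rate: float = FS_FAST,
) -> list[TrialRecording]:
    """Cut one TrialRecording per onset.

    Channels are sliced on their own sampling grid at the sample nearest the
    onset time (<= 5 ms skew for the 100 Hz COP channel; no resampling).
    Metadata dicts are joined to onsets by order.
    """
    onsets = np.asarray(onsets, dtype=int)
    if metadata is not None and len(metadata) != onsets.size:
        unmatched = list(range(min(len(metadata), onsets.size), max(len(metadata), onsets.size)))
        raise ReconciliationError(
            f"{onsets.size} onsets but {len(metadata)} metadata rows",
            unmatched=unmatched,
        )

    trials = []
    for k, onset in enumerate(onsets):
        t_onset = onset / master_rate
        chans, rates = {}, {}
        ok = True
        for name, data in recording.channels.items():
            fs = recording.rates[name]
            i0 = int(round(t_onset * fs))
            pre = int(round(EPOCH_PRE_MS * fs / 1000.0))
            post = int(round(EPOCH_POST_MS * fs / 1000.0))
            if i0 - pre < 0 or i0 + post > data.size:
                log.warning("trial %d: incomplete epoch on channel %s; dropped", k, name)
                ok = False
                break
            chans[name] = data[i0 - pre:i0 + post].copy()
            rates[name] = fs
        if not ok:
            continue
        md = dict(metadata[k]) if metadata is not None else {}
        trials.append(
            TrialRecording(
                channels=chans,
                rates=rates,
                subject=str(md.get("subject", recording.subject)),
                condition=str(md.get("condition", "")),
                direction=str(md.get("direction", "")),
                stim_phase=str(md.get("stim_phase", "none")),
                onset_sample=int(onset),
                meta=md,
            )
        )
    return trials


def characterize_platform(
    trial_or_epoch,
    fs: float = FS_FAST,
    baseline_window_ms=(-100.0, -10.0),
    plateau_window_ms=(280.0, 480.0),
) -> dict:
    """Amplitude / rise-time summary of a platform epoch.

    Amplitude is the plateau mean minus the pre-onset baseline mean (signed,
    cm); rise time spans the 5-95 % crossings of that excursion, and mean
    velocity is amplitude over the full-ramp estimate derived from it.
    """
    if isinstance(trial_or_epoch, TrialRecording):
        x = trial_or_epoch.channels[PLATFORM_CHANNEL]
        fs = trial_or_epoch.rates[PLATFORM_CHANNEL]
    else:
        x = np.asarray(trial_or_epoch, dtype=float)

    pre = EPOCH_PRE_MS

    def _win_mean(w):
        i0 = int(round((w[0] + pre) * fs / 1000.0))
        i1 = int(round((w[1] + pre) * fs / 1000.0))
        return float(np.mean(x[i0:i1]))

    baseline = _win_mean(baseline_window_ms)
    plateau = _win_mean(plateau_window_ms)
    amplitude = plateau - baseline

    frac = (x - baseline) / amplitude if amplitude != 0 else np.zeros_like(x)
    onset_idx = int(round(pre * fs / 1000.0))
    post = frac[onset_idx:]
    above05 = np.flatnonzero(post >= 0.05)
    above95 = np.flatnonzero(post >= 0.95)
    if above05.size and above95.size:
        rise_ms = (above95[0] - above05[0]) * 1000.0 / fs
        # the 5-95 % crossing span of a raised-cosine ramp covers
        # (acos(-0.9) - acos(0.9)) / pi = 0.7129 of its full duration
        duration_ms = rise_ms / 0.7129
    else:
        rise_ms = float("nan")
        duration_ms = float("nan")
    velocity = abs(amplitude) / 100.0 / (duration_ms / 1000.0) if duration_ms == duration_ms else float("nan")
    return dict(
        amplitude_cm=amplitude,
        abs_amplitude_cm=abs(amplitude),
        rise_5_95_ms=rise_ms,
        duration_ms=duration_ms,
        mean_velocity_m_s=velocity,
    )
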