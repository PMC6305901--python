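"""Phase-window construction, rectified-integrated EMG and normalization.

Units: raw EMG in mV, iEMG in mV*s, time-normalized amplitude in mV (the
integral divided by the window duration in seconds), activity in %MVC
relative to the peak-window mean amplitude of the best MVC trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    BMR_START_MS,
    EPOCH_POST_MS,
    EPOCH_PRE_MS,
    FS_FAST,
    PHASE_BOUNDS,
    PHASES,
)
from .errors import (
    DegenerateBmrWindowError,
    InvalidParameterError,
    WindowBoundsError,
    ZeroMvcError,
)
from .posturography import cop_metrics

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseWindows:
    """The five half-open analysis windows [start, end) in ms from onset."""

    pre: tuple = PHASE_BOUNDS["PRE"]
    slr: tuple = PHASE_BOUNDS["SLR"]
    mlr: tuple = PHASE_BOUNDS["MLR"]
    llr: tuple = PHASE_BOUNDS["LLR"]
    bmr: tuple = (BMR_START_MS, 344.0)

    def as_dict(self) -> dict:
        return {"PRE": self.pre, "SLR": self.slr, "MLR": self.mlr,
                "LLR": self.llr, "BMR": self.bmr}


def build_phase_windows(cop_peak_index_ms: float) -> PhaseWindows:
    """Windows with the trial-specific BMR endpoint at the COP peak latency."""
    if cop_peak_index_ms <= BMR_START_MS:
        raise DegenerateBmrWindowError(
            f"COP peak at {cop_peak_index_ms} ms leaves an empty BMR window"
        )
    if cop_peak_index_ms > EPOCH_POST_MS:
        raise InvalidParameterError("COP peak latency beyond the 500 ms epoch")
    return PhaseWindows(bmr=(BMR_START_MS, float(cop_peak_index_ms)))


def _window_indices(window_ms, fs, epoch_pre_ms, n):
    a, b = window_ms
    i0 = int(round((a + epoch_pre_ms) * fs / 1000.0))
    i1 = int(round((b + epoch_pre_ms) * fs / 1000.0))
    if i1 <= i0:
        raise WindowBoundsError(f"empty window [{a}, {b}) ms")
    if i0 < 0 or i0 >= n or i1 > n:
        raise WindowBoundsError(f"window [{a}, {b}) ms outside epoch of {n} samples")
    return i0, i1


def rectified_integral(emg_epoch, window_ms, fs: float = FS_FAST,
                       epoch_pre_ms: float = EPOCH_PRE_MS) -> float:
    """Trapezoidal integral of |signal| over a half-open window, in mV*s.

    The trapezoid includes the sample at the window end, so a constant c mV
    over a w ms window integrates to exactly c * w / 1000 and integrals over
    adjacent windows add exactly.  A window ending at the epoch edge is
    integrated up to the last available sample.
    """
    x = np.asarray(emg_epoch, dtype=float)
    a, b = window_ms
    i0 = int(round((a + epoch_pre_ms) * fs / 1000.0))
    i1 = int(round((b + epoch_pre_ms) * fs / 1000.0))
    if i1 <= i0:
        raise WindowBoundsError(f"empty window [{a}, {b}) ms")
    if i0 < 0 or i1 > x.size:
        raise WindowBoundsError(f"window [{a}, {b}) ms outside epoch")
    i1 = min(i1, x.size - 1)
    return float(np.trapezoid(np.abs(x[i0:i1 + 1]), dx=1.0 / fs))


def integrated_duration_s(window_ms, fs: float = FS_FAST,
                          epoch_pre_ms: float = EPOCH_PRE_MS,
                          n_samples: int | None = None) -> float:
    """Duration actually covered by ``rectified_integral`` for this window."""
    a, b = window_ms
    i0 = int(round((a + epoch_pre_ms) * fs / 1000.0))
    i1 = int(round((b + epoch_pre_ms) * fs / 1000.0))
    if n_samples is not None:
        i1 = min(i1, n_samples - 1)
    return (i1 - i0) / fs


@dataclass(frozen=True)
class MvcReference:
    """Per-muscle normalization basis from the best MVC trial."""

    muscle: str
    mean_amplitude_mv: float   # mean rectified amplitude over the peak window
    iemg_mvs: float
    duration_s: float
    trial_index: int


def extract_mvc_reference(mvc_trials, muscle: str, fs: float = FS_FAST,
                          half_window_ms: float = 50.0) -> MvcReference:
    """Reference amplitude from the MVC trial with the largest rectified peak.

    Integrates |signal| over [peak - 50 ms, peak + 50 ms); at a recording
    edge the window is clipped to the available samples and the (shorter)
    actual duration is used.
    """
    if len(mvc_trials) == 0:
        raise InvalidParameterError(f"no MVC trials for muscle {muscle!r}")
    peaks = [float(np.max(np.abs(np.asarray(t, dtype=float)))) for t in mvc_trials]
    best = int(np.argmax(peaks))
    if peaks[best] == 0:
        raise ZeroMvcError(muscle)

    x = np.asarray(mvc_trials[best], dtype=float)
    p = int(np.argmax(np.abs(x)))
    half = int(round(half_window_ms * fs / 1000.0))
    i0, i1 = p - half, p + half
    if i0 < 0 or i1 > x.size - 1:
        log.warning("MVC peak of %s within %g ms of the edge; window clipped",
                    muscle, half_window_ms)
        i0, i1 = max(i0, 0), min(i1, x.size - 1)
    duration = (i1 - i0) / fs
    iemg = float(np.trapezoid(np.abs(x[i0:i1 + 1]), dx=1.0 / fs))
    return MvcReference(
        muscle=muscle,
        mean_amplitude_mv=iemg / duration,
        iemg_mvs=iemg,
        duration_s=duration,
        trial_index=best,
    )


def normalize_features(iemg_mvs: float, duration_s: float, mvc: MvcReference):
    """(mean amplitude mV, %MVC) from an iEMG value and its window duration."""
    if duration_s <= 0:
        raise InvalidParameterError("window duration must be > 0")
    if mvc.mean_amplitude_mv <= 0:
        raise ZeroMvcError(mvc.muscle)
    mean_mv = iemg_mvs / duration_s
    pct_mvc = mean_mv / mvc.mean_amplitude_mv * 100.0
    return mean_mv, pct_mvc


@dataclass(frozen=True)
class ReflexPeakLatencies:
    slr_ms: float
    mlr_ms: float
    llr_ms: float
    low_confidence: bool = False

    def as_dict(self):
        return {"SLR": self.slr_ms, "MLR": self.mlr_ms, "LLR": self.llr_ms}


def detect_reflex_peaks(trials, muscle: str = "SOL", fs: float = FS_FAST,
                        smooth_ms: float = 9.0) -> ReflexPeakLatencies:
    """Individual SLR/MLR/LLR peak latencies from unstimulated trials.

    The rectified traces are ensemble-averaged, smoothed with a moving
    average, and the argmax latency inside each reflex window is returned
    (ties to the earliest sample).
    """
    epochs = []
    for t in trials:
        x = t.channels[muscle] if hasattr(t, "channels") else np.asarray(t, dtype=float)
        epochs.append(np.abs(np.asarray(x, dtype=float)))
    if len(epochs) < 2:
        raise InvalidParameterError("reflex-peak detection needs >= 2 trials")
    mean = np.mean(np.stack(epochs), axis=0)

    k = max(int(round(smooth_ms * fs / 1000.0)), 1)
    kernel = np.ones(k)
    smooth = np.convolve(mean, kernel, mode="same") / np.convolve(
        np.ones_like(mean), kernel, mode="same")

    flat = bool(np.ptp(smooth) == 0)
    out = {}
    for phase in ("SLR", "MLR", "LLR"):
        a, b = PHASE_BOUNDS[phase]
        i0, i1 = _window_indices((a, b), fs, EPOCH_PRE_MS, mean.size)
        out[phase] = (i0 + int(np.argmax(smooth[i0:i1]))) * 1000.0 / fs - EPOCH_PRE_MS
    return ReflexPeakLatencies(out["SLR"], out["MLR"], out["LLR"], low_confidence=flat)


def features_table(trials, mvc_refs: dict, fs: float = FS_FAST,
                   muscles=None) -> pd.DataFrame:
    """Tidy per-trial muscle x phase feature rows for unstimulated trials.

    Stimulated trials are excluded (their SOL trace carries the evoked
    responses).  The BMR endpoint is each trial's own COP peak latency;
    trials whose COP peak precedes 120 ms contribute no BMR row.
    """
    from .constants import COP_CHANNEL, EMG_CHANNELS

    muscles = tuple(muscles) if muscles is not None else EMG_CHANNELS
    rows = []
    for t in trials:
        if t.stim_phase != "none":
            continue
        windows = PhaseWindows()
        have_bmr = False
        if COP_CHANNEL in t.channels:
            cm = cop_metrics(t.channels[COP_CHANNEL], fs=t.rates[COP_CHANNEL])
            try:
                windows = build_phase_windows(cm.peak_index_ms)
                have_bmr = True
            except DegenerateBmrWindowError:
                log.warning("trial %s: COP peak at %g ms; excluded from BMR",
                            t.meta.get("trial_id", "?"), cm.peak_index_ms)
        for muscle in muscles:
            if muscle not in t.channels:
                continue
            epoch = t.channels[muscle]
            mvc = mvc_refs[muscle]
            for phase, win in windows.as_dict().items():
                if phase == "BMR" and not have_bmr:
                    continue
                iemg = rectified_integral(epoch, win, fs=t.rates[muscle])
                dur = integrated_duration_s(win, fs=t.rates[muscle],
                                            n_samples=epoch.size)
                mean_mv, pct = normalize_features(iemg, dur, mvc)
                rows.append(dict(
                    subject=t.subject, condition=t.condition,
                    direction=t.direction, trial_id=t.meta.get("trial_id", ""),
                    muscle=muscle, phase=phase,
                    iemg_mvs=iemg, mean_mv=mean_mv, pct_mvc=pct,
                ))
    return pd.DataFrame(rows)
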