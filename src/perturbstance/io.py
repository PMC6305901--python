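"""Text serialization of multichannel time series.

One self-describing TSV dialect is used for both continuous recordings and
cut epochs: ``#``-prefixed header lines carry JSON metadata and per-channel
sample rates, then a header row and one row per master-rate sample.  Channels
sampled below the master rate appear only on the rows where they have a
sample (other cells are empty), so mixed 1 kHz / 100 Hz data share one file.

Values are written with 17 significant digits, making write -> read a
lossless round trip for float64 data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .segmentation import ContinuousRecording, TrialRecording

MAGIC = "# perturbstance-timeseries v1"
_FMT = "%.17g"


def _write(path, channels, rates, meta):
    names = list(channels)
    master = max(rates[n] for n in names)
    n_rows = max(channels[n].size * int(round(master / rates[n])) for n in names)
    steps = {n: int(round(master / rates[n])) for n in names}

    lines = [MAGIC,
             "# meta\t" + json.dumps(meta, sort_keys=True),
             "# rates\t" + json.dumps({n: rates[n] for n in names}, sort_keys=True),
             "\t".join(["row"] + names)]
    cols = {n: np.char.mod(_FMT, channels[n]) for n in names}
    for i in range(n_rows):
        cells = [str(i)]
        for n in names:
            st = steps[n]
            if i % st == 0 and i // st < channels[n].size:
                cells.append(cols[n][i // st])
            else:
                cells.append("")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _read(path):
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != MAGIC:
        raise ValueError(f"{path}: not a perturbstance timeseries file")
    meta = json.loads(lines[1].split("\t", 1)[1])
    rates = json.loads(lines[2].split("\t", 1)[1])
    names = lines[3].split("\t")[1:]
    data = {n: [] for n in names}
    for line in lines[4:]:
        cells = line.split("\t")
        for n, c in zip(names, cells[1:]):
            if c != "":
                data[n].append(float(c))
    channels = {n: np.asarray(v, dtype=float) for n, v in data.items()}
    return channels, {n: float(rates[n]) for n in names}, meta


def write_continuous(path, recording: ContinuousRecording) -> None:
    meta = dict(recording.meta)
    meta["subject"] = recording.subject
    meta["kind"] = "continuous"
    _write(path, recording.channels, recording.rates, meta)


def read_continuous(path) -> ContinuousRecording:
    channels, rates, meta = _read(path)
    subject = meta.pop("subject", "")
    meta.pop("kind", None)
    return ContinuousRecording(channels=channels, rates=rates, subject=subject, meta=meta)


def write_trial(path, trial: TrialRecording) -> None:
    meta = dict(trial.meta)
    meta.update(
        kind="trial",
        subject=trial.subject,
        condition=trial.condition,
        direction=trial.direction,
        stim_phase=trial.stim_phase,
        onset_sample=trial.onset_sample,
    )
    _write(path, trial.channels, trial.rates, meta)


def read_trial(path) -> TrialRecording:
    channels, rates, meta = _read(path)
    meta.pop("kind", None)
    return TrialRecording(
        channels=channels,
        rates=rates,
        subject=str(meta.pop("subject", "")),
        condition=str(meta.pop("condition", "")),
        direction=str(meta.pop("direction", "")),
        stim_phase=str(meta.pop("stim_phase", "none")),
        onset_sample=int(meta.pop("onset_sample", 0)),
        meta=meta,
    )


def read_plain_tsv(path, rates: dict | None = None) -> ContinuousRecording:
    """Import a plain multi-column TSV (``time_ms`` + channel columns).

    The sample rate is inferred from the ``time_ms`` column unless per-channel
    rates are given explicitly.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: plain TSV import requires a 'time_ms' column")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = np.median(np.diff(t))
    fs = 1000.0 / dt
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_ms"}
    rr = {c: (rates.get(c, fs) if rates else fs) for c in channels}
    return ContinuousRecording(channels=channels, rates=rr)
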