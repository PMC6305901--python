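"""On-disk layout of a synthetic cohort.

::

    outdir/
      config.yaml          declarative generator configuration
      subjects.tsv         subject-level truth (long format)
      trials.tsv           trial metadata (subject, condition, direction, ...)
      truth.tsv            reflex latencies and MVC reference truth
      <subject>/
        trial_<id>.tsv     one continuous multichannel snippet per trial
        mvc_<muscle>_<k>.tsv
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..constants import EMG_CHANNELS
from ..io import read_continuous, write_continuous
from ..segmentation import ContinuousRecording
from .cohort import Cohort, CohortConfig
from .platform import PlatformParams


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["latent_correlation"] = {
        cond: {f"{a}|{b}": rho for (a, b), rho in pairs.items()}
        for cond, pairs in config.latent_correlation.items()}
    d["conditions"] = list(config.conditions)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "platform" in d and isinstance(d["platform"], dict):
        p = dict(d["platform"])
        if "inter_trial_interval_s" in p:
            p["inter_trial_interval_s"] = tuple(p["inter_trial_interval_s"])
        d["platform"] = PlatformParams(**p)
    if "latent_correlation" in d:
        d["latent_correlation"] = {
            cond: {tuple(k.split("|")): v for k, v in pairs.items()}
            for cond, pairs in d["latent_correlation"].items()}
    if "conditions" in d:
        d["conditions"] = tuple(d["conditions"])
    return CohortConfig(**d)


def write_cohort(cohort: Cohort, outdir, waveforms: bool = True,
                 directions=("posterior",)) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config_to_dict(cohort.config)))
    cohort.subject_table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    cohort.trial_table.to_csv(out / "trials.tsv", sep="\t", index=False)

    truth_rows = []
    for sid, lat in cohort.reflex_latencies.items():
        for phase, ms in lat.items():
            truth_rows.append((sid, f"reflex_latency_{phase}", ms))
    for (sid, muscle), amp in cohort.mvc_amp.items():
        truth_rows.append((sid, f"mvc_amp_{muscle}", amp))
    pd.DataFrame(truth_rows, columns=["subject", "quantity", "value"]).to_csv(
        out / "truth.tsv", sep="\t", index=False)

    if not waveforms:
        return
    for _, row in cohort.trial_table.iterrows():
        if row["direction"] not in directions:
            continue
        rec = cohort.trial_recording(row)
        sdir = out / row["subject"]
        sdir.mkdir(exist_ok=True)
        write_continuous(sdir / f"trial_{row['trial_id']}.tsv", rec)
    for sid in cohort.reflex_latencies:
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        for muscle, trials in cohort.mvc_trials(sid).items():
            for k, x in enumerate(trials):
                rec = ContinuousRecording(channels={muscle: np.asarray(x)},
                                          rates={muscle: 1000.0}, subject=sid,
                                          meta={"kind_detail": "mvc", "rep": k})
                write_continuous(sdir / f"mvc_{muscle}_{k}.tsv", rec)


def read_cohort_dir(path):
    """Load config and tables; waveform files are read lazily by the caller."""
    p = Path(path)
    config = config_from_dict(yaml.safe_load((p / "config.yaml").read_text()))
    subjects = pd.read_csv(p / "subjects.tsv", sep="\t")
    trials = pd.read_csv(p / "trials.tsv", sep="\t")
    truth = pd.read_csv(p / "truth.tsv", sep="\t")
    return config, subjects, trials, truth


def iter_trial_files(path):
    p = Path(path)
    for f in sorted(p.glob("*/trial_*.tsv")):
        yield f, read_continuous(f)


def read_mvc_trials(path, subject):
    p = Path(path) / subject
    out = {}
    for muscle in EMG_CHANNELS:
        files = sorted(p.glob(f"mvc_{muscle}_*.tsv"))
        if files:
            out[muscle] = [read_continuous(f).channels[muscle] for f in files]
    return out
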