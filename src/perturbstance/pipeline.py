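"""End-to-end orchestration: generate -> segment -> features -> stats.

One root seed fans out to stage-level streams; a JSON manifest records the
stage list, output-file hashes and versions so a rerun with an identical
config can be verified to be byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .constants import PLATFORM_CHANNEL
from .emg_features import extract_mvc_reference, features_table
from .errors import ConfigValidationError, PerturbstanceError
from .hreflex import hm_table, normalize_hm_to_predicted
from .posturography import kinematics_table
from .segmentation import detect_onsets, segment
from .stats import correlation_family, rm_anova, render_report, summary_table
from .synth import (
    CohortConfig,
    config_from_dict,
    generate_cohort,
    iter_trial_files,
    read_mvc_trials,
    write_cohort,
)
from .io import read_trial, write_trial

log = logging.getLogger("perturbstance.pipeline")

STAGES = ("synth_cohort", "segment", "emg_features", "hreflex", "kinematics", "stats")


def validate_run_config(raw: dict) -> dict:
    """Schema check with field-path errors; returns a normalized config dict."""
    if not isinstance(raw, dict):
        raise ConfigValidationError("<root>", "run config must be a mapping")
    cfg = dict(raw)
    cfg.setdefault("threshold_fraction", 0.05)
    cfg.setdefault("reuse_cohort", False)
    cfg.setdefault("fdr_q", 0.05)
    cfg.setdefault("seed", 0)
    cfg.setdefault("cohort", {})

    if "out" not in cfg:
        raise ConfigValidationError("out", "output directory is required")
    if not 0 < cfg["threshold_fraction"] < 1:
        raise ConfigValidationError("threshold_fraction", "must be in (0, 1)")
    if not 0 < cfg["fdr_q"] < 1:
        raise ConfigValidationError("fdr_q", "must be in (0, 1)")
    if not isinstance(cfg["seed"], int):
        raise ConfigValidationError("seed", "must be an integer")
    try:
        cohort_cfg = dict(cfg["cohort"])
        cohort_cfg["seed"] = cfg["seed"]
        cfg["_cohort_config"] = config_from_dict(cohort_cfg)
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError("cohort", str(exc)) from exc
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, out: Path, config: dict, seed: int):
        self.data = {"version": __version__, "seed": seed,
                     "config": {k: v for k, v in config.items() if not k.startswith("_")},
                     "stages": []}
        self.out = out

    def stage(self, name: str, outputs):
        entry = {"stage": name,
                 "outputs": {str(p.relative_to(self.out)): _sha256(p)
                             for p in outputs}}
        self.data["stages"].append(entry)
        log.info("stage %s complete (%d outputs)", name, len(outputs))

    def write(self):
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def run_all(raw_config: dict) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    cfg = validate_run_config(raw_config)
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, cfg, cfg["seed"])

    # 1. synthetic cohort -------------------------------------------------
    cohort = generate_cohort(cfg["_cohort_config"])
    cohort_dir = out / "cohort"
    if not (cfg["reuse_cohort"] and cohort_dir.exists()):
        write_cohort(cohort, cohort_dir, waveforms=True, directions=("posterior",))
    manifest.stage("synth_cohort",
                   sorted(p for p in cohort_dir.rglob("*.tsv"))
                   + [cohort_dir / "config.yaml"])

    # 2. segmentation -----------------------------------------------------
    trials_dir = out / "trials"
    trials_dir.mkdir(exist_ok=True)
    trial_files = []
    for f, rec in iter_trial_files(cohort_dir):
        try:
            onsets = detect_onsets(rec.channels[PLATFORM_CHANNEL],
                                   cfg["threshold_fraction"])
            trials = segment(rec, onsets, metadata=[rec.meta] * len(onsets))
        except PerturbstanceError as exc:
            raise PerturbstanceError(f"segmentation failed on {f}: {exc}") from exc
        if len(trials) != 1:
            raise PerturbstanceError(
                f"segmentation failed on {f}: expected 1 trial, got {len(trials)}")
        tpath = trials_dir / f.name
        write_trial(tpath, trials[0])
        trial_files.append(tpath)
    manifest.stage("segment", trial_files)

    trials = [read_trial(p) for p in trial_files]

    # 3. EMG features -----------------------------------------------------
    mvc_refs_by_subject = {}
    for sid in cohort.reflex_latencies:
        mvc = read_mvc_trials(cohort_dir, sid)
        mvc_refs_by_subject[sid] = {
            m: extract_mvc_reference(arrs, m) for m, arrs in mvc.items()}
    feat_frames = []
    for sid, refs in mvc_refs_by_subject.items():
        sub_trials = [t for t in trials if t.subject == sid]
        feat_frames.append(features_table(sub_trials, refs))
    features = pd.concat(feat_frames, ignore_index=True)
    fpath = out / "features.tsv"
    features.to_csv(fpath, sep="\t", index=False)
    manifest.stage("emg_features", [fpath])

    # 4. H-reflexes -------------------------------------------------------
    hm = hm_table(trials)
    hm_norm = normalize_hm_to_predicted(hm) if len(hm) else pd.DataFrame()
    hpath = out / "hm.tsv"
    hm_norm.to_csv(hpath, sep="\t", index=False)
    manifest.stage("hreflex", [hpath])

    # 5. kinematics -------------------------------------------------------
    kin = kinematics_table(trials)
    kpath = out / "kin.tsv"
    kin.to_csv(kpath, sep="\t", index=False)
    manifest.stage("kinematics", [kpath])

    # 6. statistics -------------------------------------------------------
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    outputs = run_stats_stage(features, hm_norm, kin, report_dir,
                              fdr_q=cfg["fdr_q"])
    manifest.stage("stats", outputs)

    mpath = manifest.write()
    manifest.data["manifest_path"] = str(mpath)
    return manifest.data


def run_stats_stage(features, hm_norm, kin, report_dir: Path, fdr_q=0.05):
    """Summary tables, the anticipation rmANOVA and the correlation family."""
    report_dir = Path(report_dir)
    outputs = []

    cop = kin[kin["measure"] == "cop"]
    subj_cop = cop.groupby(["subject", "condition"], as_index=False)[
        ["cop_onset_cm", "cop_peak_cm", "cop_peak_index_ms"]].mean()

    tables = {}
    tables["cop"] = summary_table(
        subj_cop.melt(id_vars=["subject", "condition"], var_name="variable"),
        "value", by=["variable"])
    subj_emg = features.groupby(["subject", "condition", "muscle", "phase"],
                                as_index=False)["pct_mvc"].mean()
    tables["emg_pct_mvc"] = summary_table(subj_emg, "pct_mvc", by=["muscle", "phase"])
    if len(hm_norm):
        tables["h_reflex_pct_predicted"] = summary_table(
            hm_norm, "h_pct_predicted", by=["phase"])

    anova = rm_anova(subj_cop, "cop_peak_cm", within="condition")
    anova_df = pd.DataFrame([vars(a) | {"partial_eta_sq": a.partial_eta_sq}
                             for a in anova])
    apath = report_dir / "anova_cop_peak.tsv"
    anova_df.to_csv(apath, sep="\t", index=False)
    outputs.append(apath)

    pairs = []
    for cond, sub in subj_cop.groupby("condition"):
        if len(sub) < 4:  # Spearman needs n >= 4; small demo cohorts skip it
            continue
        pairs.append((f"{cond}:cop_onset", f"{cond}:cop_peak",
                      sub["cop_onset_cm"].to_numpy(), sub["cop_peak_cm"].to_numpy()))
    corr = correlation_family(pairs, q=fdr_q) if pairs else []
    cpath = report_dir / "correlations.tsv"
    pd.DataFrame([vars(c) for c in corr]).to_csv(cpath, sep="\t", index=False)
    outputs.append(cpath)

    for name, tab in tables.items():
        tpath = report_dir / f"table_{name}.tsv"
        tab.to_csv(tpath, sep="\t", index=False)
        outputs.append(tpath)
    rpath = report_dir / "report.txt"
    render_report(tables, corr, path=rpath)
    outputs.append(rpath)
    return outputs
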