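"""Whole-cohort forward model: subjects x conditions x trials.

Subject-level quantities are drawn from configured per-condition effect
tables through a Gaussian copula: one latent multivariate-normal vector per
subject and condition, whose correlation matrix realizes the configured
rank-correlation targets (latent Pearson r = 2 sin(pi * rho / 6)), mapped
through per-variable quantile transforms.  Trial waveforms are synthesized
on demand from those subject-level values, so every downstream analysis has
an exact ground truth.

Seeding: one root ``numpy.random.SeedSequence(seed)``; child k is subject
k's stream, from which per-trial and per-MVC streams are spawned in a fixed
order.  Identical configs therefore give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..constants import CONDITIONS, EMG_CHANNELS, JOINT_CHANNELS, PHASES, REFLEX_PHASES
from ..errors import InvalidParameterError, NonPositiveDefiniteError
from ..segmentation import ContinuousRecording
from . import defaults
from .emg import ReflexBurstSpec, generate_emg_trial
from .platform import PlatformParams, generate_platform_trajectory
from .traces import build_cop_epoch, build_joint_epoch

_REFLEX_LATENCY_PRIORS = {"SLR": (45.0, 3.0, 38.0, 54.0),
                          "MLR": (72.0, 3.0, 65.0, 80.0),
                          "LLR": (100.0, 4.0, 92.0, 112.0)}


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 29
    trials_per_phase: int = 10          # posterior trials per stimulation phase
    n_anterior: int = 40                # anterior trials per condition (bookkeeping)
    conditions: tuple = CONDITIONS
    platform: PlatformParams = field(default_factory=PlatformParams)
    cop_table: dict = field(default_factory=lambda: defaults.COP_TABLE)
    joint_table: dict = field(default_factory=lambda: defaults.JOINT_TABLE)
    emg_table: dict = field(default_factory=lambda: defaults.EMG_TABLE)
    h_modulation: dict = field(default_factory=lambda: defaults.H_MODULATION)
    latent_correlation: dict = field(default_factory=lambda: defaults.LATENT_CORRELATION)
    h_base_p2p_mv: float = 2.0
    m_p2p_mv: float = 6.0
    h_factor_sd_frac: float = 0.10      # subject scatter of the H modulation factors
    mvc_mean_amp_mv: float = 0.5
    mvc_amp_sd_mv: float = 0.05
    trial_jitter_frac: float = 0.05     # per-trial scatter, fraction of subject SD
    burst_gain: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_phase < 1:
            raise InvalidParameterError("subject and trial counts must be > 0")
        if self.n_anterior < 0:
            raise InvalidParameterError("n_anterior must be >= 0")
        for table in (self.cop_table, self.emg_table):
            for entry in table.values():
                for sub in entry.values():
                    vals = sub.values() if isinstance(sub, dict) else [sub]
                    for v in vals:
                        if isinstance(v, tuple) and v[1] < 0:
                            raise InvalidParameterError("SDs must be >= 0")
        for cond, pairs in self.latent_correlation.items():
            for pair, rho in pairs.items():
                if not -1.0 <= rho <= 1.0:
                    raise InvalidParameterError(
                        f"correlation target {pair} = {rho} outside [-1, 1]")


def variable_marginals(config: CohortConfig, condition: str) -> dict:
    """Ordered mapping variable name -> (mean, sd) for one condition."""
    out = {}
    for var, per_cond in config.cop_table.items():
        out[var] = per_cond[condition]
    for joint, entries in config.joint_table.items():
        for key, per_cond in entries.items():
            out[f"{joint.lower()}_{key}"] = per_cond[condition]
    for muscle, phases in config.emg_table.items():
        for phase, per_cond in phases.items():
            out[f"emg_{muscle}_{phase}"] = per_cond[condition]
    for phase, per_cond in config.h_modulation.items():
        f = per_cond[condition]
        out[f"h_{phase}"] = (f, config.h_factor_sd_frac * f)
    return out


def latent_correlation_matrix(names, targets: dict):
    """Latent Pearson matrix realizing Spearman targets; validates PD."""
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    mat = np.eye(k)
    for (a, b), rho in targets.items():
        if a not in idx or b not in idx:
            raise InvalidParameterError(f"unknown correlation variable in ({a}, {b})")
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        offenders = []
        for pair in targets:
            trial = dict(targets)
            trial.pop(pair)
            try:
                latent_correlation_matrix(names, trial)
                offenders.append(pair)
            except (NonPositiveDefiniteError, np.linalg.LinAlgError):
                pass
        raise NonPositiveDefiniteError(offenders or list(targets))
    return mat


def generate_subject_table(config: CohortConfig, seed_seq=None) -> pd.DataFrame:
    """Long table (subject, condition, variable, value) of subject-level truth."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    subject_seqs = seed_seq.spawn(config.n_subjects)

    # pre-build per-condition copula pieces
    pieces = {}
    for cond in config.conditions:
        marg = variable_marginals(config, cond)
        names = list(marg)
        mat = latent_correlation_matrix(names, config.latent_correlation.get(cond, {}))
        means = np.array([marg[n][0] for n in names])
        sds = np.array([marg[n][1] for n in names])
        pieces[cond] = (names, means, sds, np.linalg.cholesky(mat))

    rows = []
    for s, sseq in enumerate(subject_seqs):
        rng = np.random.default_rng(sseq.spawn(1)[0])
        sid = f"S{s + 1:02d}"
        for cond in config.conditions:
            names, means, sds, chol = pieces[cond]
            z = chol @ rng.standard_normal(len(names))
            # quantile transform; for the normal marginals used here the
            # round trip is the identity on z, kept explicit for clarity
            values = means + sds * norm.ppf(norm.cdf(z))
            rows.extend((sid, cond, n, float(v)) for n, v in zip(names, values))
    return pd.DataFrame(rows, columns=["subject", "condition", "variable", "value"])


def trial_bookkeeping(config: CohortConfig) -> pd.DataFrame:
    """Metadata rows for every trial of every subject and condition."""
    rows = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for cond in config.conditions:
            k = 0
            for phase in ("none", "SLR", "MLR", "LLR"):
                for _ in range(config.trials_per_phase):
                    rows.append((sid, cond, "posterior", phase,
                                 f"{sid}_{cond}_post_{k:03d}"))
                    k += 1
            for a in range(config.n_anterior):
                rows.append((sid, cond, "anterior", "none",
                             f"{sid}_{cond}_ant_{a:03d}"))
    return pd.DataFrame(rows, columns=["subject", "condition", "direction",
                                       "stim_phase", "trial_id"])


@dataclass
class Cohort:
    """Generated cohort: truth tables plus on-demand trial waveforms."""

    config: CohortConfig
    subject_table: pd.DataFrame
    trial_table: pd.DataFrame
    reflex_latencies: dict          # subject -> {phase: latency ms}
    mvc_amp: dict                   # (subject, muscle) -> mean rectified amp, mV

    def subject_value(self, subject: str, condition: str, variable: str) -> float:
        t = self.subject_table
        m = t[(t.subject == subject) & (t.condition == condition)
              & (t.variable == variable)]
        return float(m["value"].iloc[0])

    def _subject_values(self, subject, condition):
        t = self.subject_table
        sub = t[(t.subject == subject) & (t.condition == condition)]
        return dict(zip(sub["variable"], sub["value"]))

    def _trial_rng(self, trial_id: str):
        # deterministic per-trial stream independent of generation order
        h = np.frombuffer(trial_id.encode(), dtype=np.uint8)
        return np.random.default_rng(
            np.random.SeedSequence([self.config.seed, int(h.sum()), len(trial_id),
                                    int(np.dot(h, np.arange(1, h.size + 1)) % (2 ** 31))]))

    def trial_recording(self, trial_row) -> ContinuousRecording:
        """Synthesize the continuous 2.5 s snippet for one trial-table row."""
        cfg = self.config
        row = trial_row
        rng = self._trial_rng(row["trial_id"])
        vals = self._subject_values(row["subject"], row["condition"])
        jit = cfg.trial_jitter_frac

        pre_s, post_s = 0.6, 1.9
        params = replace(cfg.platform, direction=row["direction"])
        platform, onset = generate_platform_trajectory(
            params, sample_rate=1000.0, seed=rng, pre_s=pre_s, post_s=post_s)

        marg = variable_marginals(cfg, row["condition"])

        def tval(name):
            mean, sd = marg[name]
            return vals[name] + rng.normal(0.0, jit * sd)

        peak_idx = tval("cop_peak_index")
        cop_epoch = build_cop_epoch(
            tval("cop_onset"), tval("cop_peak"), peak_idx,
            cop_90_cm=tval("cop_90"), cop_120_cm=tval("cop_120"),
            noise_sd_cm=0.0)
        n_cop = int(round((pre_s + post_s) * 100))
        cop = np.full(n_cop, cop_epoch[0])
        c0 = int(round(pre_s * 100)) - 10
        cop[c0:c0 + cop_epoch.size] = cop_epoch
        cop[c0 + cop_epoch.size:] = cop_epoch[-1]

        joints = {}
        for joint in JOINT_CHANNELS:
            ep = build_joint_epoch(
                tval(f"{joint.lower()}_onset"),
                max(tval(f"{joint.lower()}_excursion"), 0.0),
                tval(f"{joint.lower()}_peak_index"),
                noise_sd_deg=0.02, rng=rng)
            full = np.full(platform.size, ep[0])
            j0 = onset - 100
            full[j0:j0 + ep.size] = ep
            full[j0 + ep.size:] = ep[-1]
            joints[joint] = full

        levels = {}
        for muscle in EMG_CHANNELS:
            amp = self.mvc_amp[(row["subject"], muscle)]
            levels[muscle] = {
                phase: max(vals.get(f"emg_{muscle}_{phase}", 0.0), 0.0) / 100.0 * amp
                for phase in PHASES}

        lat = self.reflex_latencies[row["subject"]]
        bursts = {m: [ReflexBurstSpec(p, lat[p], 4.0, cfg.burst_gain)
                      for p in REFLEX_PHASES]
                  for m in ("SOL", "MG")}

        stim_kw = {}
        if row["stim_phase"] != "none":
            factor = max(vals[f"h_{row['stim_phase']}"], 0.0)
            h = cfg.h_base_p2p_mv * factor * float(np.exp(rng.normal(0.0, 0.02)))
            stim_kw = dict(stim_time_ms=lat[row["stim_phase"]],
                           h_p2p_mv=h, m_p2p_mv=cfg.m_p2p_mv)

        emg, truth = generate_emg_trial(
            row["condition"], row["direction"], row["stim_phase"],
            bursts, levels, seed=rng,
            pre_ms=pre_s * 1000.0, post_ms=post_s * 1000.0,
            bmr_end_ms=min(max(peak_idx, 150.0), 480.0), **stim_kw)

        channels = dict(emg)
        channels.update(joints)
        channels["PLATFORM"] = platform
        channels["COP_AP"] = cop
        rates = {name: 1000.0 for name in channels}
        rates["COP_AP"] = 100.0

        meta = dict(row)
        meta["onset_sample"] = int(onset)
        if stim_kw:
            meta["stim_time_ms"] = float(stim_kw["stim_time_ms"])
            meta["true_h_p2p_mv"] = float(stim_kw["h_p2p_mv"])
            meta["true_m_p2p_mv"] = float(stim_kw["m_p2p_mv"])
        return ContinuousRecording(channels=channels, rates=rates,
                                  subject=row["subject"], meta=meta)

    def mvc_trials(self, subject: str) -> dict:
        """Three 3 s MVC recordings per muscle; the first has the largest amplitude."""
        out = {}
        for m, muscle in enumerate(EMG_CHANNELS):
            sub_key = int(sum(subject.encode()))  # stable across interpreter runs
            rng = np.random.default_rng(
                np.random.SeedSequence([self.config.seed, 7919, sub_key, m]))
            amp = self.mvc_amp[(subject, muscle)]
            trials = []
            for scale in (1.0, 0.9, 0.8):
                lv = amp * scale
                ch, _ = generate_emg_trial(
                    "predicted", "posterior", "none", None,
                    {muscle: {p: lv for p in PHASES}},
                    seed=rng, pre_ms=0.0, post_ms=3000.0)
                trials.append(ch[muscle])
            out[muscle] = trials
        return out

    def iter_trial_recordings(self, directions=("posterior",)):
        for _, row in self.trial_table.iterrows():
            if row["direction"] in directions:
                yield self.trial_recording(row)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Build the cohort truth (subject table, bookkeeping, latencies, MVC)."""
    root = np.random.SeedSequence(config.seed)
    subject_table = generate_subject_table(config, root.spawn(1)[0])
    trial_table = trial_bookkeeping(config)

    aux = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    latencies = {}
    mvc_amp = {}
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        lat = {}
        for phase, (mu, sd, lo, hi) in _REFLEX_LATENCY_PRIORS.items():
            lat[phase] = float(np.clip(aux.normal(mu, sd), lo, hi))
        latencies[sid] = lat
        for muscle in EMG_CHANNELS:
            mvc_amp[(sid, muscle)] = float(
                max(aux.normal(config.mvc_mean_amp_mv, config.mvc_amp_sd_mv), 0.05))
    return Cohort(config=config, subject_table=subject_table,
                  trial_table=trial_table, reflex_latencies=latencies,
                  mvc_amp=mvc_amp)
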