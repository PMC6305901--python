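# perturbstance

Analysis pipeline for perturbed-stance neuromechanics experiments, paired
with a synthetic trial generator so that every stage can be verified against
a known ground truth without any recorded data.

The pipeline covers:

- **Synthetic cohorts** (`perturbstance.synth`) — smoothed-trapezoid platform
  displacement traces, band-limited stochastic EMG with phase-specific
  envelopes and reflex bursts, biphasic H-reflex / M-wave insertion, H/M
  recruitment-curve models, and whole cohorts (subjects × conditions ×
  trials) whose subject-level statistics follow configurable per-condition
  effect tables with a Gaussian-copula rank-correlation structure.
- **Segmentation** (`perturbstance.segmentation`, `perturbstance.io`) —
  platform-onset detection with sqrt back-extrapolation refinement and fixed
  600 ms epoching (100 ms pre / 500 ms post onset; EMG and goniometry at
  1 kHz, COP at 100 Hz), plus a self-describing mixed-rate TSV dialect.
- **EMG features** (`perturbstance.emg_features`) — the PRE / SLR / MLR /
  LLR / BMR phase windows, rectified-integrated EMG (iEMG, mV·s),
  time-normalized amplitude (mV), %MVC normalization against the 100 ms
  peak window of the best MVC trial, and reflex-peak latency detection.
- **H-reflexes** (`perturbstance.hreflex`) — recruitment-curve calibration
  to 25 % of M-max on the ascending limb, per-trial H and M peak-to-peak
  extraction, and normalization to the predicted condition.
- **Posturography** (`perturbstance.posturography`) — COP onset / 90 ms /
  120 ms / signed peak excursion / peak latency, and joint-excursion
  summaries.
- **Statistics** (`perturbstance.stats`) — normalization to the predicted
  condition, repeated-measures ANOVA (1–2 within factors) with Mauchly's
  test, Greenhouse-Geisser correction and partial eta squared, Spearman
  correlations (exact permutation p for n ≤ 10), and Benjamini-Yekutieli
  FDR control.

## CLI

All stages are subcommands of one entry point:

```sh
perturbstance synth-cohort --out cohort/ --seed 1
perturbstance segment --in cohort/ --out trials/ --threshold 0.05
perturbstance emg-features --trials trials/ --mvc cohort/ --out features.tsv
perturbstance hreflex --trials trials/ --out hm.tsv
perturbstance kinematics --trials trials/ --out kin.tsv
perturbstance stats --features features.tsv --kin kin.tsv --hm hm.tsv --out report/
```

or end-to-end from one config and one root seed:

```sh
perturbstance run --config run.yaml
```

where `run.yaml` looks like

```yaml
out: runs/demo
seed: 42
cohort:
  n_subjects: 5
  trials_per_phase: 2
  n_anterior: 0
threshold_fraction: 0.05
fdr_q: 0.05
```

A rerun with the same config reproduces byte-identical outputs; the
`manifest.json` in the output directory records stage order and SHA-256
hashes of every produced file.

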