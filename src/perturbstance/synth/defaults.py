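"""Default effect tables for the synthetic cohort generator.

Values are per-condition means and standard deviations of subject-level
quantities: COP summary metrics (cm / ms), joint kinematics (degrees / ms),
phase-windowed EMG activity (%MVC), per-phase H-reflex modulation factors
(relative to the predicted condition) and rank-correlation targets between
subject-level variables.  All of them are plain configuration: the generator
reproduces whatever tables it is given.
"""

# condition order everywhere: predicted, unpredicted, cheated
CONDITIONS = ("predicted", "unpredicted", "cheated")

COP_TABLE = {
    # variable: {condition: (mean, sd)}
    "cop_onset": {"predicted": (-0.7, 0.5), "unpredicted": (-0.1, 0.1), "cheated": (0.7, 0.2)},
    "cop_90": {"predicted": (-1.4, 0.5), "unpredicted": (-1.5, 0.6), "cheated": (-1.1, 0.4)},
    "cop_120": {"predicted": (-2.1, 0.9), "unpredicted": (-2.5, 0.7), "cheated": (-2.5, 0.6)},
    "cop_peak": {"predicted": (-2.5, 0.7), "unpredicted": (-3.1, 0.9), "cheated": (-3.7, 1.1)},
    "cop_peak_index": {"predicted": (230.0, 44.0), "unpredicted": (287.0, 65.0), "cheated": (344.0, 73.0)},
}

JOINT_TABLE = {
    "HIP": {
        "onset": {"predicted": (179.0, 6.7), "unpredicted": (179.1, 5.9), "cheated": (179.5, 4.8)},
        "excursion": {"predicted": (1.2, 0.9), "unpredicted": (4.6, 2.6), "cheated": (6.1, 2.7)},
        "peak_index": {"predicted": (225.0, 95.0), "unpredicted": (278.0, 89.0), "cheated": (346.0, 120.0)},
    },
    "KNEE": {
        "onset": {"predicted": (178.3, 2.9), "unpredicted": (178.6, 3.0), "cheated": (178.9, 3.0)},
        "excursion": {"predicted": (1.5, 1.2), "unpredicted": (4.1, 2.8), "cheated": (5.9, 3.0)},
        "peak_index": {"predicted": (230.0, 109.0), "unpredicted": (268.0, 107.0), "cheated": (290.0, 111.0)},
    },
    "ANKLE": {
        "onset": {"predicted": (96.4, 4.4), "unpredicted": (95.9, 4.5), "cheated": (95.0, 4.2)},
        "excursion": {"predicted": (2.0, 0.5), "unpredicted": (4.7, 2.3), "cheated": (7.1, 2.8)},
        "peak_index": {"predicted": (192.0, 69.0), "unpredicted": (216.0, 77.0), "cheated": (227.0, 85.0)},
    },
}

# %MVC by muscle x phase x condition: (mean, sd)
EMG_TABLE = {
    "SOL": {
        "PRE": {"predicted": (0.18, 0.08), "unpredicted": (0.18, 0.06), "cheated": (0.14, 0.07)},
        "SLR": {"predicted": (0.27, 0.10), "unpredicted": (0.20, 0.09), "cheated": (0.12, 0.06)},
        "MLR": {"predicted": (0.30, 0.12), "unpredicted": (0.35, 0.14), "cheated": (0.21, 0.12)},
        "LLR": {"predicted": (0.41, 0.14), "unpredicted": (0.58, 0.16), "cheated": (0.65, 0.20)},
        "BMR": {"predicted": (0.34, 0.15), "unpredicted": (0.46, 0.19), "cheated": (0.61, 0.17)},
    },
    "MG": {
        "PRE": {"predicted": (0.14, 0.09), "unpredicted": (0.12, 0.09), "cheated": (0.08, 0.04)},
        "SLR": {"predicted": (0.22, 0.08), "unpredicted": (0.19, 0.07), "cheated": (0.12, 0.09)},
        "MLR": {"predicted": (0.25, 0.12), "unpredicted": (0.29, 0.14), "cheated": (0.21, 0.10)},
        "LLR": {"predicted": (0.33, 0.27), "unpredicted": (0.43, 0.25), "cheated": (0.39, 0.21)},
        "BMR": {"predicted": (0.37, 0.23), "unpredicted": (0.45, 0.47), "cheated": (0.51, 0.26)},
    },
    "TA": {
        "PRE": {"predicted": (0.05, 0.04), "unpredicted": (0.12, 0.05), "cheated": (0.31, 0.12)},
        "SLR": {"predicted": (0.07, 0.06), "unpredicted": (0.06, 0.04), "cheated": (0.28, 0.21)},
        "MLR": {"predicted": (0.06, 0.04), "unpredicted": (0.05, 0.03), "cheated": (0.09, 0.08)},
        "LLR": {"predicted": (0.04, 0.03), "unpredicted": (0.07, 0.06), "cheated": (0.04, 0.03)},
        "BMR": {"predicted": (0.06, 0.05), "unpredicted": (0.09, 0.05), "cheated": (0.03, 0.03)},
    },
    "GMAX": {
        "PRE": {"predicted": (0.21, 0.09), "unpredicted": (0.22, 0.08), "cheated": (0.19, 0.11)},
        "SLR": {"predicted": (0.18, 0.07), "unpredicted": (0.20, 0.08), "cheated": (0.18, 0.07)},
        "MLR": {"predicted": (0.23, 0.10), "unpredicted": (0.21, 0.10), "cheated": (0.24, 0.12)},
        "LLR": {"predicted": (0.20, 0.11), "unpredicted": (0.22, 0.09), "cheated": (0.27, 0.11)},
        "BMR": {"predicted": (0.26, 0.13), "unpredicted": (0.31, 0.17), "cheated": (0.40, 0.15)},
    },
    "RF": {
        "PRE": {"predicted": (0.12, 0.07), "unpredicted": (1.04, 0.67), "cheated": (1.00, 0.65)},
        "SLR": {"predicted": (0.13, 0.09), "unpredicted": (1.04, 0.69), "cheated": (1.07, 0.84)},
        "MLR": {"predicted": (0.10, 0.11), "unpredicted": (1.04, 0.68), "cheated": (0.97, 0.66)},
        "LLR": {"predicted": (0.14, 0.07), "unpredicted": (1.02, 0.65), "cheated": (1.06, 0.64)},
        "BMR": {"predicted": (0.17, 0.11), "unpredicted": (0.15, 0.09), "cheated": (0.19, 0.13)},
    },
    "BF": {
        "PRE": {"predicted": (0.12, 0.08), "unpredicted": (0.10, 0.05), "cheated": (0.12, 0.09)},
        "SLR": {"predicted": (0.14, 0.10), "unpredicted": (0.11, 0.07), "cheated": (0.10, 0.10)},
        "MLR": {"predicted": (0.16, 0.09), "unpredicted": (0.18, 0.12), "cheated": (0.15, 0.11)},
        "LLR": {"predicted": (0.20, 0.12), "unpredicted": (0.25, 0.16), "cheated": (0.34, 0.17)},
        "BMR": {"predicted": (0.23, 0.13), "unpredicted": (0.28, 0.12), "cheated": (0.39, 0.19)},
    },
}

# Multiplicative H-reflex modulation relative to the predicted condition:
# suppression in the SLR, facilitation in the LLR from predicted through
# unpredicted to cheated; the MLR facilitated for unpredicted only.
H_MODULATION = {
    "SLR": {"predicted": 1.00, "unpredicted": 0.85, "cheated": 0.70},
    "MLR": {"predicted": 1.00, "unpredicted": 1.15, "cheated": 1.00},
    "LLR": {"predicted": 1.00, "unpredicted": 1.25, "cheated": 1.45},
}

# Rank-correlation targets between subject-level variables, per condition.
# Only a positive-definite-compatible subset is configured by default; EMG
# variables are addressed as emg_<MUSCLE>_<PHASE>, H modulation as h_<PHASE>.
LATENT_CORRELATION = {
    "predicted": {
        ("cop_onset", "cop_peak"): -0.699,
        ("cop_peak", "emg_SOL_PRE"): -0.523,
    },
    "unpredicted": {
        ("cop_peak", "h_MLR"): -0.616,
        ("cop_peak_index", "h_LLR"): -0.717,
    },
    "cheated": {
        ("cop_onset", "cop_peak"): 0.771,
        ("cop_peak", "emg_TA_PRE"): 0.601,
        # factor-model completion: without it the two pairs above are jointly
        # borderline non-PD; this is the product correlation they imply
        ("cop_onset", "emg_TA_PRE"): 0.469,
    },
}
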