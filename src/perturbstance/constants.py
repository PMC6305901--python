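"""Shared channel names, sampling rates and analysis-window constants."""

EMG_CHANNELS = ("SOL", "MG", "TA", "RF", "BF", "GMAX")
JOINT_CHANNELS = ("ANKLE", "KNEE", "HIP")
COP_CHANNEL = "COP_AP"
PLATFORM_CHANNEL = "PLATFORM"

ALL_CHANNELS = EMG_CHANNELS + JOINT_CHANNELS + (COP_CHANNEL, PLATFORM_CHANNEL)

FS_FAST = 1000.0   # Hz: EMG, goniometry, platform potentiometer
FS_COP = 100.0     # Hz: centre-of-pressure trace

# Analysis epoch: 100 ms before to 500 ms after perturbation onset.
EPOCH_PRE_MS = 100.0
EPOCH_POST_MS = 500.0
EPOCH_MS = EPOCH_PRE_MS + EPOCH_POST_MS

# Half-open phase windows [start, end) in ms relative to perturbation onset.
# BMR runs from 120 ms to the trial's own COP peak latency.
PHASE_BOUNDS = {
    "PRE": (-100.0, 0.0),
    "SLR": (30.0, 60.0),
    "MLR": (60.0, 85.0),
    "LLR": (85.0, 120.0),
}
BMR_START_MS = 120.0

PHASES = ("PRE", "SLR", "MLR", "LLR", "BMR")
REFLEX_PHASES = ("SLR", "MLR", "LLR")

CONDITIONS = ("predicted", "unpredicted", "cheated")
DIRECTIONS = ("anterior", "posterior")
STIM_PHASES = ("none", "SLR", "MLR", "LLR")

MUSCLE_GROUPS = {
    "SOL": "shank", "MG": "shank", "TA": "shank",
    "RF": "thigh", "BF": "thigh",
    "GMAX": "hip",
}
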