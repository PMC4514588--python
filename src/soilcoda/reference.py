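"""Published reference statistics for the five-layer forest-soil ^137Cs dataset.

These are the printed summary statistics of a 39-profile survey of forest-soil
^137Cs activity in south-western Poland: per-layer summaries of the relative
activities (closed to 1 over the top five horizons of each profile), the matrix
of pairwise log-ratio variances between layers, and the categorical structure of
the profiles (which genetic horizon occupies each depth-ordered layer, which soil
types occur).  The raw per-profile activities were never deposited, so these
tables serve two purposes here: they calibrate the synthetic profile generator,
and they are sufficient input on their own to reconstruct the full
balance-variance ranking (any zero-sum log-contrast variance is a quadratic form
in the variation matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Depth-ordered layer labels, w1 at the soil surface.
LAYERS: tuple[str, ...] = ("w1", "w2", "w3", "w4", "w5")

#: Soil type codes present in the survey.
SOIL_TYPES: tuple[str, ...] = ("PZ", "CM", "GLm", "PLp", "GLs", "LV", "LC", "RB")

#: Per-layer summary statistics of the relative activities a_r (dimensionless).
#: Rows: minimum, lower quartile, median, arithmetic mean, geometric mean,
#: upper quartile, maximum.
LAYER_STATS = pd.DataFrame(
    {
        "w1": [0.003, 0.026, 0.035, 0.046, 0.034, 0.063, 0.258],
        "w2": [0.113, 0.275, 0.365, 0.420, 0.379, 0.523, 0.971],
        "w3": [0.020, 0.302, 0.449, 0.421, 0.365, 0.516, 0.769],
        "w4": [0.000, 0.011, 0.051, 0.103, 0.031, 0.161, 0.404],
        "w5": [0.000, 0.002, 0.003, 0.010, 0.003, 0.009, 0.120],
    },
    index=["min", "q1", "median", "mean", "gmean", "q3", "max"],
)

#: Geometric means of the relative activities per layer (the "gmean" row above).
#: Not closed to 1; close before using as a compositional center.
GEOMEAN_AR = LAYER_STATS.loc["gmean"].to_numpy()

#: Pairwise log-ratio variances VR[i, j] = var(ln a_i / a_j) between layers,
#: printed to 2 significant figures.  Symmetric, zero diagonal.
VARIATION = pd.DataFrame(
    [
        [0.00, 0.85, 1.20, 5.10, 3.80],
        [0.85, 0.00, 1.10, 6.20, 4.10],
        [1.20, 1.10, 0.00, 5.20, 4.40],
        [5.10, 6.20, 5.20, 0.00, 3.80],
        [3.80, 4.10, 4.40, 3.80, 0.00],
    ],
    index=LAYERS,
    columns=LAYERS,
)

#: Observed frequency (out of 39 profiles) of each genetic horizon name per
#: depth-ordered layer.  w1 and w2 were Ol and Of litter subhorizons in every
#: profile; deeper layers mix organic and mineral horizons.
HORIZON_FREQS: dict[str, dict[str, int]] = {
    "w1": {"Ol": 39},
    "w2": {"Of": 39},
    "w3": {"Oh": 20, "A": 15, "AE": 4},
    "w4": {"A": 17, "Bbr": 15, "Ees": 5, "AE": 2},
    "w5": {"Bbr": 21, "C": 16, "Ees": 2},
}

#: Centre and spread of the total (per-sample) specific activity in Bq/kg:
#: geometric mean of the measured specific activities, and the log-scale
#: standard deviation used by the synthetic generator's lognormal law.
TOTAL_ACTIVITY_GEOMEAN_BQKG = 92.6
TOTAL_ACTIVITY_LOG_SD = 2.3

#: Number of profiles in the survey.
N_PROFILES = 39


def reference_center() -> np.ndarray:
    """Closed compositional center of the survey (closure of the geometric means)."""
    g = GEOMEAN_AR.astype(float)
    return g / g.sum()


def reference_variation() -> np.ndarray:
    """The published variation matrix as a plain (5, 5) float array."""
    return VARIATION.to_numpy(dtype=float)
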