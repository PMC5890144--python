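"""Published summary statistics of the reference cohort.

The synthetic population is parameterised to the reference sample of 31
healthy young adults on which this analysis design was established: TVA
parameter means and SDs for the entire sample and for the median-split
performance groups, the design trial counts, and the acquisition constants
of the resting-state scan.  These are study inputs, not fitted values.
"""

from __future__ import annotations

# entire sample, n = 31: mean, sd
POPULATION = {
    "C": (25.89, 7.34),
    "K": (3.03, 0.47),
    "alpha": (0.52, 0.21),
    "w_lat": (0.49, 0.06),
}
N_SUBJECTS = 31

# median-split group summaries: (mean, sd, n)
GROUPS = {
    "C": {"high": (30.76, 7.05, 16), "low": (20.70, 2.45, 15)},
    "K": {"high": (3.37, 0.41, 16), "low": (2.66, 0.10, 15)},
    "alpha": {"high": (0.34, 0.12, 16), "low": (0.71, 0.10, 15)},
    "w_lat": {"right": (0.45, 0.04, 16), "left": (0.54, 0.03, 15)},
}

MEDIANS = {"C": 24.30, "K": 2.83, "alpha": 0.49, "w_lat": 0.49}

# mean calibrated whole-report exposures, ms (short, middle, long)
CALIBRATED_EXPOSURES_MS = (45.17, 82.23, 164.90)
PARTIAL_EXPOSURE_MS = 91.50

# resting-state acquisition
N_VOLUMES = 250
TR_SECONDS = 2.608

# multiple-testing constants
N_NETWORKS = 6
N_INTERNETWORK_TESTS = 5
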