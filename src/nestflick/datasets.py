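"""Bundled reference numbers from the two-colony field study this package models.

Two Giant Honey Bee nests were filmed before (preP), during (P) and after
(postP) arousal by a dummy wasp.  The original video footage is not
publicly available, so only the published summary statistics are bundled
here: per-phase wave and trigger-site counts, relF occupancy fractions,
grid geometry, exponential rate-intensity fit coefficients and arousal
means.  They serve as worked-example inputs for the arithmetic the package
automates (trigger pooling totals, grid extents, relF additivity,
fold-change summaries); they are *data*, not values the pipeline computes.
"""

from __future__ import annotations

import pandas as pd

#: Grid geometry of the two experimental nests: (cols, rows) test squares,
#: pixels were aggregated into 1.5 cm squares; frame rates of the recordings.
NEST_GRIDS = {
    "expN1": {"cols": 123, "rows": 53, "fps": 25.0, "unit_len_cm": 1.5},
    "expN2": {"cols": 73, "rows": 48, "fps": 50.0, "unit_len_cm": 1.5},
}


def phase_summary() -> pd.DataFrame:
    """Per-phase wave counts, trigger-site counts and relF occupancy.

    ``n_waves`` counts parental shimmering waves evaluated in the phase and
    ``n_ts`` the pooled trigger events; ``relf_*`` are fractions of nest
    squares that were flickering-active (total = ts + nts cohorts).
    """
    rows = [
        ("expN1", "preP",      36, 322, 0.40, 0.18, 0.22),
        ("expN1", "P1+postP1", 26, 325, 0.86, 0.28, 0.58),
        ("expN1", "P2+postP2", 13, 258, 0.88, 0.33, 0.55),
        ("expN2", "preP",      11,  61, 0.34, 0.08, 0.26),
        ("expN2", "P1+postP1", 27, 276, 0.24, 0.13, 0.11),
        ("expN2", "P2+postP2", 17, 211, 0.73, 0.26, 0.47),
    ]
    return pd.DataFrame(rows, columns=["nest", "phase", "n_waves", "n_ts",
                                       "relf_total", "relf_ts", "relf_nts"])


#: Published totals of the phase summary (all phases, both nests).
TOTAL_TRIGGER_EVENTS = 1453
TOTAL_PARENTAL_WAVES = 130

#: Exponential rate-intensity fits (y = a * exp(b * x)) of the quiescent
#: (preP) phase class means, per nest and cohort.
PREP_EXP_FITS = {
    ("expN1", "ts"):  {"a": 0.037,  "b": 15.457, "r_squared": 0.98},
    ("expN1", "nts"): {"a": 0.0325, "b": 14.583, "r_squared": 0.97},
    ("expN2", "ts"):  {"a": 0.2485, "b": 5.2793, "r_squared": 0.94},
    ("expN2", "nts"): {"a": 0.2501, "b": 3.8059, "r_squared": 0.80},
}

#: Mean flickering levels of expN2 cohorts before/after its third arousal
#: session, used for the reported ~3-fold (ts) and ~2-fold (nts) increases.
AROUSAL_MEANS = {
    "ts":  {"before": 0.64, "after": 1.96},
    "nts": {"before": 1.21, "after": 2.18},
}
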