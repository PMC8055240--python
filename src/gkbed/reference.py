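"""Published reference cohort for validating the cohort statistics.

Per-case sequencing results of a published 15-case vestibular schwannoma
Gamma Knife series (prescriptions 12 Gy, 6 cases; 13 Gy, 9 cases): total
treatment time, iso-centre count, and the shell-mean BED of the original,
BED-minimising and BED-maximising delivery sequences.  The BED values
derive from clinical dose exports that are not redistributable, so only
these printed summary values are carried; they exercise the cohort
statistics (group averages, spreads, achievable ranges, paired t-tests)
independently of the BED engine.
"""

from __future__ import annotations

from .sequence import CohortRow

__all__ = ["reference_cohort"]

# case, dose (Gy), T (min), iso-centres, BED_orig, BED_min, BED_max (Gy_2.47)
_ROWS = [
    ("01", 12.0, 20.80, 13, 61.95, 60.67, 63.33),
    ("02", 12.0, 24.07, 8, 61.62, 60.63, 62.88),
    ("03", 12.0, 39.06, 17, 58.44, 55.24, 60.39),
    ("04", 12.0, 41.00, 14, 57.07, 54.80, 59.04),
    ("05", 12.0, 59.32, 19, 57.04, 50.54, 56.77),
    ("06", 12.0, 72.05, 19, 51.87, 50.05, 55.07),
    ("07", 13.0, 22.37, 9, 71.37, 70.22, 72.47),
    ("08", 13.0, 22.44, 4, 71.70, 71.43, 71.29),
    ("09", 13.0, 30.17, 7, 67.98, 66.32, 69.83),
    ("10", 13.0, 31.84, 15, 68.27, 65.16, 71.18),
    ("11", 13.0, 35.22, 13, 69.84, 63.10, 71.97),
    ("12", 13.0, 46.95, 11, 68.02, 63.57, 68.50),
    ("13", 13.0, 48.32, 12, 66.78, 64.53, 69.43),
    ("14", 13.0, 55.25, 13, 65.57, 63.03, 67.55),
    ("15", 13.0, 73.68, 17, 61.83, 55.64, 64.42),
]


def reference_cohort() -> list[CohortRow]:
    """The reference cohort as :class:`~gkbed.sequence.CohortRow` objects."""
    return [
        CohortRow(
            case_id=case,
            prescription=dose,
            total_time=t,
            n_shots=n,
            bed_orig=orig,
            bed_min=lo,
            bed_max=hi,
        )
        for case, dose, t, n, orig, lo, hi in _ROWS
    ]
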