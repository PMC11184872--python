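"""Reported clinical reference values for the cohort this package emulates.

The clinical study behind these numbers analysed 8 intracranial proton
therapy cases (2 toxicity index cases, 6 controls) whose plans and delivery
logs were not deposited; the values below are the printed summary data.
They parameterize the synthetic cohort defaults and serve as inputs to
reporting — they are not recomputed by this package.
"""

from __future__ import annotations

#: Near-maximum constant-RBE dose (D2, Gy_RBE) of the optic apparatus for
#: the two toxicity index cases, as clinically reported.
REPORTED_INDEX_D2_GYRBE: dict[str, float] = {
    "T4-03": 51.05,
    "T3-06": 48.95,
}

#: Reported plan-level near-maximum dose rate (MDR2, Gy_RBE/s) for the two
#: index cases; control cases ranged between about 1 and 3.2 Gy_RBE/s.
REPORTED_INDEX_MDR2_GYRBES: dict[str, float] = {
    "T4-03": 3.9,
    "T3-06": 4.3,
}
REPORTED_CONTROL_MDR2_RANGE_GYRBES: tuple[float, float] = (1.0, 3.2)

#: Dry-run spot-duration reproducibility over repeated uninterrupted
#: deliveries: relative variation 0.1 +/- 0.9 percent.
REPORTED_DURATION_VARIATION_PCT: tuple[float, float] = (0.1, 0.9)


def mean_index_d2() -> float:
    """Arithmetic mean of the reported index-case D2 values (Gy_RBE)."""
    vals = list(REPORTED_INDEX_D2_GYRBE.values())
    return sum(vals) / len(vals)
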