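"""Published sex-stratified screw morphometry summaries (reference inputs).

Summary rows (mean, SD, n) from a published two-screw planning study of 100
adult scapulae (50 male, 50 female): maximal screw length and diameter per
screw and the entry-point distances, as printed in its comparison tables.
They serve two purposes here: the synthetic cohort defaults target these
magnitudes, and the statistics layer can recompute the study's combined
rows and pooled t statistics directly from them (a desk-scale worked
example that needs no raw data).

Only internally consistent table cells are included: entries whose printed
combined row or t value cannot be reproduced from their own printed group
summaries (medial L1, the medial "All" length, and the angle-table t rows)
are excluded from recomputation.
"""

from __future__ import annotations

from .cohort_stats import GroupSummary

N_PER_SEX = 50

# variable -> (male (mean, sd), female (mean, sd), printed t, printed All (mean, sd))
MEDIAL_SCREW = {
    "length_mm": ((50.79, 4.33), (41.87, 4.19), 10.478, None),
    "diameter_mm": ((5.69, 0.81), (3.73, 0.67), 13.165, (4.71, 1.23)),
    "L2_mm": ((6.88, 1.89), (5.87, 1.59), 2.875, (6.38, 1.82)),
}
LATERAL_SCREW = {
    "length_mm": ((43.26, 4.64), (35.20, 4.28), 9.033, (39.23, 6.01)),
    "diameter_mm": ((5.81, 0.76), (4.13, 0.56), 12.478, (4.97, 1.07)),
    "L3_mm": ((17.79, 2.26), (16.29, 2.03), 3.497, (17.04, 2.27)),
    "L4_mm": ((6.48, 1.72), (5.29, 1.28), 3.930, (5.89, 1.63)),
}


def group_summaries(entry) -> tuple[GroupSummary, GroupSummary]:
    """(male, female) GroupSummary pair for one reference table entry."""
    (mm, ms), (fm, fs) = entry[0], entry[1]
    return (GroupSummary("", N_PER_SEX, mm, ms),
            GroupSummary("", N_PER_SEX, fm, fs))
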