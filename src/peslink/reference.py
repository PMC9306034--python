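"""Published reference aggregates of the study this pipeline replicates.

The individual-level datasets behind the 2013 Hong Kong inpatient
experience-survey linkage study are confidential, but its published
aggregate counts are reproducible inputs: the linkage partition of the
2811 survey respondents aged 45+, and the descriptive table of the 1746
uniquely matched patients with their next-calendar-month readmission
counts by admission source. They anchor the package's worked examples and
validation checks; none of these numbers is used in any shipped
computation path.
"""

from __future__ import annotations

import pandas as pd

#: Linkage partition of the 2811 age-eligible survey respondents.
LINKAGE_COUNTS = {"unique": 1746, "one_to_many": 996, "unmatched": 69}

SURVEY_TOTAL = 3566          # all survey respondents
SURVEY_AGE_ELIGIBLE = 2811   # aged 45 or above

#: Next-calendar-month readmissions among the uniquely matched patients.
READMITTED_ANY = 416
MATCHED_TOTAL = 1746

#: Descriptive table of matched patients: per level, the level size and the
#: readmission counts through any department / A&E / outpatient referral.
#: Source categories overlap (a patient can enter through both routes).
DESCRIPTIVE_ROWS = [
    # variable, level, n, any, ae, opd
    ("sex", "male", 919, 230, 88, 159),
    ("sex", "female", 827, 186, 57, 132),
    ("age_group", "45-54", 368, 84, 15, 70),
    ("age_group", "55-64", 504, 129, 37, 100),
    ("age_group", "65-74", 382, 79, 28, 56),
    ("age_group", "75+", 492, 124, 65, 65),
    ("los_group", "1-3", 877, 164, 53, 116),
    ("los_group", "4-7", 479, 130, 42, 95),
    ("los_group", "8+", 390, 122, 50, 80),
    ("cssa", False, 1525, 357, 119, 256),
    ("cssa", True, 221, 59, 26, 35),
    ("specialty_group", "Medicine", 661, 174, 74, 113),
    ("specialty_group", "Surgery", 421, 105, 34, 74),
    ("specialty_group", "Oncology", 85, 55, 8, 47),
    ("specialty_group", "Others", 579, 82, 29, 57),
    ("quality_high", True, 1353, 331, 107, 243),
    ("quality_high", False, 393, 85, 38, 48),
    ("experience_high", True, 1303, 316, 105, 230),
    ("experience_high", False, 443, 100, 40, 61),
]


def descriptive_table() -> pd.DataFrame:
    return pd.DataFrame(
        DESCRIPTIVE_ROWS,
        columns=["variable", "level", "n", "any", "ae", "opd"])


def two_by_two(variable: str, exposed_level, outcome: str = "any"
               ) -> tuple[int, int, int, int]:
    """Collapse a binary descriptive variable into 2x2 cells
    (exposed-event, exposed-nonevent, unexposed-event, unexposed-nonevent)."""
    df = descriptive_table()
    sub = df[df["variable"] == variable]
    if len(sub) != 2:
        raise ValueError(f"{variable!r} is not binary in the descriptive table")
    exp = sub[sub["level"] == exposed_level].iloc[0]
    unexp = sub[sub["level"] != exposed_level].iloc[0]
    return (int(exp[outcome]), int(exp["n"] - exp[outcome]),
            int(unexp[outcome]), int(unexp["n"] - unexp[outcome]))


def specialty_pooled_two_by_two(outcome: str = "any") -> tuple[int, int, int, int]:
    """Medicine + Surgery + Oncology pooled against the Others specialty."""
    df = descriptive_table()
    sub = df[df["variable"] == "specialty_group"].set_index("level")
    pooled = sub.loc[["Medicine", "Surgery", "Oncology"]].sum()
    others = sub.loc["Others"]
    return (int(pooled[outcome]), int(pooled["n"] - pooled[outcome]),
            int(others[outcome]), int(others["n"] - others[outcome]))


def los_by_readmission_counts(outcome: str = "any") -> list[list[int]]:
    """The 3x2 LOS-band by readmission-status count table."""
    df = descriptive_table()
    sub = df[df["variable"] == "los_group"]
    return [[int(r[outcome]), int(r["n"] - r[outcome])]
            for _, r in sub.iterrows()]


def expand_binary_rows(variable: str, outcome: str = "any") -> pd.DataFrame:
    """Patient-level expansion of one descriptive variable (exposure 0/1
    indicator plus outcome 0/1), for logistic-vs-crude-OR checks."""
    df = descriptive_table()
    sub = df[df["variable"] == variable]
    rows = []
    for _, r in sub.iterrows():
        exposed = bool(r["level"]) if isinstance(r["level"], (bool,)) else r["level"]
        events = int(r[outcome])
        rows.extend([{"level": exposed, "event": 1}] * events)
        rows.extend([{"level": exposed, "event": 0}] * (int(r["n"]) - events))
    return pd.DataFrame(rows)
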