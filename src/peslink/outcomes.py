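"""Readmission outcome construction for uniquely linked patients.

The primary outcome is whether a linked patient had any admission in the
calendar month following the *discharge* month of the index admission (the
survey samples discharges; month granularity is all the data carry, so
28/30-day definitions are out of reach by design). Outcomes are further
classified by admission source: accident & emergency (unplanned) and
outpatient referral (planned). The flags overlap — a patient admitted once
through each route in the window sets both — and sources beyond those two
count toward the any-department flag only.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .config import SPECIALTY_GROUPS
from .errors import DataIntegrityError, ValidationError
from .months import next_calendar_month, parse_month  # noqa: F401  (re-export)

AGE_GROUPS = ("45-54", "55-64", "65-74", "75+")
LOS_GROUPS = ("1-3", "4-7", "8+")


def age_group(age: int) -> str:
    """Bin an age (>= 45) into the analysis age bands."""
    if age < 45:
        raise ValidationError(f"age {age} below the analysis population (45+)")
    if age <= 54:
        return "45-54"
    if age <= 64:
        return "55-64"
    if age <= 74:
        return "65-74"
    return "75+"


def los_group(los: int) -> str:
    """Bin a length of stay into 1-3 / 4-7 / 8+ days (disjoint bins)."""
    if los < 1:
        raise ValidationError(f"length of stay {los} below one night")
    if los <= 3:
        return "1-3"
    if los <= 7:
        return "4-7"
    return "8+"


def specialty_group(code: str,
                    mapping: Mapping[str, str] | None = None) -> str:
    mapping = mapping or SPECIALTY_GROUPS
    try:
        return mapping[code]
    except KeyError:
        raise ValidationError(
            f"specialty code {code!r} missing from the group dictionary") from None


def flag_readmissions(linked: pd.DataFrame,
                      full_admissions: pd.DataFrame) -> pd.DataFrame:
    """Attach the three patient-level readmission flags to linked rows.

    ``linked`` must carry ``pseudo_id``, ``discharge_month`` (of the index
    episode) and ``admission_row`` (the index episode's row label in
    ``full_admissions``, excluded from its own outcome scan).
    ``full_admissions`` must be the *unfiltered* episode table so that
    admissions in the month after the linkage window remain visible.

    Multiple readmissions in the window count once per flag.
    """
    by_patient: dict[str, list[tuple[int, str, str]]] = {}
    for row_label, row in full_admissions[[
            "pseudo_id", "admission_month", "admission_source"]].iterrows():
        by_patient.setdefault(str(row["pseudo_id"]), []).append(
            (row_label, row["admission_month"], row["admission_source"]))

    out = linked.copy()
    flags_any, flags_ae, flags_opd = [], [], []
    for row in linked.itertuples(index=False):
        pid = str(row.pseudo_id)
        if pid not in by_patient:
            raise DataIntegrityError(
                f"linked patient {pid!r} has no episodes in the admissions table")
        target = next_calendar_month(row.discharge_month)
        window = [(lbl, src) for lbl, month, src in by_patient[pid]
                  if month == target and lbl != row.admission_row]
        flags_any.append(bool(window))
        flags_ae.append(any(src == "ae" for _, src in window))
        flags_opd.append(any(src == "outpatient" for _, src in window))
    out["readmit_any"] = flags_any
    out["readmit_ae"] = flags_ae
    out["readmit_opd"] = flags_opd
    return out


def derive_covariates(linked: pd.DataFrame,
                      specialty_groups: Mapping[str, str] | None = None,
                      experience_cut: int = 8) -> pd.DataFrame:
    """Fill the grouped model covariates and the two dichotomized exposures.

    Quality of care is split top-two levels ("good" or better) against the
    rest; the 0-10 experience score at ``experience_cut`` (>= cut is high),
    the published median of 8 by default.
    """
    out = linked.copy()
    out["age_group"] = out["age"].map(age_group)
    out["los_group"] = out["length_of_stay"].map(los_group)
    out["specialty_group"] = out["discharge_specialty"].map(
        lambda c: specialty_group(c, specialty_groups))
    out["quality_high"] = out["quality_rating"] >= 4
    out["experience_high"] = out["experience_score"] >= experience_cut
    return out


def build_analysis_table(pairs: pd.DataFrame, survey: pd.DataFrame,
                         full_admissions: pd.DataFrame,
                         specialty_groups: Mapping[str, str] | None = None,
                         ) -> pd.DataFrame:
    """Assemble one analysis row per uniquely linked patient.

    Joins the survey responses and the index episode (including the CSSA
    welfare flag from the admissions side) onto the linkage pairs, then
    derives covariate groups and readmission flags.
    """
    idx_cols = ["cssa_flag"] if "cssa_flag" in full_admissions.columns else []
    episode = full_admissions.loc[pairs["admission_row"], idx_cols].reset_index(drop=True)
    merged = pairs.merge(survey, on="survey_id", how="left", validate="1:1")
    if merged["age"].isna().any():
        raise DataIntegrityError("linkage pairs reference survey ids absent "
                                 "from the survey table")
    merged = pd.concat([merged.reset_index(drop=True), episode], axis=1)
    merged["cssa"] = merged.get("cssa_flag", 0).astype(bool) \
        if idx_cols else False
    merged = flag_readmissions(merged, full_admissions)
    return derive_covariates(merged, specialty_groups)
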