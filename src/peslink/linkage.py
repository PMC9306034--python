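"""Deterministic exact-match record linkage on the ten-identifier key.

For each survey row the candidate set is every admission row equal on
**all** key fields (exact equality after standardization — no fuzzy
tolerance on age or length of stay). Exactly one candidate makes a unique
(1:1) pair; several make a one-to-many (1:M) survey row; none leaves the
row unmatched. Only unique pairs proceed to outcome analysis.

One extra rule the survey-side classification cannot express: if a single
admission episode is the unique candidate of two or more survey rows, one
person would have to be several respondents, so all involved survey rows
are demoted to one-to-many. Demotions are recorded separately so their
effect is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import KEY_FIELDS
from .errors import ConfigurationError


@dataclass
class LinkageResult:
    """Exhaustive partition of the survey input into unique / 1:M / unmatched.

    ``unique_pairs`` has columns ``survey_id``, ``admission_row`` (index
    label into the candidate table) and ``pseudo_id``.
    """

    unique_pairs: pd.DataFrame
    one_to_many_ids: list[str]
    unmatched_ids: list[str]
    n_survey: int
    demoted_ids: list[str] = field(default_factory=list)

    @property
    def matching_rate(self) -> float:
        return len(self.unique_pairs) / self.n_survey if self.n_survey else 0.0

    def check_partition(self) -> None:
        """Assert the three id sets are disjoint and exhaustive."""
        u = set(self.unique_pairs["survey_id"])
        m, n = set(self.one_to_many_ids), set(self.unmatched_ids)
        assert len(u) + len(m) + len(n) == self.n_survey
        assert not (u & m or u & n or m & n)


def link_deterministic(survey: pd.DataFrame, admission_candidates: pd.DataFrame,
                       key_fields: Sequence[str] = KEY_FIELDS) -> LinkageResult:
    """Link survey rows to admission candidates by composite-key equality.

    The output is invariant to the row order of either table.
    """
    key_fields = list(key_fields)
    for frame, label in ((survey, "survey"), (admission_candidates, "admissions")):
        missing = [c for c in key_fields if c not in frame.columns]
        if missing:
            raise ConfigurationError(
                f"key_fields not present in the {label} table: {missing}")

    if len(admission_candidates) == 0 or len(survey) == 0:
        return LinkageResult(
            unique_pairs=pd.DataFrame(
                columns=["survey_id", "admission_row", "pseudo_id"]),
            one_to_many_ids=[],
            unmatched_ids=sorted(survey["survey_id"].astype(str)),
            n_survey=len(survey),
        )

    adm = admission_candidates.copy()
    adm["admission_row"] = adm.index  # row label in the (full) admissions table
    merged = survey[["survey_id", *key_fields]].merge(
        adm[["admission_row", "pseudo_id", *key_fields]],
        on=key_fields, how="left")
    counts = merged.groupby("survey_id", sort=False)["admission_row"].count()

    unmatched = sorted(counts.index[counts == 0].astype(str))
    one_to_many = set(counts.index[counts > 1].astype(str))
    unique_ids = counts.index[counts == 1]
    pairs = merged[merged["survey_id"].isin(unique_ids)][
        ["survey_id", "admission_row", "pseudo_id"]].copy()
    pairs["admission_row"] = pairs["admission_row"].astype(int)

    # reverse multiplicity: an episode claimed uniquely by several survey rows
    claim_counts = pairs.groupby("admission_row")["survey_id"].transform("size")
    demoted = sorted(pairs.loc[claim_counts > 1, "survey_id"].astype(str))
    one_to_many |= set(demoted)
    pairs = pairs[claim_counts == 1]

    pairs = pairs.sort_values("survey_id").reset_index(drop=True)
    return LinkageResult(
        unique_pairs=pairs,
        one_to_many_ids=sorted(one_to_many),
        unmatched_ids=unmatched,
        n_survey=len(survey),
        demoted_ids=demoted,
    )


def matching_report_from_counts(n_unique: int, n_one_to_many: int,
                                n_unmatched: int, n_demoted: int = 0) -> dict:
    """Linkage summary from partition counts alone.

    One-to-many and unmatched shares are expressed both of the whole survey
    input and of the non-unique subset; empty denominators report ``None``
    rather than raising.
    """
    n = n_unique + n_one_to_many + n_unmatched
    n_non = n_one_to_many + n_unmatched
    pct = lambda a, b: round(100.0 * a / b, 1) if b else None  # noqa: E731
    return {
        "n_survey": n,
        "n_unique": n_unique,
        "n_one_to_many": n_one_to_many,
        "n_unmatched": n_unmatched,
        "n_demoted": n_demoted,
        "matching_rate_pct": pct(n_unique, n),
        "one_to_many_pct_of_total": pct(n_one_to_many, n),
        "unmatched_pct_of_total": pct(n_unmatched, n),
        "one_to_many_pct_of_non_unique": pct(n_one_to_many, n_non),
        "unmatched_pct_of_non_unique": pct(n_unmatched, n_non),
    }


def matching_report(result: LinkageResult) -> dict:
    """Counts and percentages of the linkage partition (see
    :func:`matching_report_from_counts`)."""
    return matching_report_from_counts(
        len(result.unique_pairs), len(result.one_to_many_ids),
        len(result.unmatched_ids), len(result.demoted_ids))
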