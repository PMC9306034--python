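"""Cleaning, standardization and eligibility filtering of the two tables.

Deterministic exact-key linkage is only as good as the canonical form of
the key, so everything funnels through :func:`standardize` first: category
text is trimmed and lower-cased, calendar months are coerced to ``YYYY-MM``
(several input dialects accepted), and age / length-of-stay become
integers. Rows that cannot be canonicalized are counted and reported —
never silently dropped — and excluded from linkage, because an incomplete
key can never match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import GeneratorConfig, SEXES, SOURCES, SPECIALTIES
from .errors import ConfigurationError, ValidationError
from .months import parse_month

MONTH_FIELDS = ("admission_month", "discharge_month")
INTEGER_FIELDS = ("age", "length_of_stay")


@dataclass
class KeySpec:
    """Declared vocabularies of the categorical identifier fields."""

    sexes: frozenset = frozenset(SEXES)
    sources: frozenset = frozenset(SOURCES)
    districts: frozenset = frozenset(GeneratorConfig().districts)
    hospitals: frozenset = frozenset(GeneratorConfig().hospitals)
    specialties: frozenset = frozenset(SPECIALTIES)

    def vocabulary(self, column: str) -> frozenset | None:
        return {
            "sex": self.sexes,
            "admission_source": self.sources,
            "residence_district": self.districts,
            "discharge_hospital": self.hospitals,
            "admission_specialty": self.specialties,
            "discharge_specialty": self.specialties,
        }.get(column)

    @classmethod
    def from_generator(cls, cfg: GeneratorConfig) -> "KeySpec":
        return cls(districts=frozenset(cfg.districts),
                   hospitals=frozenset(cfg.hospitals),
                   specialties=frozenset(cfg.specialty_vocabulary))


@dataclass
class CleaningReport:
    """Audit of one standardization pass: kept + dropped = input, always."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    issues: list[dict] = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "n_dropped": self.n_dropped, "issues": list(self.issues)}


@dataclass
class FilterReport:
    name: str
    n_input: int
    n_kept: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept

    def as_dict(self) -> dict:
        return {"filter": self.name, "n_input": self.n_input,
                "n_kept": self.n_kept, "n_dropped": self.n_dropped}


def standardize(records: pd.DataFrame, key_spec: KeySpec | None = None,
                strict: bool = False,
                extra_category_fields: Mapping[str, Iterable[str]] | None = None,
                ) -> tuple[pd.DataFrame, CleaningReport]:
    """Canonicalize a raw table; idempotent on its own output.

    Returns the cleaned table (invalid rows excluded) and a
    :class:`CleaningReport` listing every offending row and field. With
    ``strict=True`` the first invalid value raises
    :class:`ValidationError` instead.
    """
    key_spec = key_spec or KeySpec()
    df = records.copy()
    report = CleaningReport(n_input=len(df))
    bad: dict[int, list[str]] = {}

    def flag(i, column, value, reason):
        if strict:
            raise ValidationError(
                f"row {i}, field {column!r}: {reason} ({value!r})")
        report.issues.append({"row": int(i), "field": column,
                              "value": None if value is None else str(value),
                              "reason": reason})
        bad.setdefault(i, []).append(column)

    category_vocab: dict[str, frozenset | None] = {}
    for col in df.columns:
        vocab = key_spec.vocabulary(col)
        if vocab is not None:
            category_vocab[col] = vocab
    if extra_category_fields:
        for col, vocab in extra_category_fields.items():
            category_vocab[col] = frozenset(vocab)

    for col, vocab in category_vocab.items():
        cleaned = df[col].astype(str).str.strip().str.lower()
        df[col] = cleaned
        for i in df.index[~cleaned.isin(vocab)]:
            flag(i, col, records.loc[i, col], "value outside declared vocabulary")

    for col in MONTH_FIELDS:
        if col not in df.columns:
            continue
        out = []
        for i, value in df[col].items():
            try:
                out.append(parse_month(value))
            except ValidationError:
                flag(i, col, value, "unparseable calendar month")
                out.append(None)
        df[col] = out

    for col in INTEGER_FIELDS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        whole = coerced.notna() & (coerced == coerced.round())
        for i in df.index[~whole]:
            flag(i, col, records.loc[i, col], "not an integer")
        df[col] = coerced.where(whole).astype("Int64")

    if {"admission_month", "discharge_month"} <= set(df.columns):
        both = df["admission_month"].notna() & df["discharge_month"].notna()
        backwards = both & (df["discharge_month"] < df["admission_month"])
        for i in df.index[backwards]:
            flag(i, "discharge_month", df.loc[i, "discharge_month"],
                 "discharge month precedes admission month")
    if "length_of_stay" in df.columns:
        neg = df["length_of_stay"].notna() & (df["length_of_stay"] < 1)
        for i in df.index[neg]:
            flag(i, "length_of_stay", records.loc[i, "length_of_stay"],
                 "length of stay below one night")

    keep = df.index[~df.index.isin(bad)]
    cleaned = df.loc[keep].copy()
    for col in INTEGER_FIELDS:
        if col in cleaned.columns:
            cleaned[col] = cleaned[col].astype(int)
    report.n_kept = len(cleaned)
    report.n_dropped = report.n_input - report.n_kept
    return cleaned.reset_index(drop=True), report


def filter_survey_eligible(survey: pd.DataFrame, min_age: int = 45
                           ) -> tuple[pd.DataFrame, FilterReport]:
    """Keep survey respondents aged ``min_age`` or above (inclusive)."""
    kept = survey[survey["age"] >= min_age]
    return kept, FilterReport("survey_age", len(survey), len(kept))


def filter_admission_candidates(admissions: pd.DataFrame,
                                window: tuple[str, str],
                                hospitals: Sequence[str] | None = None,
                                min_age: int = 45,
                                require_home: bool = True,
                                ) -> tuple[pd.DataFrame, FilterReport]:
    """Restrict admissions to the linkable candidate subset.

    Keeps episodes discharged home inside the closed month ``window``, at a
    study hospital, among patients aged ``min_age``+. The caller must
    retain the *full* table separately: readmissions in the month after the
    window close must stay findable for outcome construction.

    ``hospitals=None`` means every hospital present in the data;
    an explicitly empty hospital set is a configuration error.
    """
    if hospitals is not None and len(hospitals) == 0:
        raise ConfigurationError("hospitals: the study hospital set is empty")
    start, end = parse_month(window[0]), parse_month(window[1])
    mask = (admissions["discharge_month"] >= start) \
        & (admissions["discharge_month"] <= end) \
        & (admissions["age"] >= min_age)
    if hospitals is not None:
        mask &= admissions["discharge_hospital"].isin(set(hospitals))
    if require_home:
        if "discharge_destination" in admissions.columns:
            mask &= admissions["discharge_destination"] == "home"
        # tables lacking a destination column cannot apply the discharged-home
        # rule; the count report makes the omission visible
    # row labels are preserved: filters are pure row subsets, and downstream
    # outcome lookup addresses index episodes by their full-table label
    kept = admissions[mask]
    return kept, FilterReport("admission_candidates", len(admissions), len(kept))
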