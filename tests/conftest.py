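"""Shared fixtures: a study-scale cohort, a small cohort for quadratic
oracles, and a derandomised hypothesis profile."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from peslink import linkage, outcomes, synthetic
from peslink.config import GeneratorConfig
from peslink.preprocess import (filter_admission_candidates,
                                filter_survey_eligible)

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

LINKAGE_WINDOW = ("2013-10", "2013-12")


def build_cohort(cfg: GeneratorConfig) -> SimpleNamespace:
    """Generate a cohort and run it through linkage + outcome construction."""
    patients = synthetic.generate_population(cfg)
    survey = synthetic.emit_survey(patients, cfg)
    admissions = synthetic.emit_admissions(patients, cfg)
    survey45, _ = filter_survey_eligible(survey)
    candidates, _ = filter_admission_candidates(admissions, LINKAGE_WINDOW, None)
    result = linkage.link_deterministic(survey45, candidates)
    analysis = outcomes.build_analysis_table(result.unique_pairs, survey45,
                                             admissions)
    return SimpleNamespace(cfg=cfg, patients=patients, survey=survey,
                           admissions=admissions, survey45=survey45,
                           candidates=candidates, result=result,
                           analysis=analysis)


@pytest.fixture(scope="session")
def cohort10k() -> SimpleNamespace:
    """Study-scale cohort at the generator defaults (n = 10 000 patients)."""
    return build_cohort(GeneratorConfig(n_patients=10_000, seed=1729))


@pytest.fixture(scope="session")
def small_cohort() -> SimpleNamespace:
    """A cohort whose age-eligible survey stays below 200 rows, small enough
    for quadratic brute-force comparison."""
    cfg = GeneratorConfig(n_patients=400, seed=99, survey_sampling_fraction=0.6)
    return build_cohort(cfg)


def quadratic_link(survey: pd.DataFrame, admissions: pd.DataFrame,
                   key_fields) -> dict:
    """Brute-force linkage oracle: per survey row, compare every admission
    row field by field; then apply the same reverse-multiplicity demotion
    rule as the production matcher. Independent of the hash-join path."""
    key_fields = list(key_fields)
    adm_keys = admissions[key_fields]
    unique, one_to_many, unmatched = {}, set(), set()
    for _, srow in survey.iterrows():
        mask = np.ones(len(admissions), dtype=bool)
        for f in key_fields:
            mask &= (adm_keys[f] == srow[f]).to_numpy()
        hits = list(admissions.index[mask])
        sid = str(srow["survey_id"])
        if len(hits) == 0:
            unmatched.add(sid)
        elif len(hits) == 1:
            unique[sid] = hits[0]
        else:
            one_to_many.add(sid)
    claimed: dict = {}
    for sid, row_label in unique.items():
        claimed.setdefault(row_label, []).append(sid)
    for row_label, sids in claimed.items():
        if len(sids) > 1:
            for sid in sids:
                del unique[sid]
                one_to_many.add(sid)
    return {"unique": unique, "one_to_many": one_to_many,
            "unmatched": unmatched}
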