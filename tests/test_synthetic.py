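"""Generator contracts: validation, determinism, conservation, anonymity,
and the key-collision / cohort-summary calibration of the defaults."""

import numpy as np
import pandas as pd
import pytest

from peslink import synthetic
from peslink.config import GeneratorConfig, KEY_FIELDS
from peslink.errors import ConfigurationError, OracleLookupError
from peslink.synthetic import (ADMISSION_COLUMNS, Episode, LatentPatient,
                               SURVEY_COLUMNS)


@pytest.mark.parametrize("patch, field", [
    ({"n_patients": 0}, "n_patients"),
    ({"n_patients": -5}, "n_patients"),
    ({"survey_sampling_fraction": 1.5}, "survey_sampling_fraction"),
    ({"cssa_prevalence": -0.1}, "cssa_prevalence"),
    ({"study_months": ("2013-12", "2013-10", "2013-11", "2014-01")},
     "study_months"),
    ({"study_months": ("2013-10", "2013-13")}, "study_months"),
], ids=["empty-population", "negative-population", "fraction-above-one",
        "negative-prevalence", "unsorted-months", "invalid-month"])
def test_invalid_config_names_offending_field(patch, field):
    cfg = GeneratorConfig(**patch)
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        synthetic.generate_population(cfg)


def test_missing_outcome_coefficient_rejected():
    cfg = GeneratorConfig()
    del cfg.outcome_coefficients["opd"]["oncology"]
    with pytest.raises(ConfigurationError, match="oncology"):
        cfg.validate()


def test_same_seed_gives_byte_identical_tables(tmp_path):
    outputs = []
    for run in range(2):
        cfg = GeneratorConfig(n_patients=300, seed=42)
        patients = synthetic.generate_population(cfg)
        survey = synthetic.emit_survey(patients, cfg)
        admissions = synthetic.emit_admissions(patients, cfg)
        s_path = tmp_path / f"survey_{run}.csv"
        a_path = tmp_path / f"admissions_{run}.csv"
        survey.to_csv(s_path, index=False)
        admissions.to_csv(a_path, index=False)
        outputs.append((s_path.read_bytes(), a_path.read_bytes()))
    assert outputs[0] == outputs[1]


def test_different_seed_changes_output():
    def table(seed):
        cfg = GeneratorConfig(n_patients=200, seed=seed)
        return synthetic.emit_admissions(synthetic.generate_population(cfg), cfg)

    assert not table(1).equals(table(2))


class TestPopulationStructure:
    def test_every_patient_has_an_episode_and_chronology_holds(self):
        cfg = GeneratorConfig(n_patients=250, seed=5)
        for p in synthetic.generate_population(cfg):
            assert p.episodes
            months = [e.admission_month for e in p.episodes]
            assert months == sorted(months)
            for e in p.episodes:
                assert e.discharge_month >= e.admission_month
                assert e.length_of_stay >= 1

    def test_admission_rows_conserve_episodes(self):
        cfg = GeneratorConfig(n_patients=250, seed=5)
        patients = synthetic.generate_population(cfg)
        admissions = synthetic.emit_admissions(patients, cfg)
        assert len(admissions) == sum(len(p.episodes) for p in patients)
        assert list(admissions.columns) == list(ADMISSION_COLUMNS)
        assert not admissions.isna().any().any()

    def test_scores_within_scale(self):
        cfg = GeneratorConfig(n_patients=500, seed=8)
        survey = synthetic.emit_survey(synthetic.generate_population(cfg), cfg)
        assert survey["quality_rating"].between(1, 5).all()
        assert survey["experience_score"].between(0, 10).all()


class TestSurveyEmission:
    def test_no_pseudo_id_column(self):
        cfg = GeneratorConfig(n_patients=200, seed=3)
        survey = synthetic.emit_survey(synthetic.generate_population(cfg), cfg)
        assert "pseudo_id" not in survey.columns
        assert list(survey.columns) == list(SURVEY_COLUMNS)

    def test_zero_sampling_fraction_gives_empty_table(self):
        cfg = GeneratorConfig(n_patients=200, seed=3,
                              survey_sampling_fraction=0.0)
        survey = synthetic.emit_survey(synthetic.generate_population(cfg), cfg)
        assert len(survey) == 0
        assert list(survey.columns) == list(SURVEY_COLUMNS)

    def test_at_most_one_row_per_patient(self, small_cohort):
        oracle = synthetic.true_linkage_oracle(
            small_cohort.patients, small_cohort.survey, small_cohort.cfg)
        pseudo_ids = list(oracle.values())
        assert len(pseudo_ids) == len(set(pseudo_ids))

    def test_patient_with_two_window_admissions_contributes_the_earlier(self):
        cfg = GeneratorConfig(n_patients=1, seed=0)

        def ep(adm, dis):
            return Episode(admission_month=adm, discharge_month=dis,
                           admission_source="ae",
                           admission_specialty="general_medicine",
                           discharge_specialty="general_medicine",
                           discharge_hospital="cluster_hosp_1",
                           length_of_stay=2, discharge_destination="home",
                           diagnosis_code="DX1", procedure_code="PR1")

        patient = LatentPatient(
            pseudo_id="P000000", age=70, sex="male", district="district_01",
            district_index=0, cssa=False, surveyed=True, quality_rating=5,
            experience_score=9, episodes=[ep("2013-10", "2013-10"),
                                          ep("2013-11", "2013-11")])
        survey = synthetic.emit_survey([patient], cfg)
        assert len(survey) == 1
        assert survey.iloc[0]["admission_month"] == "2013-10"


class TestOracle:
    def test_every_row_maps_and_foreign_row_errors(self, small_cohort):
        mapping = synthetic.true_linkage_oracle(
            small_cohort.patients, small_cohort.survey, small_cohort.cfg)
        assert set(mapping) == set(small_cohort.survey["survey_id"])
        tampered = small_cohort.survey.copy()
        tampered.loc[tampered.index[0], "age"] += 1
        with pytest.raises(OracleLookupError):
            synthetic.true_linkage_oracle(small_cohort.patients, tampered,
                                          small_cohort.cfg)

    def test_unique_links_agree_with_ground_truth(self, small_cohort):
        mapping = synthetic.true_linkage_oracle(
            small_cohort.patients, small_cohort.survey, small_cohort.cfg)
        for row in small_cohort.result.unique_pairs.itertuples(index=False):
            assert mapping[row.survey_id] == row.pseudo_id


class TestCalibration:
    """The defaults are the study conditions: collision rate and matched
    cohort summaries must land where the emulated study's did."""

    def test_one_to_many_key_fraction_in_band(self, cohort10k):
        # brute-force key-frequency count, independent of the linkage module
        freq = cohort10k.candidates.groupby(list(KEY_FIELDS)).size()
        survey_keys = cohort10k.survey45.set_index(list(KEY_FIELDS)).index
        counts = freq.reindex(survey_keys, fill_value=0).to_numpy()
        fraction = (counts >= 2).mean()
        assert 0.25 <= fraction <= 0.45

    def test_matched_cohort_summaries(self, cohort10k):
        analysis = cohort10k.analysis
        assert analysis["length_of_stay"].median() == 4
        assert abs((analysis["sex"] == "male").mean() - 0.526) < 0.04
        assert abs(analysis["quality_high"].mean() - 0.775) < 0.04
        assert abs(analysis["readmit_any"].mean() - 0.238) < 0.03

    def test_age_profile_of_eligible_survey(self, cohort10k):
        ages = cohort10k.survey45["age"]
        assert 60 <= ages.median() <= 70
        q1, q3 = np.percentile(ages, [25, 75])
        assert 52 <= q1 <= 60 and 72 <= q3 <= 80

    def test_experience_score_moments(self, cohort10k):
        scores = cohort10k.survey["experience_score"]
        assert abs(scores.mean() - 8.10) < 0.2
        assert abs(scores.std() - 1.53) < 0.25

    def test_empirical_rate_matches_model_implied(self, cohort10k):
        """The realised readmission frequency must sit within binomial
        error of the mean probability the generating models imply."""
        analysis = cohort10k.analysis
        for model, flag in (("any", "readmit_any"), ("ae", "readmit_ae"),
                            ("opd", "readmit_opd")):
            implied = synthetic.model_implied_probability(
                cohort10k.cfg, analysis, model)
            se = np.sqrt((implied * (1 - implied)).sum()) / len(analysis)
            assert abs(analysis[flag].mean() - implied.mean()) < 4 * se
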