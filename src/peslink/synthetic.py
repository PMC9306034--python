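"""Synthetic paired survey/admissions cohort generator.

Real data of this kind cannot be shared: the survey is anonymous by design
and the admissions extract is confidential. This module generates a latent
patient population with the statistical structure the downstream analysis
assumes, then emits the two tables exactly as they would arrive from the
field — an anonymous survey table (ten identifiers plus two evaluative
responses, **no** patient ID) and an administrative admissions table (one
row per episode, pseudo patient ID, identifiers, welfare flag, opaque
codes).

Two patient strata are generated. *Surveyed* patients (the survey sampling
frame) receive one index admission inside the survey window and subsequent
episodes drawn **exactly** from the configured logistic readmission models,
so the generating coefficients are recoverable from the linked data.
*Non-surveyed* patients carry a busier background admission process that
emulates the heavy-utiliser tail of an elderly admissions extract; they
contribute key-density (one-to-many collisions) but never appear in the
survey, so they cannot distort the outcome model.

The ground-truth survey-row -> patient mapping (impossible to observe in a
real anonymous survey) is exposed through :func:`true_linkage_oracle` for
validation only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import COEF_NAMES, GeneratorConfig
from .errors import ConfigurationError, OracleLookupError
from .months import next_calendar_month

SURVEY_COLUMNS = (
    "survey_id", "age", "sex", "residence_district", "admission_source",
    "admission_month", "discharge_month", "admission_specialty",
    "discharge_specialty", "discharge_hospital", "length_of_stay",
    "quality_rating", "experience_score",
)

ADMISSION_COLUMNS = (
    "pseudo_id", "age", "sex", "residence_district", "admission_source",
    "admission_month", "discharge_month", "admission_specialty",
    "discharge_specialty", "discharge_hospital", "length_of_stay",
    "discharge_destination", "cssa_flag", "diagnosis_code", "procedure_code",
)

_MAX_EPISODES = 10  # safety cap per patient


@dataclass
class Episode:
    admission_month: str
    discharge_month: str
    admission_source: str
    admission_specialty: str
    discharge_specialty: str
    discharge_hospital: str
    length_of_stay: int
    discharge_destination: str  # "home" | "institution" | "died"
    diagnosis_code: str
    procedure_code: str

    @property
    def discharged_home(self) -> bool:
        return self.discharge_destination == "home"


@dataclass
class LatentPatient:
    """Generator ground truth for one patient (never emitted as-is)."""

    pseudo_id: str
    age: int
    sex: str
    district: str
    district_index: int
    cssa: bool
    surveyed: bool
    quality_rating: int      # 1 (very poor) .. 5 (excellent/very good)
    experience_score: int    # 0 .. 10
    episodes: list[Episode] = field(default_factory=list)


# --------------------------------------------------------------------------
# Covariate expansion shared with the outcome models


def covariate_vector(age: int, sex: str, los: int, cssa: bool,
                     specialty_group: str, quality_high: bool) -> dict[str, float]:
    """Expand one patient-episode into the named model covariates.

    Reference levels (male, 45-54, LOS 1-3, no CSSA, Others specialty, low
    quality rating) map to all-zero indicators; ages below 45 fall into the
    reference age band (they are excluded from analysis upstream anyway).
    """
    return {
        "intercept": 1.0,
        "female": float(sex == "female"),
        "age_55_64": float(55 <= age <= 64),
        "age_65_74": float(65 <= age <= 74),
        "age_75p": float(age >= 75),
        "los_4_7": float(4 <= los <= 7),
        "los_8p": float(los >= 8),
        "cssa": float(cssa),
        "medicine": float(specialty_group == "Medicine"),
        "oncology": float(specialty_group == "Oncology"),
        "surgery": float(specialty_group == "Surgery"),
        "quality_high": float(quality_high),
    }


def _model_p(coefs: dict[str, float], x: dict[str, float]) -> float:
    return float(expit(sum(coefs[name] * x[name] for name in COEF_NAMES)))


# --------------------------------------------------------------------------
# Episode synthesis

# group-share tables by age band (tracking the matched-cohort margins) and
# within-group code shares (concentrated: acute throughput clusters in the
# dominant ward of each group, which is what makes exact ten-field keys
# collide at a realistic rate)
_GROUP_P_OLD = {"Medicine": 0.42, "Surgery": 0.22, "Oncology": 0.055, "Others": 0.305}
_GROUP_P_YOUNG = {"Medicine": 0.30, "Surgery": 0.28, "Oncology": 0.04, "Others": 0.38}
_WITHIN_GROUP = {
    "Medicine": (("general_medicine", 0.85), ("geriatrics", 0.08),
                 ("cardiac_care_unit", 0.05), ("infectious_disease", 0.02)),
    "Surgery": (("surgery", 1.0),),
    "Oncology": (("oncology", 1.0),),
    "Others": (("orthopaedics", 0.50), ("rehabilitation", 0.20),
               ("emergency_medicine", 0.08), ("ent", 0.06),
               ("ophthalmology", 0.06), ("gynaecology", 0.04),
               ("neurosurgery", 0.04), ("cardiothoracic_surgery", 0.02)),
}
_SOURCE_P_OLD = {"ae": 0.88, "outpatient": 0.08, "other": 0.04}
_SOURCE_P_YOUNG = {"ae": 0.70, "outpatient": 0.22, "other": 0.08}

#: admission-month weights inside the survey window (survey fieldwork ramps down)
_WINDOW_MONTH_P = (0.45, 0.33, 0.22)


def _choice(rng: np.random.Generator, table: dict[str, float] | tuple) -> str:
    items = tuple(table.items()) if isinstance(table, dict) else table
    labels = [k for k, _ in items]
    probs = np.array([p for _, p in items], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _draw_specialty(rng, cfg: GeneratorConfig, age: int,
                    hint: str | None = None) -> str:
    groups = cfg.specialty_groups
    if hint is not None and rng.random() < 0.8:
        group = groups[hint]
    else:
        group = _choice(rng, _GROUP_P_OLD if age >= 65 else _GROUP_P_YOUNG)
    within = tuple((code, p) for code, p in _WITHIN_GROUP[group]
                   if code in cfg.specialty_vocabulary)
    if not within:  # custom vocabulary without this group's defaults
        codes = [c for c in cfg.specialty_vocabulary if groups[c] == group]
        return codes[rng.integers(len(codes))] if codes \
            else cfg.specialty_vocabulary[rng.integers(len(cfg.specialty_vocabulary))]
    return _choice(rng, within)


def _make_episode(rng, cfg: GeneratorConfig, patient_age: int,
                  district_index: int, admission_month: str,
                  source: str | None = None, specialty_hint: str | None = None,
                  force_home: bool = False) -> Episode:
    discharge_specialty = _draw_specialty(rng, cfg, patient_age, specialty_hint)
    if rng.random() < cfg.same_specialty_fraction:
        admission_specialty = discharge_specialty
    else:
        admission_specialty = _draw_specialty(rng, cfg, patient_age)
    if source is None:
        source = _choice(rng, _SOURCE_P_OLD if patient_age >= 65 else _SOURCE_P_YOUNG)
    home_cluster = cfg.district_cluster(district_index)
    if rng.random() < cfg.hospital_home_fraction or cfg.n_hospitals == 1:
        hospital = cfg.hospitals[home_cluster]
    else:
        others = [h for i, h in enumerate(cfg.hospitals) if i != home_cluster]
        hospital = others[rng.integers(len(others))]
    los = int(min(rng.geometric(cfg.los_distribution.geometric_p),
                  cfg.los_distribution.max_days))
    # implicit admission day decides whether discharge rolls into the next month
    day = int(rng.integers(1, 31))
    discharge_month = (next_calendar_month(admission_month)
                       if day + los > 30 else admission_month)
    if force_home or rng.random() < cfg.home_discharge_fraction:
        destination = "home"
    else:
        destination = "institution" if rng.random() < 0.6 else "died"
    return Episode(
        admission_month=admission_month,
        discharge_month=discharge_month,
        admission_source=source,
        admission_specialty=admission_specialty,
        discharge_specialty=discharge_specialty,
        discharge_hospital=hospital,
        length_of_stay=los,
        discharge_destination=destination,
        diagnosis_code=f"DX{int(rng.integers(100, 600)):03d}",
        procedure_code=f"PR{int(rng.integers(100, 400)):03d}",
    )


# --------------------------------------------------------------------------
# Population generation


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def generate_population(config: GeneratorConfig) -> list[LatentPatient]:
    """Generate the latent patient population (deterministic given the seed).

    Every patient carries at least one episode; surveyed patients' episode
    chains realise the configured readmission models exactly.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_patients

    ages = _draw_ages(rng, config, n)
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")
    dist_w = config.district_decay ** np.arange(config.n_districts)
    district_idx = rng.choice(config.n_districts, size=n, p=dist_w / dist_w.sum())
    cssa = rng.random(n) < config.cssa_prevalence
    surveyed = rng.random(n) < config.survey_sampling_fraction
    quality, score = _draw_experience(rng, config, n)

    patients: list[LatentPatient] = []
    for i in range(n):
        p = LatentPatient(
            pseudo_id=f"P{i:06d}",
            age=int(ages[i]),
            sex=str(sexes[i]),
            district=config.districts[district_idx[i]],
            district_index=int(district_idx[i]),
            cssa=bool(cssa[i]),
            surveyed=bool(surveyed[i]),
            quality_rating=int(quality[i]),
            experience_score=int(score[i]),
        )
        if p.surveyed:
            _simulate_surveyed_history(rng, config, p)
        else:
            _simulate_background_history(rng, config, p)
        p.episodes.sort(key=lambda e: (e.admission_month, e.discharge_month))
        patients.append(p)
    return patients


def _draw_ages(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    a = cfg.age_distribution
    young = rng.random(n) < a.young_weight
    draws = np.where(young,
                     rng.normal(a.young_mean, a.young_sd, n),
                     rng.normal(a.old_mean, a.old_sd, n))
    return np.clip(np.rint(draws), a.min_age, a.max_age).astype(int)


def _draw_experience(rng, cfg: GeneratorConfig, n: int):
    """Correlated quality rating (ordinal 1-5) and 0-10 experience score."""
    e = cfg.experience_model
    z = rng.normal(size=n)
    # rating from marginal cutpoints on z (levels listed worst -> best)
    from scipy.stats import norm
    cum = np.cumsum(e.quality_probs)[:-1]
    cuts = norm.ppf(cum)
    rating = 1 + np.searchsorted(cuts, z)
    rho = e.latent_correlation
    raw = e.score_mean + e.score_sd * (rho * z +
                                       np.sqrt(1 - rho ** 2) * rng.normal(size=n))
    score = np.clip(np.rint(raw), 0, 10).astype(int)
    return rating.astype(int), score


def _simulate_surveyed_history(rng, cfg: GeneratorConfig, p: LatentPatient) -> None:
    month_p = np.asarray(_WINDOW_MONTH_P[:len(cfg.survey_months)], dtype=float)
    index_month = cfg.survey_months[rng.choice(len(cfg.survey_months),
                                               p=month_p / month_p.sum())]
    index = _make_episode(rng, cfg, p.age, p.district_index, index_month,
                          force_home=True)
    p.episodes.append(index)
    coefs = cfg.outcome_coefficients
    groups = cfg.specialty_groups
    current = index
    while len(p.episodes) < _MAX_EPISODES:
        nxt = next_calendar_month(current.discharge_month)
        if nxt not in cfg.study_months:
            break
        x = covariate_vector(p.age, p.sex, current.length_of_stay, p.cssa,
                             groups[current.discharge_specialty],
                             p.quality_rating >= 4)
        p_ae = _model_p(coefs["ae"], x)
        p_opd = _model_p(coefs["opd"], x)
        p_any = _model_p(coefs["any"], x)
        union = p_ae + p_opd - p_ae * p_opd
        p_other = 0.0 if union >= 1.0 else max(0.0, (p_any - union) / (1.0 - union))
        fired = [src for src, prob in
                 (("ae", p_ae), ("outpatient", p_opd), ("other", p_other))
                 if rng.random() < prob]
        if not fired:
            break
        new = [_make_episode(rng, cfg, p.age, p.district_index, nxt, source=src,
                             specialty_hint=current.discharge_specialty)
               for src in fired]
        p.episodes.extend(new)
        current = max(new, key=lambda e: e.discharge_month)


def _simulate_background_history(rng, cfg: GeneratorConfig, p: LatentPatient) -> None:
    """Background utilisers: 1 + Poisson extra episodes across the survey
    window (their January admissions are irrelevant to every downstream
    quantity, so months are drawn from the window itself)."""
    k = 1 + int(rng.poisson(cfg.background_extra_episodes))
    k = min(k, _MAX_EPISODES)
    month_p = np.asarray(_WINDOW_MONTH_P[:len(cfg.survey_months)], dtype=float)
    months = [cfg.survey_months[j] for j in
              sorted(rng.choice(len(cfg.survey_months), size=k,
                                p=month_p / month_p.sum()))]
    for m in months:
        p.episodes.append(_make_episode(rng, cfg, p.age, p.district_index, m))


# --------------------------------------------------------------------------
# Table emission


def emit_admissions(patients: list[LatentPatient],
                    config: GeneratorConfig) -> pd.DataFrame:
    """One row per admission episode; row order randomised under the seed."""
    rows = []
    for p in patients:
        for e in p.episodes:
            rows.append((p.pseudo_id, p.age, p.sex, p.district,
                         e.admission_source, e.admission_month, e.discharge_month,
                         e.admission_specialty, e.discharge_specialty,
                         e.discharge_hospital, e.length_of_stay,
                         e.discharge_destination, int(p.cssa),
                         e.diagnosis_code, e.procedure_code))
    df = pd.DataFrame(rows, columns=list(ADMISSION_COLUMNS))
    order = _rng(config, 1).permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def _survey_id(pseudo_id: str) -> str:
    return "S" + hashlib.sha1(f"{pseudo_id}|pes".encode()).hexdigest()[:10]


def _index_episode(p: LatentPatient, config: GeneratorConfig) -> Episode | None:
    """The episode a surveyed patient rates: their first eligible discharge
    (home, within the survey window). Later in-window admissions never
    produce a second row — one voice per patient."""
    eligible = [e for e in p.episodes
                if e.discharged_home and e.discharge_month in config.survey_months]
    if not eligible:
        return None
    return min(eligible, key=lambda e: (e.admission_month, e.discharge_month))


def emit_survey(patients: list[LatentPatient],
                config: GeneratorConfig) -> pd.DataFrame:
    """The anonymous survey table: at most one row per surveyed patient.

    Carries the ten identifiers plus the two evaluative responses and a
    survey-internal id. Deliberately has **no** pseudo_id column.
    """
    rows = []
    for p in patients:
        if not p.surveyed:
            continue
        idx = _index_episode(p, config)
        if idx is None:
            continue
        rows.append((_survey_id(p.pseudo_id), p.age, p.sex, p.district,
                     idx.admission_source, idx.admission_month, idx.discharge_month,
                     idx.admission_specialty, idx.discharge_specialty,
                     idx.discharge_hospital, idx.length_of_stay,
                     p.quality_rating, p.experience_score))
    df = pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))
    order = _rng(config, 2).permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def true_linkage_oracle(patients: list[LatentPatient],
                        survey: pd.DataFrame,
                        config: GeneratorConfig | None = None
                        ) -> dict[str, str]:
    """Ground-truth mapping ``survey_id -> pseudo_id`` (test use only).

    Raises :class:`OracleLookupError` for any survey row that was not
    generated from this population.
    """
    config = config or GeneratorConfig()
    truth: dict[str, tuple[str, tuple]] = {}
    for p in patients:
        if not p.surveyed:
            continue
        idx = _index_episode(p, config)
        if idx is None:
            continue
        key = (p.age, p.sex, p.district, idx.admission_source,
               idx.admission_month, idx.discharge_month, idx.admission_specialty,
               idx.discharge_specialty, idx.discharge_hospital,
               idx.length_of_stay, p.quality_rating, p.experience_score)
        truth[_survey_id(p.pseudo_id)] = (p.pseudo_id, key)
    mapping: dict[str, str] = {}
    for row in survey.itertuples(index=False):
        entry = truth.get(row.survey_id)
        observed = (row.age, row.sex, row.residence_district, row.admission_source,
                    row.admission_month, row.discharge_month,
                    row.admission_specialty, row.discharge_specialty,
                    row.discharge_hospital, row.length_of_stay,
                    row.quality_rating, row.experience_score)
        if entry is None or entry[1] != observed:
            raise OracleLookupError(
                f"survey row {row.survey_id!r} was not generated from this population")
        mapping[str(row.survey_id)] = entry[0]
    return mapping


def model_implied_probability(config: GeneratorConfig, analysis: pd.DataFrame,
                              model: str = "any") -> np.ndarray:
    """Per-row outcome probability implied by the generating coefficients.

    ``analysis`` must carry the derived covariate columns of the analysis
    table (sex, age_group, los_group, cssa, specialty_group, quality_high).
    """
    if model not in config.outcome_coefficients:
        raise ConfigurationError(f"unknown outcome model {model!r}")
    coefs = config.outcome_coefficients[model]
    probs = np.empty(len(analysis))
    for i, row in enumerate(analysis.itertuples(index=False)):
        x = covariate_vector(int(row.age), row.sex, int(row.length_of_stay),
                             bool(row.cssa), row.specialty_group,
                             bool(row.quality_high))
        probs[i] = _model_p(coefs, x)
    return probs
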