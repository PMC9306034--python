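"""End-to-end pipeline: simulate (optional) -> preprocess -> link ->
outcomes -> analyze, with a reconciling manifest and structured logs.

Every run writes, under its output directory: the (possibly simulated)
input CSVs, cleaned CSVs, the linked-pairs CSV, the linkage report JSON,
the analysis table CSV, descriptive and model tables, a JSON-lines log of
every row-dropping decision, and ``manifest.json`` recording the config
hash, seed and the row count at every stage. The stage-count ledger always
reconciles exactly (eligible = unique + one-to-many + unmatched).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import linkage, outcomes, preprocess, stats, synthetic
from .config import PipelineConfig
from .errors import PeslinkError


class StageError(PeslinkError):
    """Wraps a stage failure with the stage name attached."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(_as_plain(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _as_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None
                 ) -> dict:
    """Execute the full pipeline and return the manifest."""
    config.validate()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "counts": {}, "files": []}
    counts = manifest["counts"]

    def emit(path: Path, df: pd.DataFrame):
        df.to_csv(path, index=False)
        manifest["files"].append(path.name)

    def record(stage: str, **kv):
        log.append({"stage": stage, **kv})

    try:
        if config.generator is not None:
            gen = config.generator
            patients = synthetic.generate_population(gen)
            survey_raw = synthetic.emit_survey(patients, gen)
            admissions_raw = synthetic.emit_admissions(patients, gen)
            emit(out / "survey.csv", survey_raw)
            emit(out / "admissions.csv", admissions_raw)
            key_spec = preprocess.KeySpec.from_generator(gen)
            record("simulate", n_patients=gen.n_patients,
                   n_survey_rows=len(survey_raw),
                   n_admission_rows=len(admissions_raw))
        else:
            survey_raw = pd.read_csv(config.survey_path)
            admissions_raw = pd.read_csv(config.admissions_path)
            key_spec = preprocess.KeySpec()
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc
    counts["survey_rows_in"] = len(survey_raw)
    counts["admission_rows_in"] = len(admissions_raw)

    try:
        survey_clean, survey_clean_rep = preprocess.standardize(
            survey_raw, key_spec)
        admissions_clean, adm_clean_rep = preprocess.standardize(
            admissions_raw, key_spec)
        for rep, which in ((survey_clean_rep, "survey"),
                           (adm_clean_rep, "admissions")):
            for issue in rep.issues:
                record("standardize", table=which, reason_code="invalid_field",
                       **issue)
        survey_eligible, age_rep = preprocess.filter_survey_eligible(
            survey_clean, config.min_age)
        record("filter_survey", reason_code="age_below_minimum",
               **age_rep.as_dict())
        candidates, cand_rep = preprocess.filter_admission_candidates(
            admissions_clean, config.linkage_window, config.hospitals,
            config.min_age)
        record("filter_admissions", reason_code="outside_linkage_frame",
               **cand_rep.as_dict())
        emit(out / "survey_clean.csv", survey_eligible)
        emit(out / "admission_candidates.csv", candidates)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc
    counts["survey_rows_clean"] = len(survey_clean)
    counts["admission_rows_clean"] = len(admissions_clean)
    counts["survey_age_eligible"] = len(survey_eligible)
    counts["admission_candidates"] = len(candidates)

    try:
        result = linkage.link_deterministic(survey_eligible, candidates,
                                            config.key_fields)
        result.check_partition()
        report = linkage.matching_report(result)
        emit(out / "linked_pairs.csv", result.unique_pairs)
        with open(out / "linkage_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        manifest["files"].append("linkage_report.json")
        record("link", reason_code="one_to_many",
               n=report["n_one_to_many"])
        record("link", reason_code="unmatched", n=report["n_unmatched"])
        record("link", reason_code="demoted_reverse_multiplicity",
               n=report["n_demoted"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("link", exc) from exc
    counts.update({
        "linked_unique": report["n_unique"],
        "one_to_many": report["n_one_to_many"],
        "unmatched": report["n_unmatched"],
    })
    manifest["linkage_report"] = report

    try:
        analysis = outcomes.build_analysis_table(
            result.unique_pairs, survey_eligible, admissions_clean)
        emit(out / "analysis_table.csv", analysis)
    except Exception as exc:  # noqa: BLE001
        raise StageError("outcomes", exc) from exc
    counts["analysis_rows"] = len(analysis)
    counts["readmit_any"] = int(analysis["readmit_any"].sum())
    counts["readmit_ae"] = int(analysis["readmit_ae"].sum())
    counts["readmit_opd"] = int(analysis["readmit_opd"].sum())

    try:
        descriptive = pd.concat(
            [stats.crosstab(analysis, var, "readmit_any").assign(variable=var)
             for var in ("sex", "age_group", "los_group", "cssa",
                         "specialty_group", "quality_high", "experience_high")],
            ignore_index=True) if len(analysis) else pd.DataFrame()
        emit(out / "descriptive_table.csv", descriptive)
        model_summaries = {}
        for exposure in ("quality", "experience") if len(analysis) else ():
            fits = stats.fit_outcome_models(analysis, exposure)
            table = stats.model_tables(fits)
            emit(out / f"model_table_{exposure}.csv", table)
            model_summaries[exposure] = {
                model: {"r2_mcfadden": round(fit.r2_mcfadden, 4),
                        "r2_nagelkerke": round(fit.r2_nagelkerke, 4),
                        "converged": fit.converged}
                for model, fit in fits.items()}
        manifest["models"] = model_summaries
    except Exception as exc:  # noqa: BLE001
        raise StageError("analyze", exc) from exc

    # conservation audit: the linkage partition must reconcile exactly
    assert counts["survey_age_eligible"] == (counts["linked_unique"]
                                             + counts["one_to_many"]
                                             + counts["unmatched"])
    assert counts["analysis_rows"] == counts["linked_unique"]

    with open(out / "run_log.jsonl", "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    manifest["files"].append("run_log.jsonl")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
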