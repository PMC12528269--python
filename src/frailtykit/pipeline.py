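"""End-to-end pipeline: generate -> ascertain -> score -> harmonise -> compare.

One root seed is split deterministically per stage (via
``numpy.random.SeedSequence``), so a fixed :class:`RunConfig` reproduces
every output byte for byte. Row counts at every stage -- including
completeness-filter exclusions -- are recorded in a manifest, mirroring
the count bookkeeping an epidemiological audit trail needs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ascertain import (
    apply_cohort_criteria,
    build_ehr_matrix,
    build_survey_matrix,
    filter_survey_completeness,
    load_codelists,
)
from .cohort import generate_ehr_records, generate_population, generate_survey_responses
from .compare import (
    StandardizationScheme,
    distribution_report,
    fit_all_deficit_logistics,
    fit_frailty_linear,
    ks_two_sample,
    standardized_prevalence_table,
)
from .errors import FrailtykitError
from .harmonize import load_mapping, relation_counts, select_comparable
from .index import CategoryThresholds, score_matrix, summarize
from .matrix import EHR, SURVEY
from .params import POLYPHARMACY, default_codelists, default_mapping, load_params

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str
    n_ehr: int = 2000
    n_survey: int = 2000
    seed: int = 0
    params_path: str | None = None  # None -> packaged defaults
    mapping_path: str | None = None
    codelists_path: str | None = None
    thresholds: tuple[float, float, float] = (0.12, 0.24, 0.36)
    denominator: str = "assessed"
    survey_total_deficits: int = 58
    survey_max_missing: int = 20
    log_level: str = "INFO"


def validate_config(config: RunConfig) -> list[str]:
    """Return all violations; an empty list means the config is valid."""
    violations: list[str] = []
    if config.n_ehr < 1 or config.n_survey < 1:
        violations.append("n_ehr and n_survey must be >= 1")
    t = tuple(config.thresholds)
    if len(t) != 3 or not (0 < t[0] < t[1] < t[2] < 1):
        violations.append(f"thresholds must be strictly increasing within (0,1), got {t}")
    if config.denominator not in ("assessed", "total"):
        violations.append(f"denominator must be 'assessed' or 'total', got {config.denominator!r}")
    if config.survey_max_missing >= config.survey_total_deficits:
        violations.append("survey_max_missing must be below survey_total_deficits")
    for name in ("params_path", "mapping_path", "codelists_path"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            violations.append(f"{name}: file not found: {path}")
    if not isinstance(config.seed, (int, np.integer)):
        violations.append("seed must be an integer")
    return violations


def _stage_seeds(root_seed: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    problems = validate_config(config)
    if problems:
        raise FrailtykitError("invalid RunConfig: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = load_params(config.params_path)
    mapping = (
        default_mapping() if config.mapping_path is None else load_mapping(config.mapping_path)
    )
    codelists = (
        default_codelists()
        if config.codelists_path is None
        else load_codelists(config.codelists_path)
    )
    thresholds = CategoryThresholds(*config.thresholds)
    index_date = params.index_date
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": int(config.seed),
        "stage_seeds": seeds,
        "index_date": index_date.isoformat(),
        "thresholds": list(config.thresholds),
        "denominator": config.denominator,
        "quantile_convention": "linear interpolation",
        "multiple_testing": "none (per-deficit p-values reported unadjusted)",
        "stages": {},
    }

    # ---- stage 1: simulate -------------------------------------------------
    log.info("stage simulate: n_ehr=%d n_survey=%d", config.n_ehr, config.n_survey)
    ehr_cfg = params.cohort_config(EHR, config.n_ehr, seeds[0])
    svy_cfg = params.cohort_config(SURVEY, config.n_survey, seeds[1])
    ehr_persons = generate_population(ehr_cfg)
    svy_persons = generate_population(svy_cfg)
    ehr_records = generate_ehr_records(
        ehr_persons,
        params.ehr_models,
        codelists,
        params.polypharmacy,
        index_date,
        seed=seeds[2],
        polypharmacy_name=POLYPHARMACY,
    )
    svy_records = generate_survey_responses(
        svy_persons, params.survey_models, params.missingness, seed=seeds[3]
    )
    ehr_persons.to_csv(out / "ehr_persons.csv", index=False)
    svy_persons.drop(columns=["registration_start"]).to_csv(out / "survey_persons.csv", index=False)
    ehr_records.coded_events.to_csv(out / "ehr_coded_events.csv", index=False)
    ehr_records.prescriptions.to_csv(out / "ehr_prescriptions.csv", index=False)
    svy_records.wide.to_csv(out / "survey_wide.csv", na_rep="")
    manifest["stages"]["simulate"] = {
        "ehr_persons": len(ehr_persons),
        "survey_persons": len(svy_persons),
        "coded_events": len(ehr_records.coded_events),
        "prescriptions": len(ehr_records.prescriptions),
    }

    # ---- stage 2: eligibility ---------------------------------------------
    ehr_eligible = apply_cohort_criteria(ehr_persons, index_date)
    svy_eligible = apply_cohort_criteria(svy_persons, index_date)
    manifest["stages"]["eligibility"] = {
        "ehr_retained": len(ehr_eligible),
        "ehr_excluded": len(ehr_persons) - len(ehr_eligible),
        "survey_retained": len(svy_eligible),
        "survey_excluded": len(svy_persons) - len(svy_eligible),
    }

    # ---- stage 3: ascertain ------------------------------------------------
    ehr_matrix = build_ehr_matrix(
        ehr_records.coded_events,
        ehr_records.prescriptions,
        codelists,
        index_date,
        person_ids=ehr_eligible["person_id"],
        polypharmacy_spec=params.polypharmacy,
        polypharmacy_name=POLYPHARMACY,
    )
    svy_matrix_all = build_survey_matrix(
        svy_records.wide.loc[svy_records.wide.index.isin(svy_eligible["person_id"])]
    )
    svy_matrix, excluded = filter_survey_completeness(
        svy_matrix_all,
        total_deficits=config.survey_total_deficits,
        max_missing=config.survey_max_missing,
    )
    ehr_matrix.to_csv(out / "ehr_matrix.csv")
    svy_matrix.to_csv(out / "survey_matrix.csv")
    manifest["stages"]["ascertain"] = {
        "ehr_matrix_persons": ehr_matrix.n_persons,
        "survey_matrix_persons_before_filter": svy_matrix_all.n_persons,
        "survey_completeness_excluded": excluded,
        "survey_matrix_persons": svy_matrix.n_persons,
    }

    # ---- stage 4: score ----------------------------------------------------
    ehr_scores = score_matrix(ehr_matrix, thresholds, config.denominator)
    svy_scores = score_matrix(svy_matrix, thresholds, config.denominator)
    ehr_scores.to_csv(out / "ehr_scores.csv", index=False)
    svy_scores.to_csv(out / "survey_scores.csv", index=False)
    summary = pd.concat(
        [
            summarize(ehr_scores, thresholds=thresholds).assign(source=EHR),
            summarize(svy_scores, thresholds=thresholds).assign(source=SURVEY),
        ],
        ignore_index=True,
    )
    summary.to_csv(out / "summary.csv", index=False)
    manifest["stages"]["score"] = {
        "ehr_scored": len(ehr_scores),
        "survey_scored": len(svy_scores),
    }

    # ---- stage 5: harmonise ------------------------------------------------
    mapping.validate_against(ehr_matrix.deficit_names, svy_matrix.deficit_names)
    counts = relation_counts(mapping)
    eligible_svy_persons = svy_eligible.loc[
        svy_eligible["person_id"].isin(svy_matrix.person_ids)
    ]
    paired = select_comparable(mapping, ehr_matrix, svy_matrix, ehr_eligible, eligible_svy_persons)
    paired.to_csv(out / "comparable_long.csv", index=False)
    manifest["stages"]["harmonize"] = {**counts, "paired_rows": len(paired)}

    # ---- stage 6: compare --------------------------------------------------
    pooled_persons = pd.concat(
        [ehr_eligible[["person_id", "age", "sex", "source"]],
         eligible_svy_persons[["person_id", "age", "sex", "source"]]],
        ignore_index=True,
    )
    scheme = StandardizationScheme.from_persons(pooled_persons)
    prev = pd.concat(
        [
            standardized_prevalence_table(ehr_matrix, ehr_eligible, scheme).assign(source=EHR),
            standardized_prevalence_table(svy_matrix, eligible_svy_persons, scheme).assign(
                source=SURVEY
            ),
        ],
        ignore_index=True,
    )
    prev.to_csv(out / "standardized_prevalence.csv", index=False)

    or_table = fit_all_deficit_logistics(paired)
    or_table.to_csv(out / "odds_ratios.csv", index=False)

    ks = ks_two_sample(ehr_scores["score"], svy_scores["score"])

    scored_pooled = pd.concat(
        [
            ehr_scores.merge(ehr_eligible, on="person_id"),
            svy_scores.merge(eligible_svy_persons, on="person_id"),
        ],
        ignore_index=True,
    )
    linear = fit_frailty_linear(scored_pooled)
    pd.DataFrame(
        {
            "term": list(linear.coefficients),
            "coefficient": list(linear.coefficients.values()),
            "std_error": [linear.standard_errors[t] for t in linear.coefficients],
            "p_value": [linear.p_values[t] for t in linear.coefficients],
        }
    ).to_csv(out / "linear_fit.csv", index=False)

    dist = distribution_report(ehr_scores, svy_scores, pooled_persons,
                               bins=(len(ehr_matrix.deficit_names), len(svy_matrix.deficit_names)))
    dist["histogram"].to_csv(out / "histogram.csv", index=False)
    dist["ecdf"].to_csv(out / "ecdf.csv", index=False)
    dist["quartiles_by_age"].to_csv(out / "quartiles_by_age.csv", index=False)

    manifest["stages"]["compare"] = {
        "ks_statistic": ks.statistic,
        "ks_p_value": ks.p_value,
        "linear_r_squared": linear.r_squared,
        "linear_residual_sd": linear.residual_sd,
        "n_deficit_models": int(len(or_table)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
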