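"""Shipped default parameters, mapping and toy codelists.

The default generator parameter set lives in ``data/default_params.yaml``
(versioned, never hard-coded) and defines the study conditions every
test and report runs under: cohort age/sex structure, per-deficit
logistic coefficients for a 36-deficit EHR index and a 58-deficit survey
index, the latent-factor loadings, and survey missingness rates. The
companion files ship the cross-source deficit mapping and flat toy
codelists for the 35 coded EHR deficits.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources

import yaml

from .ascertain import Codelist, load_codelists
from .cohort import CohortConfig, DeficitModel, MissingnessConfig, PolypharmacySpec
from .errors import ConfigurationError
from .harmonize import DeficitMapping, load_mapping
from .matrix import EHR

POLYPHARMACY = "polypharmacy"


def _data_path(name: str):
    return resources.files("frailtykit").joinpath("data", name)


@dataclass(frozen=True)
class DefaultParams:
    """Everything needed to generate and analyse the default synthetic study."""

    version: int
    index_date: dt.date
    cohorts: dict  # source -> dict(prob_female, age_band_weights, registration_years_range)
    ehr_models: tuple[DeficitModel, ...]
    survey_models: tuple[DeficitModel, ...]
    missingness: MissingnessConfig
    polypharmacy: PolypharmacySpec

    def cohort_config(self, source: str, n_persons: int, seed: int) -> CohortConfig:
        if source not in self.cohorts:
            raise ConfigurationError(f"no cohort defaults for source {source!r}")
        c = self.cohorts[source]
        return CohortConfig(
            n_persons=n_persons,
            age_band_weights=c["age_band_weights"],
            prob_female=c["prob_female"],
            source_label=source,
            index_date=self.index_date,
            registration_years_range=tuple(c.get("registration_years_range", (9.0, 20.0))),
            seed=seed,
        )

    def models(self, source: str) -> tuple[DeficitModel, ...]:
        return self.ehr_models if source == EHR else self.survey_models


def _parse_models(entries) -> tuple[DeficitModel, ...]:
    return tuple(
        DeficitModel(
            deficit_name=e["name"],
            beta0=float(e["beta0"]),
            beta_age=float(e.get("beta_age", 0.0)),
            beta_sex=float(e.get("beta_sex", 0.0)),
            beta_source=float(e.get("beta_source", 0.0)),
            lambda_load=float(e.get("lambda_load", 0.0)),
        )
        for e in entries
    )


def load_params(path=None) -> DefaultParams:
    """Load a generator parameter file (defaults to the packaged one)."""
    if path is None:
        text = _data_path("default_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    poly = raw.get("polypharmacy", {})
    return DefaultParams(
        version=int(raw["version"]),
        index_date=raw["index_date"]
        if isinstance(raw["index_date"], dt.date)
        else dt.date.fromisoformat(str(raw["index_date"])),
        cohorts=raw["cohorts"],
        ehr_models=_parse_models(raw["deficits"]["ehr"]),
        survey_models=_parse_models(raw["deficits"]["survey"]),
        missingness=MissingnessConfig(
            per_deficit_missing_prob=float(raw["missingness"]["per_deficit_missing_prob"]),
            heavy_missing_prob=float(raw["missingness"].get("heavy_missing_prob", 0.0)),
            heavy_item_missing_prob=float(
                raw["missingness"].get("heavy_item_missing_prob", 0.5)
            ),
        ),
        polypharmacy=PolypharmacySpec(
            window_days=int(poly.get("window_days", 84)),
            min_paragraphs=int(poly.get("min_paragraphs", 5)),
            chapter_range=tuple(poly.get("chapter_range", (1, 15))),
            excluded_paragraphs=frozenset(poly.get("excluded_paragraphs", [])),
        ),
    )


def default_mapping() -> DeficitMapping:
    """The shipped cross-source deficit mapping."""
    with resources.as_file(_data_path("deficit_mapping.csv")) as p:
        return load_mapping(p)


def default_codelists() -> dict[str, Codelist]:
    """The shipped toy codelists for the coded EHR deficits."""
    with resources.as_file(_data_path("toy_codelists.csv")) as p:
        return load_codelists(p)
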