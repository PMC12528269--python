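"""Synthetic two-source cohort generator.

Emulates the two study populations a cumulative-deficit frailty
comparison needs: an EHR-style primary-care cohort (aged 65+, long
continuous registration, deficits ascertained from coded events and
prescriptions) and a survey-style cohort (deficits from questionnaire
items with item missingness).

Deficit presence follows a per-deficit logistic model in age, sex and
data source,

    logit p = beta0 + beta_age*(age-65) + beta_sex*sex + beta_source*source
              + lambda_load * u,

with ``sex`` coded 0=male/1=female and ``source`` coded 0=survey/1=EHR.
``u`` is one shared standard-normal latent factor per person: it induces
positive correlation between deficits and gives the frailty score its
characteristic right-skewed, gamma-like shape with an effective upper
bound well below 1. The latent factor is generator-internal and never
exported to analysis inputs.
"""

from __future__ import annotations

import datetime as dt
from collections import namedtuple
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .matrix import EHR, SOURCES, SOURCE_CODE, SURVEY

AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90+")
_BAND_BOUNDS = {
    "65-69": (65, 69),
    "70-74": (70, 74),
    "75-79": (75, 79),
    "80-84": (80, 84),
    "85-89": (85, 89),
    "90+": (90, 99),
}


def age_band(age) -> "str | pd.Series":
    """Map an age (or Series of ages) to its 5-year band label, 90+ topcoded."""
    if isinstance(age, (pd.Series, np.ndarray)):
        ages = pd.Series(age)
        bins = [64, 69, 74, 79, 84, 89, np.inf]
        return pd.cut(ages, bins=bins, labels=list(AGE_BANDS)).astype(str)
    for band, (lo, hi) in _BAND_BOUNDS.items():
        if lo <= age <= hi or (band == "90+" and age >= 90):
            return band
    raise ValueError(f"age {age} below cohort minimum of 65")


@dataclass(frozen=True)
class CohortConfig:
    """Population structure for one synthetic cohort.

    ``age_band_weights`` gives the probability of each 5-year band
    (65-69 ... 90+); ages are drawn uniformly (integer years) within the
    sampled band, with the open-ended 90+ band drawn uniformly on 90-99.
    """

    n_persons: int
    age_band_weights: Mapping[str, float]
    prob_female: float
    source_label: str
    index_date: dt.date
    registration_years_range: tuple[float, float] = (9.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if not 0.0 <= self.prob_female <= 1.0:
            raise ConfigurationError("prob_female must lie in [0, 1]")
        if self.source_label not in SOURCES:
            raise ConfigurationError(f"source_label must be one of {SOURCES}")
        unknown = set(self.age_band_weights) - set(AGE_BANDS)
        if unknown:
            raise ConfigurationError(f"unknown age bands: {sorted(unknown)}")
        total = sum(self.age_band_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"age_band_weights sum to {total}, not 1")
        lo, hi = self.registration_years_range
        if lo > hi:
            raise ConfigurationError("registration_years_range must be (min, max)")


@dataclass(frozen=True)
class DeficitModel:
    """Logistic model for one deficit's presence probability."""

    deficit_name: str
    beta0: float
    beta_age: float = 0.0
    beta_sex: float = 0.0
    beta_source: float = 0.0
    lambda_load: float = 0.0

    def __post_init__(self) -> None:
        coefs = (self.beta0, self.beta_age, self.beta_sex, self.beta_source, self.lambda_load)
        if not all(np.isfinite(coefs)):
            raise ConfigurationError(f"non-finite coefficient for {self.deficit_name!r}")


@dataclass(frozen=True)
class MissingnessConfig:
    """Item missingness for survey responses (applied after presence draws).

    Missingness is MCAR: independent of deficit values. Two layers are
    mixed to emulate near-complete questionnaires alongside a small group
    of heavy non-responders (the group later removed by the completeness
    filter): every cell is missing with ``per_deficit_missing_prob``, and
    with probability ``heavy_missing_prob`` a person instead answers each
    item only with probability ``1 - heavy_item_missing_prob``.
    """

    per_deficit_missing_prob: "float | Mapping[str, float]" = 0.0
    mode: str = "MCAR"
    heavy_missing_prob: float = 0.0
    heavy_item_missing_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.mode != "MCAR":
            raise ConfigurationError("only MCAR missingness is supported")
        probs = (
            list(self.per_deficit_missing_prob.values())
            if isinstance(self.per_deficit_missing_prob, Mapping)
            else [self.per_deficit_missing_prob]
        )
        probs += [self.heavy_missing_prob, self.heavy_item_missing_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("missingness probabilities must lie in [0, 1]")

    def item_probs(self, deficit_names: Sequence[str]) -> np.ndarray:
        if isinstance(self.per_deficit_missing_prob, Mapping):
            return np.array([self.per_deficit_missing_prob.get(d, 0.0) for d in deficit_names])
        return np.full(len(deficit_names), float(self.per_deficit_missing_prob))


def generate_population(config: CohortConfig) -> pd.DataFrame:
    """Draw a person table with age, sex, source and (EHR) registration date.

    Returns a DataFrame with columns person_id, age, sex (0/1),
    source (0=survey/1=EHR), registration_start (NaT for survey persons)
    and latent_u. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    bands = list(config.age_band_weights)
    weights = np.array([config.age_band_weights[b] for b in bands], dtype=float)
    weights = weights / weights.sum()  # exact renormalisation of validated weights
    band_idx = rng.choice(len(bands), size=n, p=weights)
    lows = np.array([_BAND_BOUNDS[b][0] for b in bands])
    highs = np.array([_BAND_BOUNDS[b][1] for b in bands])
    ages = rng.integers(lows[band_idx], highs[band_idx] + 1)
    sex = (rng.random(n) < config.prob_female).astype(int)
    latent_u = rng.standard_normal(n)

    index_ts = pd.Timestamp(config.index_date)
    if config.source_label == EHR:
        lo, hi = config.registration_years_range
        years_registered = rng.uniform(lo, hi, size=n)
        registration_start = index_ts - pd.to_timedelta(
            np.round(years_registered * 365.25), unit="D"
        )
    else:
        registration_start = pd.Series([pd.NaT] * n)

    prefix = config.source_label
    return pd.DataFrame(
        {
            "person_id": [f"{prefix}-{i:06d}" for i in range(n)],
            "age": ages.astype(int),
            "sex": sex,
            "source": SOURCE_CODE[config.source_label],
            "registration_start": pd.Series(registration_start).values,
            "latent_u": latent_u,
        }
    )


def deficit_probability(model: DeficitModel, persons) -> "float | np.ndarray":
    """Presence probability under the per-deficit logistic model.

    ``persons`` may be a single mapping-like record or a DataFrame with
    columns age, sex, source and latent_u; returns a float or an array
    accordingly. Probabilities are strictly inside (0, 1).
    """
    scalar = not isinstance(persons, pd.DataFrame)
    p = pd.DataFrame([persons]) if scalar else persons
    eta = (
        model.beta0
        + model.beta_age * (np.asarray(p["age"], dtype=float) - 65.0)
        + model.beta_sex * np.asarray(p["sex"], dtype=float)
        + model.beta_source * np.asarray(p["source"], dtype=float)
        + model.lambda_load * np.asarray(p["latent_u"], dtype=float)
    )
    prob = expit(eta)
    return float(prob[0]) if scalar else prob


def draw_deficits(
    persons: pd.DataFrame, models: Sequence[DeficitModel], seed: int
) -> pd.DataFrame:
    """Draw ground-truth presence flags (person x deficit, int 0/1)."""
    names = [m.deficit_name for m in models]
    if len(set(names)) != len(names):
        raise ConfigurationError("deficit names must be unique within a model set")
    rng = np.random.default_rng(seed)
    flags = {}
    for model in models:
        prob = deficit_probability(model, persons)
        flags[model.deficit_name] = (rng.random(len(persons)) < prob).astype(int)
    return pd.DataFrame(flags, index=pd.Index(persons["person_id"], name="person_id"))


@dataclass(frozen=True)
class PolypharmacySpec:
    """Definition of the polypharmacy deficit.

    Present when prescriptions span at least ``min_paragraphs`` distinct
    BNF (chapter, paragraph) drug classes within ``window_days`` from the
    index date, restricted to medication chapters ``chapter_range`` and
    excluding ``excluded_paragraphs`` (non-medication classes such as
    dressings or nutritional supplements).
    """

    window_days: int = 84
    min_paragraphs: int = 5
    chapter_range: tuple[int, int] = (1, 15)
    excluded_paragraphs: frozenset = frozenset()
    missing_paragraph_policy: str = "drop"  # or "count": each missing row its own class

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ConfigurationError("window_days must be positive")
        if self.min_paragraphs < 1:
            raise ConfigurationError("min_paragraphs must be >= 1")
        if self.missing_paragraph_policy not in ("drop", "count"):
            raise ConfigurationError("missing_paragraph_policy must be 'drop' or 'count'")


EhrRecords = namedtuple("EhrRecords", ["coded_events", "prescriptions", "truth"])
SurveyRecords = namedtuple("SurveyRecords", ["wide", "truth"])

#: code guaranteed to match no codelist; used for distractor events
DISTRACTOR_CODE = "ZZ000"


def _paragraph_universe(chapter_range: tuple[int, int]) -> list[tuple[int, str]]:
    lo, hi = chapter_range
    return [(ch, f"{ch:02d}.{p:02d}") for ch in range(lo, hi + 1) for p in range(1, 9)]


def generate_ehr_records(
    persons: pd.DataFrame,
    deficit_models: Sequence[DeficitModel],
    codelists: Mapping[str, "Codelist"],
    polypharmacy_spec: PolypharmacySpec,
    index_date: dt.date,
    seed: int,
    truth: pd.DataFrame | None = None,
    polypharmacy_name: str = "polypharmacy",
    distractor_rate: float = 0.5,
    history_years: float = 9.0,
) -> EhrRecords:
    """Materialise coded events and prescriptions consistent with drawn flags.

    For every person drawn present for a coded deficit, at least one event
    carries a code from that deficit's codelist dated strictly before
    ``index_date`` (uniform over the preceding ``history_years``). Persons
    drawn present for polypharmacy receive prescriptions spanning >= the
    spec's minimum distinct BNF paragraphs inside the ascertainment
    window; absent persons receive fewer. Distractor events (a code
    matching no codelist) and out-of-scope prescriptions are interleaved
    so ascertainment cannot succeed by accident.
    """
    if not (persons["source"] == SOURCE_CODE[EHR]).all():
        raise ConfigurationError("generate_ehr_records requires an all-EHR person table")
    coded_names = [m.deficit_name for m in deficit_models if m.deficit_name != polypharmacy_name]
    missing_lists = [d for d in coded_names if d not in codelists]
    if missing_lists:
        raise ConfigurationError(f"no codelist for deficits: {missing_lists}")

    rng = np.random.default_rng(seed)
    if truth is None:
        truth = draw_deficits(persons, deficit_models, seed=int(rng.integers(2**31)))

    index_ts = pd.Timestamp(index_date)
    history_days = int(history_years * 365.25)
    pids = truth.index.to_numpy()

    ev_pid, ev_code, ev_date = [], [], []
    for name in coded_names:
        present = truth[name].to_numpy() == 1
        carriers = pids[present]
        if carriers.size == 0:
            continue
        codes = sorted(codelists[name].codes)
        n_events = 1 + rng.poisson(0.7, size=carriers.size)
        rep = np.repeat(carriers, n_events)
        ev_pid.append(rep)
        ev_code.append(rng.choice(codes, size=rep.size))
        ev_date.append(index_ts - pd.to_timedelta(rng.integers(1, history_days, rep.size), "D"))
    # distractor events: a code outside every codelist, any date
    n_distract = rng.poisson(distractor_rate, size=pids.size)
    rep = np.repeat(pids, n_distract)
    if rep.size:
        ev_pid.append(rep)
        ev_code.append(np.full(rep.size, DISTRACTOR_CODE))
        ev_date.append(index_ts - pd.to_timedelta(rng.integers(1, history_days, rep.size), "D"))

    coded_events = pd.DataFrame(
        {
            "person_id": np.concatenate(ev_pid) if ev_pid else [],
            "code": np.concatenate(ev_code) if ev_code else [],
            "event_date": pd.DatetimeIndex(np.concatenate([d.to_numpy() for d in ev_date]))
            if ev_date
            else pd.DatetimeIndex([]),
        }
    )

    spec = polypharmacy_spec
    universe = [
        (ch, par)
        for ch, par in _paragraph_universe(spec.chapter_range)
        if par not in spec.excluded_paragraphs
    ]
    out_of_scope = [(spec.chapter_range[1] + 3, f"{spec.chapter_range[1] + 3:02d}.01")]
    rx_pid, rx_ch, rx_par, rx_date = [], [], [], []
    poly_flags = (
        truth[polypharmacy_name].to_numpy()
        if polypharmacy_name in truth.columns
        else np.zeros(pids.size, dtype=int)
    )
    for pid, present in zip(pids, poly_flags):
        if present:
            k = min(len(universe), spec.min_paragraphs + rng.poisson(1.0))
        else:
            k = int(rng.integers(0, spec.min_paragraphs))
        chosen = [universe[i] for i in rng.choice(len(universe), size=k, replace=False)]
        # occasional out-of-scope chapter row; never counts toward the flag
        if rng.random() < 0.3:
            chosen.append(out_of_scope[0])
        for ch, par in chosen:
            rx_pid.append(pid)
            rx_ch.append(ch)
            rx_par.append(par)
            rx_date.append(index_ts + pd.Timedelta(int(rng.integers(0, spec.window_days)), "D"))

    prescriptions = pd.DataFrame(
        {
            "person_id": rx_pid,
            "bnf_chapter": pd.array(rx_ch, dtype="Int64"),
            "bnf_paragraph": rx_par,
            "issue_date": pd.DatetimeIndex(rx_date) if rx_date else pd.DatetimeIndex([]),
        }
    )
    return EhrRecords(coded_events, prescriptions, truth)


def generate_survey_responses(
    persons: pd.DataFrame,
    deficit_models: Sequence[DeficitModel],
    missingness: MissingnessConfig,
    seed: int,
    truth: pd.DataFrame | None = None,
) -> SurveyRecords:
    """Draw the person x deficit wide response table (1/0/NaN).

    Missingness is applied after the presence draw, so the ground-truth
    flags in ``truth`` are complete and recoverable on non-missing cells.
    """
    if not (persons["source"] == SOURCE_CODE[SURVEY]).all():
        raise ConfigurationError("generate_survey_responses requires an all-survey person table")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = draw_deficits(persons, deficit_models, seed=int(rng.integers(2**31)))

    names = truth.columns.tolist()
    item_p = missingness.item_probs(names)
    miss = rng.random(truth.shape) < item_p[np.newaxis, :]
    if missingness.heavy_missing_prob > 0:
        heavy = rng.random(len(truth)) < missingness.heavy_missing_prob
        heavy_miss = rng.random(truth.shape) < missingness.heavy_item_missing_prob
        miss = np.where(heavy[:, None], heavy_miss, miss)
    wide = truth.astype(float).mask(miss)
    return SurveyRecords(wide, truth)
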