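"""Comparison battery for pooled two-source frailty data.

Implements the four analyses used to compare a survey-based and an
EHR-based frailty index at population level:

* direct age-sex standardised deficit prevalence (reference weights
  default to the pooled two-source age-band x sex distribution);
* per-deficit logistic regression ``logit p = b0 + b_age*(age-65) +
  b_sex*sex + b_source*source`` giving age-sex-adjusted odds ratios for
  the data source (survey=0, EHR=1), with Wald 95% intervals;
* the two-sample Kolmogorov-Smirnov statistic on the frailty-score
  distributions, with an asymptotic two-sided p-value;
* an OLS model of the frailty score on age, sex, source and their three
  pairwise interactions.

Standard model fitting is delegated to statsmodels; this module owns the
epidemiological conventions (codings, centring, standardisation scheme,
degenerate-input handling) around it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import AGE_BANDS, age_band
from .errors import ConfigurationError, DataError
from .matrix import DeficitMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- prevalence

@dataclass(frozen=True)
class StandardizationScheme:
    """Reference weights for direct standardisation over (age band, sex) strata."""

    reference_weights: dict  # (age_band, sex) -> weight

    def __post_init__(self) -> None:
        w = np.array(list(self.reference_weights.values()), dtype=float)
        if (w < 0).any():
            raise ConfigurationError("standardisation weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"standardisation weights sum to {w.sum()}, not 1")

    @classmethod
    def from_persons(cls, persons: pd.DataFrame) -> "StandardizationScheme":
        """Weights = the (pooled) person table's own stratum distribution."""
        strata = pd.DataFrame(
            {"band": age_band(persons["age"]), "sex": persons["sex"].to_numpy()}
        )
        counts = strata.value_counts()
        weights = (counts / counts.sum()).to_dict()
        return cls(reference_weights=weights)


def standardized_prevalence(
    deficit_values: pd.Series,
    persons: pd.DataFrame,
    scheme: StandardizationScheme,
) -> float:
    """Directly standardised prevalence of one deficit.

    ``deficit_values`` holds 1/0/NaN per person_id; missing cells are
    excluded from their stratum's denominator. Strata present in the
    scheme but empty in the data are handled by renormalising the
    remaining weights (logged), so the result stays a weighted average
    of observed stratum prevalences.
    """
    df = persons[["person_id", "age", "sex"]].copy()
    df["value"] = df["person_id"].map(deficit_values)
    df = df.dropna(subset=["value"])
    if df.empty:
        raise DataError("no observed values in any stratum")
    df["band"] = age_band(df["age"])

    stratum_prev = df.groupby(["band", "sex"], observed=True)["value"].mean()
    weights = pd.Series(scheme.reference_weights)
    observed = stratum_prev.index.intersection(weights.index)
    dropped = weights.index.difference(observed)
    if len(dropped) and weights.loc[dropped].sum() > 0:
        log.warning(
            "renormalising standardisation weights over %d observed strata "
            "(%d empty strata held weight %.4f)",
            len(observed), len(dropped), float(weights.loc[dropped].sum()),
        )
    w = weights.loc[observed]
    if w.sum() == 0:
        raise DataError("no scheme weight on any observed stratum")
    w = w / w.sum()
    return float((stratum_prev.loc[observed] * w).sum())


def standardized_prevalence_table(
    matrix: DeficitMatrix, persons: pd.DataFrame, scheme: StandardizationScheme
) -> pd.DataFrame:
    """Standardised prevalence (in %) for every deficit in a matrix."""
    rows = []
    for name in matrix.deficit_names:
        prev = standardized_prevalence(matrix.data[name], persons, scheme)
        rows.append({"deficit": name, "std_prevalence_pct": 100.0 * prev})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- logistic fits

@dataclass(frozen=True)
class ORResult:
    """Adjusted odds ratio of one deficit pair for the data source."""

    deficit_pair: str
    or_datasource: float
    ci95: tuple[float, float]
    p_value: float
    coefficients: tuple[float, float, float, float]  # (b0, b_age, b_sex, b_source)
    standard_errors: tuple[float, float, float, float] = (np.nan,) * 4
    status: str = "ok"  # or "constant_outcome" / "separation"

    def __post_init__(self) -> None:
        if self.status == "ok":
            lo, hi = self.ci95
            if not lo <= self.or_datasource <= hi:
                raise DataError("odds ratio outside its own confidence interval")


def fit_deficit_logistic(pair_table: pd.DataFrame) -> ORResult:
    """Age-sex-adjusted logistic model of one deficit pair on data source.

    Expects the long-format rows for a single pair as produced by
    :func:`frailtykit.harmonize.select_comparable`. Degenerate inputs
    (constant outcome, perfect separation / non-converged fit) return a
    flagged result rather than NaNs.
    """
    pair = pair_table["deficit_pair"].iloc[0] if len(pair_table) else "?"
    if pair_table["source"].nunique() < 2:
        raise DataError(f"pair {pair!r}: both sources must be present")
    y = pair_table["present"].to_numpy(dtype=float)
    nan4 = (np.nan,) * 4
    if y.min() == y.max():
        return ORResult(pair, np.nan, (np.nan, np.nan), np.nan, nan4, status="constant_outcome")
    X = pd.DataFrame(
        {
            "age_c": pair_table["age"].to_numpy(dtype=float) - 65.0,
            "sex": pair_table["sex"].to_numpy(dtype=float),
            "source": pair_table["source"].to_numpy(dtype=float),
        }
    )
    # constant adjustment covariates (e.g. a single-stratum table) carry no
    # information and would make the design singular; drop them, keep source
    for cov in ("age_c", "sex"):
        if X[cov].nunique() <= 1:
            X = X.drop(columns=[cov])
    X = sm.add_constant(X)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected and flagged below
            fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
    except Exception:
        return ORResult(pair, np.nan, (np.nan, np.nan), np.nan, nan4, status="separation")
    params = fit.params
    bse = fit.bse
    if not (fit.mle_retvals.get("converged", False) and np.isfinite(bse).all()):
        return ORResult(pair, np.nan, (np.nan, np.nan), np.nan, nan4, status="separation")
    b_src, se_src = float(params["source"]), float(bse["source"])
    z = stats.norm.ppf(0.975)
    return ORResult(
        deficit_pair=pair,
        or_datasource=float(np.exp(b_src)),
        ci95=(float(np.exp(b_src - z * se_src)), float(np.exp(b_src + z * se_src))),
        p_value=float(fit.pvalues["source"]),
        coefficients=tuple(
            float(params[k]) if k in params else np.nan
            for k in ("const", "age_c", "sex", "source")
        ),
        standard_errors=tuple(
            float(bse[k]) if k in bse else np.nan
            for k in ("const", "age_c", "sex", "source")
        ),
    )


def fit_all_deficit_logistics(paired_long: pd.DataFrame) -> pd.DataFrame:
    """One ORResult row per deficit pair (forest-plot table)."""
    rows = []
    for pair, table in paired_long.groupby("deficit_pair", sort=False):
        r = fit_deficit_logistic(table)
        rows.append(
            {
                "deficit_pair": pair,
                "or_datasource": r.or_datasource,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_value": r.p_value,
                "log_or": r.coefficients[3] if r.status == "ok" else np.nan,
                "log_or_se": r.standard_errors[3] if r.status == "ok" else np.nan,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- K-S

@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise DataError(f"K-S statistic {self.statistic} outside [0, 1]")


def ks_two_sample(scores_a, scores_b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |ECDF_a - ECDF_b| over the pooled jump
    points; the p-value uses the asymptotic two-sided Kolmogorov
    distribution with the standard two-sample effective n.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue))


# --------------------------------------------------------------------- OLS

LINEAR_TERMS = ("const", "age_c", "sex", "source", "age_c:sex", "age_c:source", "sex:source")


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of score on age, sex, source and pairwise interactions."""

    coefficients: dict
    standard_errors: dict
    p_values: dict
    r_squared: float
    residual_sd: float
    n_obs: int

    def __post_init__(self) -> None:
        missing = set(LINEAR_TERMS) - set(self.coefficients)
        if missing:
            raise DataError(f"linear fit missing terms: {sorted(missing)}")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise DataError(f"r_squared {self.r_squared} outside [0, 1]")


def _design(df: pd.DataFrame) -> pd.DataFrame:
    age_c = df["age"].to_numpy(dtype=float) - 65.0
    sex = df["sex"].to_numpy(dtype=float)
    source = df["source"].to_numpy(dtype=float)
    X = pd.DataFrame(
        {
            "age_c": age_c,
            "sex": sex,
            "source": source,
            "age_c:sex": age_c * sex,
            "age_c:source": age_c * source,
            "sex:source": sex * source,
        }
    )
    return sm.add_constant(X)


def fit_frailty_linear(scored_persons: pd.DataFrame) -> LinearFit:
    """Fit the pooled frailty-score regression with interaction terms.

    ``scored_persons`` needs columns score, age, sex, source. A design in
    which some term is constant (e.g. a single data source) is rejected
    with the offending term named.
    """
    X = _design(scored_persons)
    for term in X.columns:
        if term != "const" and X[term].nunique() <= 1:
            raise DataError(f"degenerate design: term {term!r} is constant")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DataError("degenerate design: collinear terms")
    fit = sm.OLS(scored_persons["score"].to_numpy(dtype=float), X).fit()
    return LinearFit(
        coefficients=dict(fit.params),
        standard_errors=dict(fit.bse),
        p_values=dict(fit.pvalues),
        r_squared=float(fit.rsquared),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        n_obs=int(fit.nobs),
    )


# ------------------------------------------------------------ distributions

def distribution_report(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    persons: pd.DataFrame,
    bins: tuple[int, int] = (36, 58),
    labels: tuple[str, str] = ("EHR", "SURVEY"),
) -> dict[str, pd.DataFrame]:
    """Histogram, ECDF and quartiles-by-age tables for two scored cohorts.

    Histograms use per-source bin counts matched to each index's deficit
    count (so one bin spans one deficit's worth of score) and are
    normalised to total mass 1 per source.
    """
    person_cov = persons.set_index("person_id")["age"]
    tables: dict[str, pd.DataFrame] = {}

    hist_rows, ecdf_frames, quart_rows = [], [], []
    for res, n_bins, label in zip((results_a, results_b), bins, labels):
        scores = res["score"].to_numpy(dtype=float)
        counts, edges = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
        mass = counts / counts.sum() if counts.sum() else counts.astype(float)
        hist_rows.append(
            pd.DataFrame(
                {
                    "source": label,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "mass": mass,
                }
            )
        )
        xs = np.sort(scores)
        ecdf_frames.append(
            pd.DataFrame(
                {"source": label, "score": xs, "ecdf": np.arange(1, xs.size + 1) / xs.size}
            )
        )
        ages = res["person_id"].map(person_cov)
        bands = age_band(ages)
        for band in AGE_BANDS:
            sel = scores[(bands == band).to_numpy()]
            if sel.size:
                q1, med, q3 = np.quantile(sel, [0.25, 0.5, 0.75])
            else:
                q1 = med = q3 = np.nan
            quart_rows.append(
                {"source": label, "age_band": band, "n": sel.size,
                 "q1": q1, "median": med, "q3": q3}
            )

    tables["histogram"] = pd.concat(hist_rows, ignore_index=True)
    tables["ecdf"] = pd.concat(ecdf_frames, ignore_index=True)
    tables["quartiles_by_age"] = pd.DataFrame(quart_rows)
    return tables
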