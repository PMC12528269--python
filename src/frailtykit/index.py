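"""Frailty index scoring and population summaries.

The cumulative-deficit frailty index is the proportion of measured
deficits present in an individual: ``score = n_present / n_assessed``,
bounded in [0, 1]. For survey data with item missingness the default
denominator is the number of assessed (non-missing) deficits for that
person, the standard cumulative-deficit convention; dividing by the
fixed deficit total instead is available via ``denominator="total"``.

Scores are banded into the conventional categories: fit (< 0.12),
mild (0.12 to < 0.24), moderate (0.24 to < 0.36) and severe (>= 0.36).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_BANDS, age_band
from .errors import ConfigurationError, DataError
from .matrix import DeficitMatrix

CATEGORIES = ("fit", "mild", "moderate", "severe")


@dataclass(frozen=True)
class CategoryThresholds:
    """Left-closed category cut points on the frailty score scale."""

    mild_at: float = 0.12
    moderate_at: float = 0.24
    severe_at: float = 0.36

    def __post_init__(self) -> None:
        cuts = (self.mild_at, self.moderate_at, self.severe_at)
        if not all(0.0 < c < 1.0 for c in cuts):
            raise ConfigurationError("thresholds must lie strictly inside (0, 1)")
        if not (cuts[0] < cuts[1] < cuts[2]):
            raise ConfigurationError(f"thresholds must be strictly increasing, got {cuts}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mild_at, self.moderate_at, self.severe_at)


@dataclass(frozen=True)
class FrailtyResult:
    """Score record for one person."""

    person_id: object
    n_present: int
    n_assessed: int
    score: float
    category: str


def categorize(score: float, thresholds: CategoryThresholds = CategoryThresholds()) -> str:
    """Band one score; intervals are closed on the left, open on the right."""
    if not 0.0 <= score <= 1.0:
        raise DataError(f"score {score} outside [0, 1]")
    idx = int(np.searchsorted(thresholds.as_tuple(), score, side="right"))
    return CATEGORIES[idx]


def categorize_scores(
    scores, thresholds: CategoryThresholds = CategoryThresholds()
) -> pd.Series:
    """Vectorised :func:`categorize`."""
    arr = np.asarray(scores, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise DataError("scores outside [0, 1]")
    idx = np.searchsorted(thresholds.as_tuple(), arr, side="right")
    out = pd.Series(np.array(CATEGORIES)[idx], index=getattr(scores, "index", None))
    return out


def compute_frailty_index(matrix_row: pd.Series, denominator: str = "assessed",
                          total_deficits: int | None = None) -> FrailtyResult:
    """Score a single person's deficit row (cells 1/0/NaN)."""
    cells = matrix_row.astype(float)
    n_assessed = int(cells.notna().sum())
    if n_assessed == 0:
        raise DataError(f"person {matrix_row.name!r} has no assessed deficits")
    n_present = int((cells == 1.0).sum())
    denom = n_assessed if denominator == "assessed" else int(total_deficits or len(cells))
    score = n_present / denom
    return FrailtyResult(
        person_id=matrix_row.name,
        n_present=n_present,
        n_assessed=n_assessed,
        score=score,
        category=categorize(score),
    )


def score_matrix(
    matrix: DeficitMatrix,
    thresholds: CategoryThresholds = CategoryThresholds(),
    denominator: str = "assessed",
) -> pd.DataFrame:
    """Score every person in a matrix.

    Returns a DataFrame with columns person_id, n_present, n_assessed,
    score and category. ``denominator="total"`` divides by the matrix's
    full deficit count regardless of missingness.
    """
    if denominator not in ("assessed", "total"):
        raise ConfigurationError("denominator must be 'assessed' or 'total'")
    data = matrix.data
    n_present = (data == 1.0).sum(axis=1).astype(int)
    n_assessed = data.notna().sum(axis=1).astype(int)
    if (n_assessed == 0).any():
        bad = n_assessed.index[n_assessed == 0].tolist()
        raise DataError(f"persons with no assessed deficits: {bad[:10]}")
    denom = n_assessed if denominator == "assessed" else len(matrix.deficit_names)
    score = n_present / denom
    return pd.DataFrame(
        {
            "person_id": data.index,
            "n_present": n_present.to_numpy(),
            "n_assessed": n_assessed.to_numpy(),
            "score": score.to_numpy(),
            "category": categorize_scores(score.to_numpy(), thresholds).to_numpy(),
        }
    ).reset_index(drop=True)


def _group_stats(scores: np.ndarray, thresholds: CategoryThresholds) -> dict:
    n = scores.size
    if n == 0:
        stats = {k: np.nan for k in ("mean", "sd", "median", "q1", "q3")}
        cats = {f"n_{c}": 0 for c in CATEGORIES}
        pcts = {f"pct_{c}": np.nan for c in CATEGORIES}
        return {"n": 0, **stats, **cats, **pcts, "pct_any_frailty": np.nan}
    q1, med, q3 = np.quantile(scores, [0.25, 0.5, 0.75])  # linear interpolation
    cats = categorize_scores(scores, thresholds)
    counts = {f"n_{c}": int((cats == c).sum()) for c in CATEGORIES}
    pcts = {f"pct_{c}": 100.0 * counts[f"n_{c}"] / n for c in CATEGORIES}
    return {
        "n": n,
        "mean": float(np.mean(scores)),
        "sd": float(np.std(scores, ddof=1)) if n > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        **counts,
        **pcts,
        "pct_any_frailty": 100.0 * (n - counts["n_fit"]) / n,
    }


def summarize(
    results: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    group_by: str = "none",
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> pd.DataFrame:
    """Population summary of frailty scores, overall or by stratum.

    ``group_by`` is one of none, age_band, sex or source; anything but
    ``"none"`` requires a ``persons`` table joinable on person_id.
    Reports n, mean, sample SD, median, Q1/Q3 (linear-interpolation
    quantiles), category counts and percentages, and the combined
    percentage with any (mild or worse) frailty.
    """
    if group_by not in ("none", "age_band", "sex", "source"):
        raise ConfigurationError(f"unsupported group_by {group_by!r}")
    df = results
    if group_by != "none":
        if persons is None:
            raise ConfigurationError(f"group_by={group_by!r} requires a persons table")
        df = results.merge(
            persons[["person_id", "age", "sex", "source"]], on="person_id", how="left"
        )
        df["age_band"] = age_band(df["age"])

    if group_by == "none":
        rows = [{"group": "all", **_group_stats(df["score"].to_numpy(), thresholds)}]
    else:
        levels = list(AGE_BANDS) if group_by == "age_band" else sorted(df[group_by].unique())
        rows = []
        for level in levels:
            scores = df.loc[df[group_by] == level, "score"].to_numpy()
            rows.append({"group": level, **_group_stats(scores, thresholds)})
    return pd.DataFrame(rows)


def summarize_counts(category_counts: dict[str, int]) -> dict[str, float]:
    """Percentages implied by per-category headcounts.

    Convenience for reproducing published category tables from their
    printed counts; returns the same pct_* keys as :func:`summarize`.
    """
    missing = set(CATEGORIES) - set(category_counts)
    if missing:
        raise DataError(f"missing categories: {sorted(missing)}")
    total = sum(category_counts[c] for c in CATEGORIES)
    if total <= 0:
        raise DataError("category counts must sum to a positive total")
    out = {f"pct_{c}": 100.0 * category_counts[c] / total for c in CATEGORIES}
    out["pct_any_frailty"] = 100.0 * (total - category_counts["fit"]) / total
    out["n"] = total
    return out
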