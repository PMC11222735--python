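"""Population-level seasonal diet summaries and male/female comparisons.

Seasonal diet is summarised as percent weighted occurrence under both the
scaled (0-5) and digestion-corrected (0-31.5) metrics, together with the
share of each season's diet coming from resource pulses (fruit pulses
plus fawn-classified deer).  Sex differences are tested per food-season
combination with a Poisson GLMM: per-scat ordinal score as the count-like
response, sex as the fixed effect, and a random intercept per individual;
a difference is called significant when the Wald 95% CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CORE_ITEMS, FOOD_ITEMS
from .diet import (aggregate_core, classify_deer_ages, digestion_correct,
                   weighted_occurrence)
from .glmm import fit_glmm

__all__ = [
    "SexSeasonModelResult",
    "seasonal_summary",
    "sex_food_model",
    "run_sex_models",
]

#: Diet items counted as resource pulses besides fawn-aged deer.
PULSE_FRUIT_ITEMS = ("blackberry", "persimmon")


@dataclass(frozen=True)
class SexSeasonModelResult:
    food: str
    season: str
    estimate: float               # log-scale coefficient for male vs female
    lo95: float
    hi95: float
    n_scats: int
    n_individuals: int
    converged: bool

    @property
    def significant(self) -> bool:
        """CI excludes zero (only meaningful for converged fits)."""
        return self.converged and (self.lo95 > 0.0 or self.hi95 < 0.0)


# ----------------------------------------------------------------------
def seasonal_summary(
    scores: pd.DataFrame,
    seasons: Mapping[str, str],
    correction_table: Mapping[str, float],
    split_deer: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Season x item weighted-occurrence table under both metrics, plus the
    per-season pulse share.

    ``scores`` is the long zeroed score table; ``seasons`` maps sample_id
    to season label.  The pulse share counts the fruit pulses plus the
    deer occurrence attributable to fawn-classified scats.  With
    ``split_deer`` the deer row is reported split by age class.  Seasons
    with no nonzero scores are omitted with a warning.
    """
    df = scores.copy()
    df["season"] = df["sample_id"].map(seasons)
    df = df[df["season"].notna()]
    ages = classify_deer_ages(scores, seasons)
    corrected = digestion_correct(df, correction_table)

    profile_rows, pulse_rows = [], []
    for metric, data, col in (("weighted", df, "score"),
                              ("digestion-corrected", corrected, "amount")):
        for season, grp in data.groupby("season", sort=True):
            try:
                prof = weighted_occurrence(grp, FOOD_ITEMS, col)
            except ValueError:
                warnings.warn(f"season {season!r} has no nonzero scores; omitted")
                continue
            deer_grp = grp[grp["item"] == "deer"].copy()
            deer_grp["age"] = deer_grp["sample_id"].map(ages).fillna("n/a")
            deer_by_age = deer_grp.groupby("age")[col].sum()
            deer_total = float(deer_by_age.sum())
            fawn_frac = (float(deer_by_age.get("fawn", 0.0)) / deer_total
                         if deer_total > 0 else 0.0)
            for item in FOOD_ITEMS:
                if item == "deer" and split_deer and deer_total > 0:
                    for age in ("fawn", "ambiguous", "adult", "n/a"):
                        share = float(deer_by_age.get(age, 0.0)) / deer_total
                        if share > 0:
                            profile_rows.append(
                                (season, f"deer_{age}", metric,
                                 prof[item] * share))
                else:
                    profile_rows.append((season, item, metric, prof[item]))
            pulse = sum(prof[i] for i in PULSE_FRUIT_ITEMS) + prof["deer"] * fawn_frac
            pulse_rows.append((season, metric, pulse))
    table = pd.DataFrame(profile_rows,
                         columns=["season", "item", "metric", "percent"])
    pulse_share = pd.DataFrame(pulse_rows,
                               columns=["season", "metric", "pulse_share_pct"])
    return table, pulse_share


# ----------------------------------------------------------------------
def sex_food_model(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    food: str,
    season: str,
    response: str = "score",
) -> SexSeasonModelResult:
    """Poisson GLMM of one food's per-scat score on sex for one season.

    ``meta`` carries sample_id, individual_id, sex, season for the
    individually identified scats.  The male coefficient is reported on
    the log scale with its Wald 95% CI.  Degenerate data (an all-zero
    sex, non-convergence) yield ``converged=False`` rather than a silent
    fallback.
    """
    sub = meta[meta["season"] == season]
    item_scores = scores[scores["item"] == food][["sample_id", response]]
    d = sub.merge(item_scores, on="sample_id")
    n_scats = len(d)
    n_ind = d["individual_id"].nunique()
    if n_scats == 0 or d["sex"].nunique() < 2:
        return SexSeasonModelResult(food, season, np.nan, np.nan, np.nan,
                                    n_scats, n_ind, False)
    y = d[response].to_numpy(dtype=float)
    male = (d["sex"] == "M").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(male), male])
    degenerate = (y[male == 1].sum() == 0) or (y[male == 0].sum() == 0)
    res = fit_glmm(y, X, d["individual_id"].to_numpy(), family="poisson",
                   names=["intercept", "male"])
    est, lo, hi = res.coef("male")
    return SexSeasonModelResult(food, season, est, lo, hi, n_scats, n_ind,
                                res.converged and not degenerate)


def run_sex_models(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    foods: Sequence[str] = CORE_ITEMS,
    seasons: Sequence[str] = ("winter", "summer", "fall"),
    response: str = "score",
) -> pd.DataFrame:
    """The full grid of food x season sex comparisons (12 models at the
    defaults: the four most-consumed foods by three seasons).  When the
    default core foods are requested, vegetation is pooled from its score
    sub-categories before modelling."""
    if tuple(foods) == tuple(CORE_ITEMS):
        scores = aggregate_core(scores, response)
    rows = []
    for food in foods:
        for season in seasons:
            r = sex_food_model(scores, meta, food, season, response)
            rows.append((r.food, r.season, r.estimate, r.lo95, r.hi95,
                         r.n_scats, r.n_individuals, r.converged,
                         r.significant))
    return pd.DataFrame(rows, columns=[
        "food", "season", "estimate", "lo95", "hi95",
        "n_scats", "n_individuals", "converged", "significant"])
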