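"""Diet scoring: zeroing rules, digestion correction, deer-age
classification, and the weighted-occurrence statistic.

Per-scat contents are scored 0-5 by relative volume (0 absent, 1 trace
<2%, 2 = 2-25%, 3 = 26-50%, 4 = 51-75%, 5 = 76-100%).  Trace scores are
zeroed for every item, and level-2 scores are additionally zeroed for
grass-like material that is often ingested incidentally.  The percent
weighted occurrence of item i in a stratum is

    100 * sum_s X_is * Y_is / sum_i sum_s X_is * Y_is

where X_is indicates presence of item i in scat s and Y_is is the scaled
(0-5) or digestion-corrected (0-31.5) amount.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CORE_ITEMS, FOOD_ITEMS, VEGETATION_PARTS

__all__ = [
    "GRASS_LIKE_ITEMS",
    "apply_zeroing",
    "aggregate_core",
    "classify_deer_age",
    "classify_deer_ages",
    "core_profile",
    "digestion_correct",
    "weighted_occurrence",
    "profiles_by",
    "placeholder_correction_factors",
]

#: Items whose level-2 scores are zeroed because they are commonly
#: swallowed incidentally rather than eaten (grass, leaves, pine needles,
#: bark).  When scoring is done at the 11-category aggregate level the
#: grass fraction is not separable, so the default names the fine-grained
#: item used when sub-item scores are available.
GRASS_LIKE_ITEMS: frozenset[str] = frozenset({"grass_leaves_pine_bark"})

#: Items billed at the medium-mammal digestion factor because feeding
#: trials did not include ungulates.
_MEDIUM_MAMMAL_ITEMS = ("deer", "wild_pig")


def apply_zeroing(scores: pd.DataFrame,
                  grass_items: Iterable[str] = GRASS_LIKE_ITEMS) -> pd.DataFrame:
    """Zero trace scores (1 -> 0 for every item; 2 -> 0 for grass-like
    items).  Input is a long table with columns ``item`` and ``score``;
    a new frame is returned, the input is not modified.  Idempotent."""
    out = scores.copy()
    sc = out["score"].to_numpy().copy()
    if not np.issubdtype(sc.dtype, np.integer):
        raise ValueError("scores must be integers in 0..5")
    if sc.min() < 0 or sc.max() > 5:
        raise ValueError("scores must be in 0..5")
    sc[sc == 1] = 0
    grass = out["item"].isin(set(grass_items)).to_numpy()
    sc[grass & (sc == 2)] = 0
    out["score"] = sc
    return out


def classify_deer_age(hair_widths: Sequence[float],
                      hooves: bool = False,
                      season: str | None = None) -> str:
    """Deer age class from hair widths (um): mean <70 fawn, >90 adult,
    70-90 inclusive ambiguous — unless the sample is from summer and
    contains small hooves, which overrides ambiguous to fawn."""
    widths = [w for w in hair_widths if w is not None and not pd.isna(w)]
    if not widths:
        return "ambiguous"
    mean = float(np.mean(widths))
    if mean < 70.0:
        return "fawn"
    if mean > 90.0:
        return "adult"
    if hooves and season == "summer":
        return "fawn"
    return "ambiguous"


def classify_deer_ages(scores: pd.DataFrame,
                       seasons: Mapping[str, str] | None = None) -> pd.Series:
    """Vectorised age class for every deer row of a long score table with
    hair columns ``hair_w1..3`` and ``hooves``; ``seasons`` maps sample_id
    to season label.  Returns a Series indexed by sample_id."""
    deer = scores[(scores["item"] == "deer") & (scores["score"] > 0)]
    hair_cols = [c for c in ("hair_w1", "hair_w2", "hair_w3")
                 if c in deer.columns]
    out = {}
    for _, row in deer.iterrows():
        widths = [row[c] for c in hair_cols]
        hooves = bool(row["hooves"]) if ("hooves" in deer.columns
                                        and not pd.isna(row["hooves"])) else False
        season = seasons.get(row["sample_id"]) if seasons else None
        out[row["sample_id"]] = classify_deer_age(widths, hooves, season)
    return pd.Series(out, name="deer_age", dtype="object")


def placeholder_correction_factors() -> dict[str, float]:
    """Synthetic stand-in digestion-correction factors.

    The real factors come from published feeding trials and are not
    bundled here; these placeholders only preserve the qualitative
    ordering (hair/bone-rich mammal remains are under-represented in
    scat, so mammals get large factors; fruit passes nearly unchanged)
    and the 0-31.5 corrected scale (max factor 6.3).  Supply measured
    factors for real analyses.
    """
    return {
        "medium_mammal": 6.3,
        "rabbit": 5.1,
        "small_mammal": 4.8,
        "other_mammal": 5.0,
        "bird": 4.0,
        "insect": 2.0,
        "blackberry": 1.0,
        "persimmon": 1.0,
        "other_fruit_vegetation": 1.0,
        "other": 1.0,
    }


def _factor_for(item: str, table: Mapping[str, float]) -> float:
    key = "medium_mammal" if item in _MEDIUM_MAMMAL_ITEMS else item
    if key not in table:
        raise KeyError(f"no digestion-correction factor for item {item!r}")
    f = table[key]
    if f <= 0:
        raise ValueError(f"correction factor for {item!r} must be positive")
    return f


def digestion_correct(scores: pd.DataFrame,
                      table: Mapping[str, float]) -> pd.DataFrame:
    """Multiply each item's scaled amount by its digestion-correction
    factor (deer and wild pig use the medium-mammal factor).  Adds an
    ``amount`` column; assumes zeroing was already applied.  Only items
    that actually occur (nonzero score) need a factor."""
    out = scores.copy()
    nonzero = out["score"] > 0
    factors = out.loc[nonzero, "item"].map(lambda it: _factor_for(it, table))
    out["amount"] = 0.0
    out.loc[nonzero, "amount"] = out.loc[nonzero, "score"] * factors
    return out


def weighted_occurrence(
    scores: pd.DataFrame,
    items: Sequence[str] = FOOD_ITEMS,
    value_col: str = "score",
) -> pd.Series:
    """Percent weighted occurrence over ``items`` for one stratum.

    ``scores`` is a long table (sample_id, item, score [, amount]); the
    statistic is each item's summed amount as a percentage of the total
    over the included items.  Raises ``ValueError`` when every amount is
    zero (the stratum's profile is undefined and must be excluded)."""
    sub = scores[scores["item"].isin(items)]
    sums = sub.groupby("item")[value_col].sum().reindex(list(items), fill_value=0.0)
    total = float(sums.sum())
    if total <= 0:
        raise ValueError("all-zero stratum: weighted occurrence undefined")
    return 100.0 * sums.astype(float) / total


def profiles_by(
    scores: pd.DataFrame,
    by: str,
    items: Sequence[str] = FOOD_ITEMS,
    value_col: str = "score",
) -> pd.DataFrame:
    """Weighted-occurrence profiles per stratum (one row per stratum,
    columns = items, rows sum to 100).  Strata whose amounts are all zero
    are dropped."""
    rows = {}
    for label, grp in scores.groupby(by, sort=True):
        try:
            rows[label] = weighted_occurrence(grp, items, value_col)
        except ValueError:
            continue
    out = pd.DataFrame(rows).T
    out.index.name = by
    return out


def aggregate_core(scores: pd.DataFrame,
                   value_col: str = "score") -> pd.DataFrame:
    """Collapse the 11 score categories to the four core analysis
    categories: deer, small mammal, and rabbit pass through, while
    "vegetation" pools the amounts of blackberry, persimmon, and other
    fruit/vegetation per scat.  Returns a long frame (sample_id, item,
    ``value_col``) restricted to the core items."""
    keep = scores[scores["item"].isin(("deer", "small_mammal", "rabbit"))]
    veg = (scores[scores["item"].isin(VEGETATION_PARTS)]
           .groupby("sample_id", as_index=False)[value_col].sum())
    veg["item"] = "vegetation"
    out = pd.concat([keep[["sample_id", "item", value_col]],
                     veg[["sample_id", "item", value_col]]],
                    ignore_index=True)
    return out.sort_values(["sample_id", "item"], ignore_index=True)


def core_profile(scores: pd.DataFrame, value_col: str = "score") -> pd.Series:
    """Weighted occurrence over the four core categories (deer,
    vegetation, small mammal, rabbit), renormalised to sum to 100.
    ``scores`` is the full 11-category table; vegetation is pooled first."""
    return weighted_occurrence(aggregate_core(scores, value_col),
                               CORE_ITEMS, value_col)
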