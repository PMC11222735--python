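"""Dietary convergence across resource-pulse periods.

Individual diet profiles over the four core foods are computed inside
each 6-week period, pairwise Bray-Curtis dissimilarities are taken
between every pair of individuals, and periods are compared with a
Kruskal-Wallis test followed by Dunn's post-hoc z tests with Bonferroni
correction.  Pairwise dissimilarities within a period share individuals
and are therefore not independent; the tests are applied to them as-is
and the caveat is recorded in the output metadata.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CORE_ITEMS
from .diet import aggregate_core, weighted_occurrence

__all__ = [
    "PeriodDefinition",
    "DissimilaritySet",
    "PeriodComparison",
    "default_periods",
    "independence_filter",
    "assign_periods",
    "individual_period_profiles",
    "bray_curtis",
    "pairwise_dissimilarity",
    "disjoint_pair_dissimilarity",
    "dunn_test",
    "compare_periods",
]

PERIOD_DAYS = 41  # six 7-day weeks, inclusive date range


@dataclass(frozen=True)
class PeriodDefinition:
    """A 6-week analysis window (inclusive dates)."""

    label: str
    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if (self.end - self.start).days != PERIOD_DAYS:
            raise ValueError(
                f"period {self.label!r} must span exactly 6 weeks "
                f"({PERIOD_DAYS} days inclusive), got "
                f"{(self.end - self.start).days}")

    @classmethod
    def from_start(cls, label: str, start: _dt.date) -> "PeriodDefinition":
        return cls(label, start, start + _dt.timedelta(days=PERIOD_DAYS))

    def contains(self, date: _dt.date) -> bool:
        return self.start <= date <= self.end


def default_periods(year: int = 2020) -> tuple[PeriodDefinition, ...]:
    """The four default pulse-centred windows: fawn (early May - mid
    June), blackberry (June - mid July), persimmon (October - November),
    and a winter control (late January - early March)."""
    d = _dt.date
    return (
        PeriodDefinition("fawn", d(year, 5, 4), d(year, 6, 14)),
        PeriodDefinition("blackberry", d(year, 6, 8), d(year, 7, 19)),
        PeriodDefinition.from_start("persimmon", d(year, 10, 8)),
        PeriodDefinition.from_start("winter", d(year, 1, 23)),
    )


@dataclass
class DissimilaritySet:
    """Pairwise Bray-Curtis values among individuals within one period."""

    period: str
    values: pd.DataFrame          # id_a, id_b, bray_curtis
    n_individuals: int
    independent: bool = False     # pairs share individuals by construction

    def __post_init__(self) -> None:
        n = self.n_individuals
        if len(self.values) != n * (n - 1) // 2:
            raise ValueError("pair count must be n(n-1)/2")
        v = self.values["bray_curtis"]
        if len(v) and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("Bray-Curtis values must lie in [0, 1]")


# ----------------------------------------------------------------------
def independence_filter(
    scats: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop pseudo-replicated scats.

    Within each (individual, transect, collection-date) group, scats whose
    estimated ages are within 1 day of each other are assumed to be the
    same defecation bout; one is retained at random (seeded) and the rest
    are removed from all further analyses.  Age-adjacency is chained:
    ages 2, 3, 4 form one cluster.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    removed: list[str] = []
    for _, grp in scats.groupby(["individual_id", "transect", "date"],
                                sort=True):
        if len(grp) < 2:
            continue
        g = grp.sort_values(["est_age_days", "sample_id"])
        ages = g["est_age_days"].to_numpy()
        ids = g["sample_id"].to_numpy()
        start = 0
        for i in range(1, len(g) + 1):
            if i == len(g) or ages[i] - ages[i - 1] > 1:
                cluster = ids[start:i]
                if len(cluster) > 1:
                    keep = rng.choice(cluster)
                    removed.extend(s for s in cluster if s != keep)
                start = i
    retained = scats[~scats["sample_id"].isin(removed)].copy()
    return retained, removed


def assign_periods(
    scats: pd.DataFrame,
    periods: Sequence[PeriodDefinition],
    use_deposition_date: bool = True,
) -> pd.DataFrame:
    """Tag each scat with the period containing its deposition date
    (collection date minus estimated age; configurable to collection
    date).  Scats outside every period get a null period."""
    out = scats.copy()
    coll = pd.to_datetime(out["date"]).dt.date
    if use_deposition_date:
        ref = [c - _dt.timedelta(days=int(a))
               for c, a in zip(coll, out["est_age_days"])]
    else:
        ref = list(coll)
    labels = []
    for d in ref:
        label = None
        for p in periods:
            if p.contains(d):
                label = p.label
                break
        labels.append(label)
    out["period"] = labels
    return out


def individual_period_profiles(
    scores: pd.DataFrame,
    scats: pd.DataFrame,
    period: PeriodDefinition,
    items: Sequence[str] = CORE_ITEMS,
    value_col: str = "score",
) -> pd.DataFrame:
    """Per-individual weighted-occurrence profiles over the core items for
    scats deposited in ``period``.

    ``scats`` must carry ``individual_id`` and a ``period`` column from
    :func:`assign_periods`.  Individuals with no nonzero core-item score
    in the period are excluded (their profile is undefined).  Rows sum
    to 100.  When the default core items are requested, the vegetation
    category is pooled from its score sub-categories first.
    """
    if tuple(items) == tuple(CORE_ITEMS):
        scores = aggregate_core(scores, value_col)
    sub = scats[scats["period"] == period.label]
    merged = scores.merge(sub[["sample_id", "individual_id"]], on="sample_id")
    rows = {}
    for ind, grp in merged.groupby("individual_id", sort=True):
        try:
            rows[ind] = weighted_occurrence(grp, items, value_col)
        except ValueError:
            continue
    prof = pd.DataFrame(rows).T
    prof.index.name = "individual_id"
    return prof


# ----------------------------------------------------------------------
def bray_curtis(p: np.ndarray, q: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|p-q| / sum(p+q) between two
    nonnegative composition vectors on the same item set."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must share the same item set")
    if p.min() < 0 or q.min() < 0:
        raise ValueError("profiles must be nonnegative")
    denom = float(np.sum(p + q))
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(np.sum(np.abs(p - q)) / denom)


def pairwise_dissimilarity(profiles: pd.DataFrame, period: str) -> DissimilaritySet:
    """All n(n-1)/2 pairwise Bray-Curtis values among the individuals in a
    profile table (rows = individuals, columns = items)."""
    ids = list(profiles.index)
    mat = profiles.to_numpy(dtype=float)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], bray_curtis(mat[i], mat[j])))
    values = pd.DataFrame(rows, columns=["id_a", "id_b", "bray_curtis"])
    return DissimilaritySet(period=period, values=values, n_individuals=len(ids))


def disjoint_pair_dissimilarity(
    profiles: pd.DataFrame,
    period: str,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bray-Curtis values over one random *disjoint* pairing of the
    individuals (each individual appears in at most one pair).

    The full pairwise matrix reuses every individual in n-1 pairs, which
    violates the independence assumption of the rank tests applied
    downstream; a disjoint pairing sacrifices pairs (n/2 instead of
    n(n-1)/2) but yields independent values on which Kruskal-Wallis and
    Dunn are correctly calibrated.  Offered as a statistically
    conservative alternative, not the default.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    ids = list(profiles.index)
    order = rng.permutation(len(ids))
    mat = profiles.to_numpy(dtype=float)
    rows = []
    for k in range(0, len(ids) - 1, 2):
        i, j = order[k], order[k + 1]
        rows.append((ids[i], ids[j], bray_curtis(mat[i], mat[j])))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "bray_curtis"])


# ----------------------------------------------------------------------
def dunn_test(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction and
    Bonferroni adjustment over all group pairs."""
    labels = list(groups)
    sizes = {k: len(np.asarray(groups[k])) for k in labels}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    pos = 0
    for k in labels:
        mean_ranks[k] = float(np.mean(ranks[pos:pos + sizes[k]]))
        pos += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append((a, b, z, p_raw, min(1.0, p_raw * n_pairs)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z",
                                       "p_raw", "p_bonferroni"])


@dataclass
class PeriodComparison:
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame
    means: pd.DataFrame           # period, n_pairs, mean, lo95, hi95
    note: str = ("pairwise dissimilarities within a period share "
                 "individuals and are not independent")


def compare_periods(
    sets: Mapping[str, DissimilaritySet] | Mapping[str, np.ndarray],
) -> PeriodComparison:
    """Kruskal-Wallis omnibus test plus Dunn/Bonferroni pairwise
    comparisons of dissimilarity values across periods, and per-period
    means with normal-approximation 95% CIs.  Periods with fewer than two
    values are dropped with a warning."""
    groups: dict[str, np.ndarray] = {}
    for label, s in sets.items():
        vals = (s.values["bray_curtis"].to_numpy()
                if isinstance(s, DissimilaritySet) else np.asarray(s, dtype=float))
        if len(vals) < 2:
            warnings.warn(f"period {label!r} has <2 dissimilarity values; dropped")
            continue
        groups[label] = vals
    if len(groups) < 2:
        raise ValueError("need at least two periods with >=2 values each")
    h, p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups)
    z95 = stats.norm.ppf(0.975)
    mean_rows = []
    for label, vals in groups.items():
        m = float(np.mean(vals))
        half = z95 * float(np.std(vals, ddof=1)) / np.sqrt(len(vals))
        mean_rows.append((label, len(vals), m, m - half, m + half))
    means = pd.DataFrame(mean_rows, columns=["period", "n_pairs", "mean",
                                             "lo95", "hi95"])
    return PeriodComparison(float(h), float(p), dunn, means)
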