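"""Pre-peak / peak / post-peak segmentation of resource pulses and the
within-pulse consumption models.

The peak of a weekly availability series is the contiguous window
maximizing summed availability; the pre- and post-peak segments are the
immediately adjacent windows of the same length.  Individual consumption
is collapsed per segment to a binary ate-it-or-not flag and to the
individual's weighted occurrence of the pulse item, then modelled with a
logistic (binary) and a Poisson (amount) random-intercept GLMM with the
segment as fixed effect, weighted by each individual's number of scats.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .config import FOOD_ITEMS
from .diet import weighted_occurrence
from .glmm import GLMMResult, fit_glmm

__all__ = [
    "PulseDefinition",
    "SegmentModels",
    "peak_window",
    "segment_pulse",
    "consumption_proxy_window",
    "weekly_consumption",
    "segment_consumption",
    "segment_models",
]

SEGMENTS = ("pre", "peak", "post")


@dataclass(frozen=True)
class PulseDefinition:
    """Week ranges (inclusive) of the three pulse segments."""

    resource: str
    pre: tuple[int, int]
    peak: tuple[int, int]
    post: tuple[int, int]

    def __post_init__(self) -> None:
        L = self.peak_length
        for name, (a, b) in (("pre", self.pre), ("post", self.post)):
            if b - a + 1 != L:
                raise ValueError(f"{name} segment must equal peak length {L}")
        if not (self.pre[1] + 1 == self.peak[0] and
                self.peak[1] + 1 == self.post[0]):
            raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def peak_length(self) -> int:
        return self.peak[1] - self.peak[0] + 1

    def segment_of(self, week: int) -> str | None:
        for name in SEGMENTS:
            a, b = getattr(self, name)
            if a <= week <= b:
                return name
        return None

    @property
    def weeks(self) -> range:
        return range(self.pre[0], self.post[1] + 1)


# ----------------------------------------------------------------------
def _as_series(series: pd.Series | pd.DataFrame, resource: str | None = None
               ) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        if resource is not None:
            series = series[series["resource"] == resource]
        series = series.set_index("week")["mean_count"]
    s = series.sort_index()
    weeks = s.index.to_numpy()
    if len(weeks) > 1 and not np.all(np.diff(weeks) == 1):
        raise ValueError("availability weeks must be contiguous")
    if (s < 0).any():
        raise ValueError("availability counts must be nonnegative")
    return s


def peak_window(series: pd.Series | pd.DataFrame, window_weeks: int,
                resource: str | None = None) -> tuple[int, int]:
    """The contiguous ``window_weeks``-long window with the greatest summed
    availability (earliest window on ties).  Returns inclusive week
    bounds."""
    s = _as_series(series, resource)
    if window_weeks < 1:
        raise ValueError("window_weeks must be >= 1")
    if window_weeks > len(s):
        raise ValueError(f"window of {window_weeks} weeks exceeds series "
                         f"length {len(s)}")
    vals = s.to_numpy(dtype=float)
    sums = np.convolve(vals, np.ones(window_weeks), mode="valid")
    start = int(np.argmax(sums))  # argmax returns the first maximum
    w0 = int(s.index[start])
    return w0, w0 + window_weeks - 1


def segment_pulse(series: pd.Series | pd.DataFrame,
                  peak_weeks: tuple[int, int],
                  resource: str = "pulse") -> PulseDefinition:
    """Build the pre/peak/post segmentation around a chosen peak window:
    pre and post are the peak-length weeks immediately before and after."""
    s = _as_series(series, resource if isinstance(series, pd.DataFrame) else None)
    a, b = peak_weeks
    L = b - a + 1
    if L < 1:
        raise ValueError("empty peak window")
    lo, hi = int(s.index.min()), int(s.index.max())
    if a - L < lo or b + L > hi:
        raise ValueError(
            f"pre/post segments of length {L} around peak {peak_weeks} "
            f"extend beyond the series (weeks {lo}..{hi})")
    return PulseDefinition(resource, pre=(a - L, a - 1), peak=(a, b),
                           post=(b + 1, b + L))


def weekly_consumption(scores: pd.DataFrame, scats: pd.DataFrame,
                       item: str, value_col: str = "score") -> pd.Series:
    """Population-level weighted occurrence (%) of ``item`` per deposition
    week — the consumption series used as an availability proxy when the
    resource itself was not surveyed."""
    merged = scores.merge(scats[["sample_id", "week"]], on="sample_id")
    out = {}
    for week, grp in merged.groupby("week", sort=True):
        try:
            out[int(week)] = float(
                weighted_occurrence(grp, FOOD_ITEMS, value_col)[item])
        except ValueError:
            out[int(week)] = 0.0
    s = pd.Series(out).sort_index()
    # Fill unsampled weeks with zero consumption to keep weeks contiguous.
    full = np.arange(s.index.min(), s.index.max() + 1)
    return s.reindex(full, fill_value=0.0)


def consumption_proxy_window(consumption: pd.Series,
                             window_weeks: int = 6) -> tuple[int, int]:
    """The ``window_weeks`` of greatest summed consumption — identical to
    :func:`peak_window` applied to the consumption series."""
    return peak_window(consumption, window_weeks)


# ----------------------------------------------------------------------
def segment_consumption(
    scats: pd.DataFrame,
    scores: pd.DataFrame,
    pulse: PulseDefinition,
    item: str,
    value_col: str = "score",
) -> pd.DataFrame:
    """Collapse each individual's scats within each pulse segment.

    Returns one row per individual x segment with at least one scat:
    ``consumed`` (1 if any of the pulse item was eaten), ``amount`` (the
    individual's weighted occurrence % of the item within the segment),
    and ``n_scats`` (used to weight the models).
    """
    sub = scats.copy()
    sub["segment"] = sub["week"].map(pulse.segment_of)
    sub = sub[sub["segment"].notna()]
    merged = scores.merge(sub[["sample_id", "individual_id", "segment"]],
                          on="sample_id")
    rows = []
    for (ind, seg), grp in merged.groupby(["individual_id", "segment"],
                                          sort=True):
        n_scats = grp["sample_id"].nunique()
        try:
            amount = float(weighted_occurrence(grp, FOOD_ITEMS, value_col)[item])
        except ValueError:
            amount = 0.0
        rows.append((ind, seg, int(amount > 0), amount, n_scats))
    return pd.DataFrame(rows, columns=["individual_id", "segment",
                                       "consumed", "amount", "n_scats"])


@dataclass
class SegmentModels:
    binary: GLMMResult
    amount: GLMMResult
    contrasts: pd.DataFrame       # model, contrast, estimate, lo95, hi95, significant
    summary: pd.DataFrame         # segment, n_individuals, prop_consumed, mean_amount


def segment_models(records: pd.DataFrame,
                   weighted: bool = True) -> SegmentModels:
    """Fit the two within-pulse models on collapsed individual x segment
    records: a logistic GLMM on the binary consumed flag and a Poisson
    GLMM on the rounded weighted-occurrence amount, both with segment
    fixed effects (peak as reference), a random intercept per individual,
    and — by default — frequency weights equal to each record's number of
    scats.  Contrasts are pre-vs-peak and post-vs-peak with Wald 95% CIs.
    """
    segs = [s for s in SEGMENTS if s in set(records["segment"])]
    if len(segs) < 2:
        raise ValueError("need at least two segments with data")
    if records["individual_id"].nunique() < 2:
        raise ValueError("need at least two individuals")
    d = records.copy()
    cols = [np.ones(len(d))]
    names = ["intercept"]
    for seg in ("pre", "post"):
        if seg in segs:
            cols.append((d["segment"] == seg).to_numpy(dtype=float))
            names.append(f"{seg}_vs_peak")
    X = np.column_stack(cols)
    groups = d["individual_id"].to_numpy()
    w = d["n_scats"].to_numpy(dtype=float) if weighted else None

    yb = d["consumed"].to_numpy(dtype=float)
    binary = fit_glmm(yb, X, groups, family="binomial", weights=w, names=names)
    ya = np.round(d["amount"].to_numpy(dtype=float))
    amount = fit_glmm(ya, X, groups, family="poisson", weights=w, names=names)

    rows = []
    for model_name, res in (("binary", binary), ("amount", amount)):
        for contrast in ("pre_vs_peak", "post_vs_peak"):
            if contrast in names:
                est, lo, hi = res.coef(contrast)
                sig = res.converged and (lo > 0 or hi < 0)
            else:
                est = lo = hi = np.nan
                sig = False
            rows.append((model_name, contrast, est, lo, hi,
                         res.converged, sig))
    contrasts = pd.DataFrame(rows, columns=[
        "model", "contrast", "estimate", "lo95", "hi95", "converged",
        "significant"])
    summ = (d.groupby("segment", sort=False)
            .agg(n_individuals=("individual_id", "nunique"),
                 prop_consumed=("consumed", "mean"),
                 mean_amount=("amount", "mean"))
            .reindex([s for s in SEGMENTS if s in set(d["segment"])])
            .reset_index())
    return SegmentModels(binary=binary, amount=amount, contrasts=contrasts,
                         summary=summ)
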