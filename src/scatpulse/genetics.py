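"""Species ID, consensus microsatellite genotyping, sibling probability of
identity, and clustering of scat samples into individuals.

The pipeline mirrors standard non-invasive genotyping practice: scats are
first species-screened by fluorescent peak class, then genotyped in
repeated PCRs; per-locus consensus requires the identical allele pair in
at least two replicates; samples reaching consensus at >=7 of 10
autosomal loci with a resolved sex are matched into individuals when they
share >=5 loci and the sibling probability of identity over the shared
loci falls below 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AUTOSOMAL_LOCI, X_LOCUS, Y_LOCUS

__all__ = [
    "SpeciesCall",
    "ConsensusGenotype",
    "Exclusion",
    "Individual",
    "MatchResult",
    "species_id",
    "replicate_qc",
    "consensus_genotype",
    "consensus_from_replicates",
    "estimate_allele_frequencies",
    "pid_sib",
    "pid_sib_locus",
    "match_pair",
    "resolve_one_allele_mismatch",
    "cluster_individuals",
]

#: Minimum fluorescent intensity for a species peak to count at all.
SPECIES_PEAK_MIN = 100.0
#: Minimum coyote-class intensity for a sample to enter individual ID.
INDIVIDUAL_ID_MIN = 1000.0

AllelePair = tuple[int, int]
Genotype = dict[str, AllelePair]


@dataclass(frozen=True)
class SpeciesCall:
    sample_id: str
    species: str                       # coyote | bobcat | gray/red fox | unknown
    eligible_for_individual_id: bool

    def __post_init__(self) -> None:
        if self.eligible_for_individual_id and self.species != "coyote":
            raise ValueError("only coyote samples are eligible for individual ID")


@dataclass
class ConsensusGenotype:
    sample_id: str
    loci: Genotype                     # consensus allele pair per resolved locus
    sex: str                           # M | F | unresolved
    n_replicates_used: int

    @property
    def n_consensus_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class Exclusion:
    sample_id: str
    reason: str


@dataclass
class Individual:
    individual_id: str
    sex: str
    members: list[str]
    reference_sample: str


@dataclass(frozen=True)
class MatchResult:
    is_match: bool
    n_matching_loci: int
    n_conflicting_loci: int
    pid: float
    sex_compatible: bool
    one_allele_locus: str | None = None  # set when exactly one allele differs


# ----------------------------------------------------------------------
# Species identification
def species_id(sample_id: str, intensities: Mapping[str, float],
               coyote_class: str = "coyote") -> SpeciesCall:
    """Classify a scat's depositor from per-species fluorescent peak
    intensities.

    A coyote call requires a peak >=100 only at coyote fragment lengths;
    intensity >=1000 additionally qualifies the sample for individual ID.
    Peaks >=100 in more than one species class, or none at all, give
    ``unknown``.
    """
    for sp, v in intensities.items():
        if v < 0:
            raise ValueError(f"negative intensity for {sp!r}")
    present = {sp for sp, v in intensities.items() if v >= SPECIES_PEAK_MIN}
    if len(present) != 1:
        return SpeciesCall(sample_id, "unknown", False)
    (sp,) = present
    if sp != coyote_class:
        return SpeciesCall(sample_id, sp, False)
    eligible = intensities[coyote_class] >= INDIVIDUAL_ID_MIN
    return SpeciesCall(sample_id, "coyote", eligible)


# ----------------------------------------------------------------------
# Replicate QC and consensus
def replicate_qc(calls: Mapping[str, AllelePair | None],
                 loci: Sequence[str] = AUTOSOMAL_LOCI,
                 min_fraction: float = 0.4) -> bool:
    """Keep a PCR replicate iff at least ``min_fraction`` of the autosomal
    loci amplified (>=4 of 10 at the default)."""
    amplified = sum(1 for l in loci if calls.get(l) is not None)
    return amplified >= min_fraction * len(loci)


def _locus_consensus(pairs: list[AllelePair]) -> AllelePair | None:
    """Allele pair observed identically in >=2 replicates; None if no pair
    reaches two observations or two distinct pairs tie for support.

    Dropout awareness: a homozygote consensus is only accepted when no
    replicate showed a heterozygote carrying that allele — such a
    heterozygote is the classic signature of allelic dropout in the other
    replicates, so the locus is left unresolved rather than called as a
    (likely false) homozygote."""
    counts: dict[AllelePair, int] = {}
    for p in pairs:
        counts[p] = counts.get(p, 0) + 1
    supported = [(n, p) for p, n in counts.items() if n >= 2]
    if not supported:
        return None
    supported.sort(key=lambda t: (-t[0], t[1]))
    if len(supported) > 1 and supported[0][0] == supported[1][0]:
        return None  # conflicting equally-supported pairs
    best = supported[0][1]
    if best[0] == best[1]:
        a = best[0]
        for p in counts:
            if p[0] != p[1] and a in p:
                return None
    return best


def _sex_consensus(replicates: Sequence[Mapping[str, AllelePair | None]]) -> str:
    """Male iff the Y product is seen in >=2 replicates; female iff >=2
    replicates amplified X without Y; otherwise unresolved."""
    y_seen = sum(1 for r in replicates if r.get(Y_LOCUS) is not None)
    x_only = sum(1 for r in replicates
                 if r.get(X_LOCUS) is not None and r.get(Y_LOCUS) is None)
    male = y_seen >= 2
    female = x_only >= 2
    if male and not female:
        return "M"
    if female and not male:
        return "F"
    return "unresolved"


def consensus_genotype(
    sample_id: str,
    replicates: Sequence[Mapping[str, AllelePair | None]],
    loci: Sequence[str] = AUTOSOMAL_LOCI,
    min_consensus_loci: int = 7,
    max_replicates: int = 6,
) -> ConsensusGenotype | Exclusion:
    """Build a consensus genotype from QC-passing PCR replicates.

    Replication in the lab is sequential — an initial pair of PCRs plus
    1-4 repeats until consensus is reached at >=7/10 autosomal loci — but
    every replicate actually run contributes to the consensus, so all
    usable replicates (capped at ``max_replicates``) are pooled.  Samples
    whose pooled consensus covers <7 loci, or whose sex loci never
    resolve, are excluded.
    """
    usable = [r for r in replicates if replicate_qc(r, loci)][:max_replicates]
    if len(usable) < 2:
        return Exclusion(sample_id, "fewer than 2 usable replicates")
    cons: Genotype = {}
    for locus in loci:
        pairs = [r[locus] for r in usable if r.get(locus) is not None]
        c = _locus_consensus(pairs)  # type: ignore[arg-type]
        if c is not None:
            cons[locus] = c
    sex = _sex_consensus(usable)
    if len(cons) < min_consensus_loci:
        return Exclusion(sample_id,
                         f"consensus at {len(cons)} loci "
                         f"(<{min_consensus_loci})")
    if sex == "unresolved":
        return Exclusion(sample_id, "sex loci unresolved")
    return ConsensusGenotype(sample_id, cons, sex,
                             n_replicates_used=len(usable))


def consensus_from_replicates(
    replicates_df: pd.DataFrame,
    loci: Sequence[str] = AUTOSOMAL_LOCI,
    **kwargs,
) -> tuple[list[ConsensusGenotype], list[Exclusion]]:
    """Run consensus calling for every sample in a long replicate table
    (columns sample_id, replicate, locus, allele1, allele2)."""
    ok: list[ConsensusGenotype] = []
    excluded: list[Exclusion] = []
    for sid, grp in replicates_df.groupby("sample_id", sort=True):
        reps: list[dict[str, AllelePair | None]] = []
        for _, rep_grp in grp.groupby("replicate", sort=True):
            calls: dict[str, AllelePair | None] = {}
            for row in rep_grp.itertuples(index=False):
                if pd.isna(row.allele1) or pd.isna(row.allele2):
                    calls[row.locus] = None
                else:
                    a, b = int(row.allele1), int(row.allele2)
                    calls[row.locus] = (a, b) if a <= b else (b, a)
            reps.append(calls)
        result = consensus_genotype(str(sid), reps, loci, **kwargs)
        (ok if isinstance(result, ConsensusGenotype) else excluded).append(result)
    return ok, excluded


# ----------------------------------------------------------------------
# Allele frequencies and probability of identity (siblings)
def estimate_allele_frequencies(
    panel: pd.DataFrame,
    loci: Sequence[str] = AUTOSOMAL_LOCI,
) -> dict[str, dict[int, float]]:
    """Allele frequencies per locus from a reference-panel genotype table
    (columns individual_id, locus, allele1, allele2).  Frequencies always
    come from an independent tissue panel, never from the scat samples
    being matched."""
    freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        sub = panel[panel["locus"] == locus]
        if sub.empty:
            raise ValueError(f"reference panel has no genotypes at locus {locus!r}")
        alleles = np.concatenate([sub["allele1"].to_numpy(),
                                  sub["allele2"].to_numpy()]).astype(int)
        vals, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): c / total for a, c in zip(vals, counts)}
    return freqs


def pid_sib_locus(frequencies: Iterable[float]) -> float:
    """Single-locus probability that two full siblings share a genotype:
    0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4 with S2 = sum p_i^2, S4 = sum p_i^4."""
    p = np.asarray(list(frequencies), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


def pid_sib(freqs: Mapping[str, Mapping[int, float]],
            loci: Sequence[str]) -> float:
    """Multilocus sibling probability of identity: the product of per-locus
    values over ``loci`` (assumes linkage equilibrium)."""
    if not loci:
        raise ValueError("pid_sib requires at least one locus")
    out = 1.0
    for locus in loci:
        if locus not in freqs:
            raise KeyError(f"no allele frequencies for locus {locus!r}")
        out *= pid_sib_locus(freqs[locus].values())
    return out


# ----------------------------------------------------------------------
# Pairwise matching and clustering
def match_pair(
    g1: ConsensusGenotype,
    g2: ConsensusGenotype,
    freqs: Mapping[str, Mapping[int, float]],
    min_matching_loci: int = 5,
    pid_threshold: float = 0.01,
    pid_loci: str = "matching",
) -> MatchResult:
    """Decide whether two consensus genotypes represent the same individual.

    Matching loci are those resolved in both genotypes with identical
    allele pairs; loci resolved in only one sample are neutral.  A match
    requires no conflicting locus, >=5 matching loci, sibling PID below
    the threshold, and compatible sexes.  ``pid_loci`` selects whether the
    PID is computed over the matching loci (default, the evidence actually
    shared) or over all loci in the frequency table.
    """
    shared = sorted(set(g1.loci) & set(g2.loci))
    matching = [l for l in shared if g1.loci[l] == g2.loci[l]]
    conflicting = [l for l in shared if g1.loci[l] != g2.loci[l]]
    one_allele_locus = None
    if len(conflicting) == 1:
        l = conflicting[0]
        if len(set(g1.loci[l]) & set(g2.loci[l])) >= 1:
            one_allele_locus = l
    if pid_loci == "all":
        pid = pid_sib(freqs, sorted(freqs))
    else:
        pid = pid_sib(freqs, matching) if matching else 1.0
    sex_ok = g1.sex == g2.sex and g1.sex != "unresolved"
    is_match = (not conflicting and len(matching) >= min_matching_loci
                and pid < pid_threshold and sex_ok)
    return MatchResult(is_match, len(matching), len(conflicting), pid,
                       sex_ok, one_allele_locus)


def resolve_one_allele_mismatch(
    candidate: ConsensusGenotype,
    group: Individual,
    genotypes: Mapping[str, ConsensusGenotype],
    coordinates: Mapping[str, tuple[float, float]],
    radius_km: float = 1.0,
) -> bool:
    """Rescue rule for a candidate differing from a group by a single
    allele at a single locus: accept iff it matches the group's reference
    sample at >=7 loci, sexes match, and it was collected within
    ``radius_km`` of another sample already in the group."""
    ref = genotypes[group.reference_sample]
    shared = set(candidate.loci) & set(ref.loci)
    matching = [l for l in shared if candidate.loci[l] == ref.loci[l]]
    conflicting = [l for l in shared if candidate.loci[l] != ref.loci[l]]
    if len(conflicting) != 1:
        return False
    l = conflicting[0]
    if len(set(candidate.loci[l]) & set(ref.loci[l])) != 1:
        return False
    if len(matching) < 7:
        return False
    if candidate.sex != group.sex or candidate.sex == "unresolved":
        return False
    if candidate.sample_id not in coordinates:
        return False
    cx, cy = coordinates[candidate.sample_id]
    for member in group.members:
        if member not in coordinates:
            continue
        mx, my = coordinates[member]
        if math.hypot(cx - mx, cy - my) <= radius_km:
            return True
    return False


def cluster_individuals(
    genotypes: Sequence[ConsensusGenotype],
    freqs: Mapping[str, Mapping[int, float]],
    coordinates: Mapping[str, tuple[float, float]] | None = None,
    radius_km: float = 1.0,
    min_matching_loci: int = 5,
    pid_threshold: float = 0.01,
    pid_loci: str = "matching",
) -> tuple[list[Individual], dict[str, str], pd.DataFrame]:
    """Greedy individual assignment seeded by sample order.

    Samples are processed in the given (collection) order; the first
    sample of each group is its reference.  Each new sample is compared
    against every existing group's reference; it joins the group with the
    most matching loci (ties break to the earliest group), falling back to
    the one-allele rescue rule, else founds a new group.  Returns the
    groups, the sample->individual map, and an audit log of every pairwise
    decision.
    """
    coordinates = coordinates or {}
    groups: list[Individual] = []
    gmap: dict[str, ConsensusGenotype] = {g.sample_id: g for g in genotypes}
    assignment: dict[str, str] = {}
    audit_rows = []
    for g in genotypes:
        best: tuple[int, int] | None = None   # (n_matching, group index)
        route = "new"
        for gi, grp in enumerate(groups):
            res = match_pair(g, gmap[grp.reference_sample], freqs,
                             min_matching_loci, pid_threshold, pid_loci)
            audit_rows.append((g.sample_id, grp.individual_id,
                               res.n_matching_loci, res.n_conflicting_loci,
                               res.pid, res.is_match))
            if res.is_match and (best is None or res.n_matching_loci > best[0]):
                best = (res.n_matching_loci, gi)
        if best is None:
            for gi, grp in enumerate(groups):
                if resolve_one_allele_mismatch(g, grp, gmap, coordinates,
                                               radius_km):
                    ref = gmap[grp.reference_sample]
                    shared = set(g.loci) & set(ref.loci)
                    n_match = sum(1 for l in shared if g.loci[l] == ref.loci[l])
                    if best is None or n_match > best[0]:
                        best = (n_match, gi)
                        route = "one-allele-rule"
        if best is not None:
            grp = groups[best[1]]
            grp.members.append(g.sample_id)
            assignment[g.sample_id] = grp.individual_id
            if route == "new":
                route = "exact"
        else:
            ind_id = f"C{len(groups) + 1:03d}"
            groups.append(Individual(ind_id, g.sex, [g.sample_id], g.sample_id))
            assignment[g.sample_id] = ind_id
            route = "founder"
        audit_rows.append((g.sample_id, assignment[g.sample_id],
                           -1, -1, np.nan, route))
    audit = pd.DataFrame(audit_rows, columns=[
        "sample_id", "individual_id", "n_matching_loci",
        "n_conflicting_loci", "pid_sib", "outcome"])
    return groups, assignment, audit
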