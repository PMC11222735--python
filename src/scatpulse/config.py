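"""Simulation and analysis configuration.

The configuration mirrors the field-study design the synthetic generator
emulates: a multi-individual coyote population sampled by repeated scat
surveys, genotyped at 10 autosomal microsatellite loci plus 2 sex loci,
with seasonally varying diets driven by resource-availability pulses
(fawns, blackberries, persimmons).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "LocusSpec",
    "SeasonSpec",
    "PulseResourceSpec",
    "HairWidthParams",
    "SimulationConfig",
    "FOOD_ITEMS",
    "CORE_ITEMS",
    "AUTOSOMAL_LOCI",
    "X_LOCUS",
    "Y_LOCUS",
    "default_config",
    "load_config",
    "save_config",
]

#: The 11 food categories scored per scat (0-5 ordinal scale).
FOOD_ITEMS: tuple[str, ...] = (
    "deer",
    "wild_pig",
    "rabbit",
    "small_mammal",
    "other_mammal",
    "bird",
    "insect",
    "blackberry",
    "persimmon",
    "other_fruit_vegetation",
    "other",
)

#: The four most-consumed categories used for sex comparisons and
#: individual convergence profiles.  "vegetation" aggregates the three
#: fruit/vegetation score categories (see ``VEGETATION_PARTS``).
CORE_ITEMS: tuple[str, ...] = (
    "deer",
    "vegetation",
    "small_mammal",
    "rabbit",
)

#: Score categories pooled into the core "vegetation" category.
VEGETATION_PARTS: tuple[str, ...] = (
    "blackberry",
    "persimmon",
    "other_fruit_vegetation",
)

#: Canid microsatellite panel (10 autosomal loci) and sex-ID loci.
AUTOSOMAL_LOCI: tuple[str, ...] = (
    "2004",
    "CXX119",
    "CXX173",
    "FH2001",
    "FH2054",
    "FH2088",
    "FH2137",
    "FH2611",
    "FH2670",
    "FH3725",
)
X_LOCUS = "X-DB6"
Y_LOCUS = "Y-DB7"


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass(frozen=True)
class LocusSpec:
    """One autosomal microsatellite locus: allele fragment lengths and
    population frequencies (estimated in the field from a tissue panel)."""

    name: str
    alleles: tuple[int, ...]
    frequencies: tuple[float, ...]

    def validate(self) -> None:
        if len(self.alleles) != len(self.frequencies):
            raise ConfigError(
                f"locus {self.name}: {len(self.alleles)} alleles but "
                f"{len(self.frequencies)} frequencies"
            )
        if len(self.alleles) != len(set(self.alleles)):
            raise ConfigError(f"locus {self.name}: duplicate allele lengths")
        if any(f < 0 for f in self.frequencies):
            raise ConfigError(f"locus {self.name}: negative allele frequency")
        total = sum(self.frequencies)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"locus {self.name}: allele frequencies sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class SeasonSpec:
    """A survey season: label, inclusive week range, and the maximum scat
    age in days (set by the survey revisit interval: 14 d in winter/fall,
    4-7 d in summer when DNA degrades faster)."""

    label: str
    week_start: int
    week_end: int
    scat_age_max_days: int = 14

    def validate(self) -> None:
        if self.week_end < self.week_start:
            raise ConfigError(f"season {self.label}: empty week range")
        if self.scat_age_max_days < 0:
            raise ConfigError(f"season {self.label}: negative scat age")

    @property
    def weeks(self) -> range:
        return range(self.week_start, self.week_end + 1)


@dataclass(frozen=True)
class PulseResourceSpec:
    """A pulsed resource driving a diet item.

    ``vulnerability_weeks > 0`` models a birth pulse whose weekly
    availability is the count of offspring at most that many weeks old
    (fawns are counted while <=3 weeks old); ``0`` means availability
    follows the bell curve directly (ripe fruit counts).
    """

    resource: str
    item: str
    peak_week: int
    sd_weeks: float
    height: float
    vulnerability_weeks: int = 0
    effect_scale: float = 1.0

    def validate(self) -> None:
        if self.height < 0:
            raise ConfigError(f"pulse {self.resource}: negative height")
        if self.sd_weeks <= 0:
            raise ConfigError(f"pulse {self.resource}: sd_weeks must be > 0")
        if self.vulnerability_weeks < 0:
            raise ConfigError(f"pulse {self.resource}: negative window")
        if self.effect_scale < 0:
            raise ConfigError(f"pulse {self.resource}: negative effect_scale")


@dataclass(frozen=True)
class HairWidthParams:
    """Gaussian hair-width distributions (micrometres) for the two deer age
    classes; fawn hair is finer (<70 um likely fawn, >90 um likely adult)."""

    fawn_mean: float = 55.0
    fawn_sd: float = 8.0
    adult_mean: float = 105.0
    adult_sd: float = 10.0

    def validate(self) -> None:
        if self.fawn_sd <= 0 or self.adult_sd <= 0:
            raise ConfigError("hair width sd must be positive")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic scat-survey dataset."""

    n_individuals: int = 30
    loci: tuple[LocusSpec, ...] = ()
    dropout_rate: float = 0.10
    false_allele_rate: float = 0.01
    locus_failure_rate: float = 0.05
    n_replicates: int = 3
    seasons: tuple[SeasonSpec, ...] = ()
    diet_base: dict[str, dict[str, float]] = field(default_factory=dict)
    pulses: tuple[PulseResourceSpec, ...] = ()
    pulse_effect: float = 3.0
    diet_consistency: float = 1.0
    scats_per_individual_per_season: float = 3.0
    hair_width_params: HairWidthParams = field(default_factory=HairWidthParams)
    fawn_fraction_peak: float = 0.85
    n_transects: int = 10
    transect_length_km: float = 1.6
    home_scatter_km: float = 0.5
    study_start: _dt.date = _dt.date(2020, 1, 6)
    n_weeks: int = 52
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for p, name in (
            (self.dropout_rate, "dropout_rate"),
            (self.false_allele_rate, "false_allele_rate"),
            (self.locus_failure_rate, "locus_failure_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not self.loci:
            raise ConfigError("at least one locus required")
        for locus in self.loci:
            locus.validate()
        if not self.seasons:
            raise ConfigError("at least one season required")
        for season in self.seasons:
            season.validate()
            if season.label not in self.diet_base:
                raise ConfigError(f"no diet_base entry for season {season.label}")
        for season_label, conc in self.diet_base.items():
            for item, a in conc.items():
                if item not in FOOD_ITEMS:
                    raise ConfigError(
                        f"diet_base[{season_label}]: unknown item {item!r}"
                    )
                if a <= 0:
                    raise ConfigError(
                        f"diet_base[{season_label}][{item}]: Dirichlet "
                        f"concentration must be strictly positive"
                    )
            missing = set(FOOD_ITEMS) - set(conc)
            if missing:
                raise ConfigError(
                    f"diet_base[{season_label}]: missing items {sorted(missing)}"
                )
        for pulse in self.pulses:
            pulse.validate()
            if pulse.item not in FOOD_ITEMS:
                raise ConfigError(f"pulse {pulse.resource}: unknown item {pulse.item}")
            if not 0 <= pulse.peak_week < self.n_weeks:
                raise ConfigError(
                    f"pulse {pulse.resource}: peak week {pulse.peak_week} "
                    f"outside study weeks 0..{self.n_weeks - 1}"
                )
        self.hair_width_params.validate()
        if self.scats_per_individual_per_season <= 0:
            raise ConfigError("scats_per_individual_per_season must be > 0")
        if self.diet_consistency <= 0:
            raise ConfigError("diet_consistency must be > 0")
        if not 0.0 <= self.fawn_fraction_peak <= 1.0:
            raise ConfigError("fawn_fraction_peak must be in [0, 1]")

    # ------------------------------------------------------------------
    def week_of(self, date: _dt.date) -> int:
        return (date - self.study_start).days // 7

    def date_of_week(self, week: int) -> _dt.date:
        """Monday of the given study week."""
        return self.study_start + _dt.timedelta(weeks=week)

    def season_of_week(self, week: int) -> str | None:
        for s in self.seasons:
            if s.week_start <= week <= s.week_end:
                return s.label
        return None

    def locus_map(self) -> dict[str, LocusSpec]:
        return {l.name: l for l in self.loci}

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["loci"] = [
            {"name": l.name, "alleles": list(l.alleles),
             "frequencies": list(l.frequencies)}
            for l in self.loci
        ]
        d["seasons"] = [asdict(s) for s in self.seasons]
        d["pulses"] = [asdict(p) for p in self.pulses]
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "study_start" in d and isinstance(d["study_start"], str):
            d["study_start"] = _dt.date.fromisoformat(d["study_start"])
        if "loci" in d:
            d["loci"] = tuple(
                LocusSpec(
                    name=str(l["name"]),
                    alleles=tuple(int(a) for a in l["alleles"]),
                    frequencies=tuple(float(f) for f in l["frequencies"]),
                )
                for l in d["loci"]
            )
        if "seasons" in d:
            d["seasons"] = tuple(SeasonSpec(**s) for s in d["seasons"])
        if "pulses" in d:
            d["pulses"] = tuple(PulseResourceSpec(**p) for p in d["pulses"])
        if "hair_width_params" in d and isinstance(d["hair_width_params"], Mapping):
            d["hair_width_params"] = HairWidthParams(**d["hair_width_params"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ----------------------------------------------------------------------
# Default study conditions.
#
# Allele counts and frequency shapes are typical of canid microsatellite
# panels; frequencies are moderately even so that 5 matched loci sit near
# the sibling-identity threshold while the full 10-locus panel is far
# below it, mirroring the discriminating power a field panel needs.
_DEFAULT_FREQS: dict[str, Sequence[float]] = {
    "2004": (0.30, 0.25, 0.20, 0.15, 0.06, 0.04),
    "CXX119": (0.28, 0.24, 0.20, 0.14, 0.08, 0.06),
    "CXX173": (0.35, 0.25, 0.18, 0.12, 0.10),
    "FH2001": (0.25, 0.22, 0.18, 0.15, 0.12, 0.08),
    "FH2054": (0.30, 0.22, 0.18, 0.12, 0.08, 0.06, 0.04),
    "FH2088": (0.26, 0.24, 0.20, 0.16, 0.14),
    "FH2137": (0.22, 0.20, 0.18, 0.14, 0.10, 0.08, 0.05, 0.03),
    "FH2611": (0.30, 0.26, 0.22, 0.12, 0.10),
    "FH2670": (0.28, 0.22, 0.18, 0.14, 0.10, 0.08),
    "FH3725": (0.32, 0.24, 0.16, 0.12, 0.09, 0.07),
}

# Concentrations are kept small (totals near 2) so individual scats are
# dominated by one or two foods, as real carnivore scats are; this is
# what gives realistic between-individual dissimilarity (~0.5-0.7 in a
# pulse-free winter) and non-universal consumption of any single item.
_DEFAULT_DIET_BASE: dict[str, dict[str, float]] = {
    # Winter: small mammals dominate, almost no fruit.
    "winter": {
        "deer": 0.45, "wild_pig": 0.05, "rabbit": 0.18, "small_mammal": 0.55,
        "other_mammal": 0.10, "bird": 0.04, "insect": 0.02, "blackberry": 0.005,
        "persimmon": 0.02, "other_fruit_vegetation": 0.28, "other": 0.05,
    },
    # Summer: fawn (deer) and blackberry pulses, more vegetation/insects.
    "summer": {
        "deer": 0.10, "wild_pig": 0.05, "rabbit": 0.15, "small_mammal": 0.30,
        "other_mammal": 0.08, "bird": 0.05, "insect": 0.15, "blackberry": 0.15,
        "persimmon": 0.005, "other_fruit_vegetation": 0.45, "other": 0.06,
    },
    # Fall: persimmon pulse alongside deer.
    "fall": {
        "deer": 0.40, "wild_pig": 0.07, "rabbit": 0.13, "small_mammal": 0.35,
        "other_mammal": 0.09, "bird": 0.04, "insect": 0.06, "blackberry": 0.01,
        "persimmon": 0.20, "other_fruit_vegetation": 0.28, "other": 0.05,
    },
}


def default_config(**overrides: Any) -> SimulationConfig:
    """The default synthetic study: 30 individuals, 10 loci, three survey
    seasons with fawn, blackberry, and persimmon pulses.

    With ``study_start`` on Monday 2020-01-06, summer weeks 17-27 span
    May 4 - Jul 19 and the fawn birth pulse peaks in week 19 (May 18),
    matching the seasonal phenology the generator emulates.
    """
    base_allele = 120
    loci = []
    for i, (name, freqs) in enumerate(_DEFAULT_FREQS.items()):
        alleles = tuple(base_allele + 10 * i + 2 * j for j in range(len(freqs)))
        loci.append(LocusSpec(name=name, alleles=alleles, frequencies=tuple(freqs)))
    seasons = (
        SeasonSpec("winter", 1, 9, scat_age_max_days=14),
        SeasonSpec("summer", 17, 27, scat_age_max_days=7),
        SeasonSpec("fall", 40, 48, scat_age_max_days=14),
    )
    # Fawns couple to diet about twice as strongly as the fruit pulses
    # (per unit availability they are far more calorically rewarding).
    pulses = (
        PulseResourceSpec("fawn", item="deer", peak_week=19, sd_weeks=1.5,
                          height=10.0, vulnerability_weeks=3, effect_scale=2.0),
        PulseResourceSpec("blackberry", item="blackberry", peak_week=24,
                          sd_weeks=1.2, height=50.0),
        PulseResourceSpec("persimmon", item="persimmon", peak_week=42,
                          sd_weeks=2.0, height=30.0),
    )
    cfg = SimulationConfig(
        loci=tuple(loci),
        seasons=seasons,
        diet_base={k: dict(v) for k, v in _DEFAULT_DIET_BASE.items()},
        pulses=pulses,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
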