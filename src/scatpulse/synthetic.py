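"""Synthetic scat-survey generator with known ground truth.

Emulates the data a non-invasive carnivore diet study produces: a coyote
population with true multilocus microsatellite genotypes, repeated PCR
replicates with realistic genotyping error (allelic dropout, false
alleles, amplification failure), weekly resource-availability pulses, and
per-scat ordinal diet scores whose composition is coupled to availability.
Every downstream stage (consensus genotyping, individual clustering, diet
profiling, convergence inference) can therefore be scored against truth.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import (
    FOOD_ITEMS,
    ConfigError,
    SimulationConfig,
    X_LOCUS,
    Y_LOCUS,
)

__all__ = [
    "Population",
    "GroundTruth",
    "SyntheticDataset",
    "gen_population",
    "gen_availability",
    "gen_scats",
    "gen_replicates",
    "gen_all_replicates",
    "score_from_proportion",
    "simulate_dataset",
]

# Fixed fragment lengths of the sex-ID products: the X-linked product
# amplifies in both sexes, the Y-linked product only in males.
X_ALLELE = 101
Y_ALLELE = 83


@dataclass
class Population:
    """A set of individuals with sexes, home locations, and true genotypes."""

    individuals: pd.DataFrame  # individual_id, sex, home_x_km, home_y_km
    genotypes: pd.DataFrame    # individual_id, locus, allele1, allele2

    def genotype_map(self) -> dict[str, dict[str, tuple[int, int]]]:
        out: dict[str, dict[str, tuple[int, int]]] = {}
        for row in self.genotypes.itertuples(index=False):
            out.setdefault(row.individual_id, {})[row.locus] = (
                int(row.allele1), int(row.allele2))
        return out

    def sex_map(self) -> dict[str, str]:
        return dict(zip(self.individuals.individual_id, self.individuals.sex))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    scat_individual: dict[str, str]
    true_diets: pd.DataFrame          # sample_id, item, proportion
    deer_age: dict[str, str]          # sample_id -> fawn/adult/n-a
    availability: pd.DataFrame        # resource, week, mean_count

    def validate(self) -> None:
        sums = self.true_diets.groupby("sample_id")["proportion"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise AssertionError(f"diet proportions do not sum to 1: {bad.index[0]}")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    population: Population
    reference_panel: Population
    availability: pd.DataFrame
    scats: pd.DataFrame
    replicates: pd.DataFrame
    diet_scores: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(self.scats, out / "scats.csv")
        _write_csv(self.replicates, out / "genotypes_replicates.csv")
        _write_csv(self.diet_scores, out / "diet_scores.csv")
        _write_csv(self.availability, out / "availability.csv")
        panel = self.reference_panel
        panel_df = panel.genotypes.merge(
            panel.individuals[["individual_id", "sex"]], on="individual_id")
        _write_csv(panel_df, out / "reference_panel.csv")
        truth = {
            "scat_individual": self.truth.scat_individual,
            "deer_age": self.truth.deer_age,
            "true_diets": {
                sid: dict(zip(grp["item"], np.round(grp["proportion"], 12)))
                for sid, grp in self.truth.true_diets.groupby("sample_id")
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


# ----------------------------------------------------------------------
def gen_population(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    id_prefix: str = "I",
) -> Population:
    """Draw ``n`` individuals (default ``config.n_individuals``) with sexes
    ~1:1 and genotypes in Hardy-Weinberg proportions at the configured
    allele frequencies."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_individuals if n is None else n
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n)]
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    extent = config.n_transects * config.transect_length_km
    home_x = rng.uniform(0.0, extent, size=n)
    home_y = rng.normal(0.0, 0.05, size=n)
    individuals = pd.DataFrame({
        "individual_id": ids, "sex": sexes,
        "home_x_km": home_x, "home_y_km": home_y,
    })
    rows = []
    for locus in config.loci:
        alleles = np.asarray(locus.alleles)
        draws = rng.choice(alleles, size=(n, 2), p=np.asarray(locus.frequencies))
        draws.sort(axis=1)
        for i, ind in enumerate(ids):
            rows.append((ind, locus.name, int(draws[i, 0]), int(draws[i, 1])))
    genotypes = pd.DataFrame(rows, columns=["individual_id", "locus",
                                            "allele1", "allele2"])
    return Population(individuals=individuals, genotypes=genotypes)


def gen_availability(config: SimulationConfig) -> pd.DataFrame:
    """Weekly mean availability per pulsed resource.

    Each resource follows a Gaussian bell over study weeks; a birth pulse
    (``vulnerability_weeks`` w) is additionally convolved with a w-week
    box so that availability at week t counts offspring born in weeks
    t-w+1..t (i.e. still inside the vulnerability window).
    """
    config.validate()
    weeks = np.arange(config.n_weeks)
    frames = []
    for pulse in config.pulses:
        curve = pulse.height * np.exp(
            -0.5 * ((weeks - pulse.peak_week) / pulse.sd_weeks) ** 2)
        curve[curve < 1e-12] = 0.0
        if pulse.vulnerability_weeks > 0:
            curve = np.convolve(
                curve, np.ones(pulse.vulnerability_weeks))[: config.n_weeks]
        frames.append(pd.DataFrame({
            "resource": pulse.resource, "week": weeks, "mean_count": curve,
        }))
    if not frames:
        return pd.DataFrame(columns=["resource", "week", "mean_count"])
    return pd.concat(frames, ignore_index=True)


def score_from_proportion(p: float) -> int:
    """Ordinal 0-5 bin for a true volume proportion.

    0 absent; 1 <2%; 2 2-25%; 3 26-50%; 4 51-75%; 5 76-100%.  Upper bin
    edges are inclusive (a proportion of exactly 0.25 scores 2).
    """
    if p <= 0:
        return 0
    if p < 0.02:
        return 1
    if p <= 0.25:
        return 2
    if p <= 0.50:
        return 3
    if p <= 0.75:
        return 4
    return 5


def _pulse_scalers(config: SimulationConfig,
                   availability: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-pulse weekly multiplier applied to the item's Dirichlet
    concentration: 1 + pulse_effect * availability / max availability."""
    scalers: dict[str, np.ndarray] = {}
    for pulse in config.pulses:
        sub = availability[availability["resource"] == pulse.resource]
        if sub.empty:
            raise ConfigError(
                f"availability series missing for pulse {pulse.resource!r}")
        series = np.zeros(config.n_weeks)
        series[sub["week"].to_numpy()] = sub["mean_count"].to_numpy()
        peak = series.max()
        rel = series / peak if peak > 0 else series
        scalers[pulse.resource] = (
            1.0 + config.pulse_effect * pulse.effect_scale * rel)
    return scalers


def gen_scats(
    config: SimulationConfig,
    population: Population,
    availability: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate scat deposition, field records, and per-scat diet scores.

    Per season and individual, a Poisson number of scats is deposited at
    uniform weeks within the season.  Individuals are not interchangeable:
    each carries a seasonal preference vector drawn from the season's base
    Dirichlet (sharper for larger ``diet_consistency``), so between-
    individual diet variation exists even without a pulse.  A pulsed
    item's concentration gains a shared additive term — the season base
    times ``pulse_effect * effect_scale`` times that week's relative
    availability — so an active pulse pulls every individual toward the
    same food regardless of preference (this is the dietary-convergence
    mechanism; on average across individuals it equals scaling the base
    concentration by availability).  True proportions are binned to the
    ordinal 0-5 scale; deer-containing scats receive three hair-width
    measurements drawn from the true age class's distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    scalers = _pulse_scalers(config, availability)
    fawn_rel = None
    for pulse in config.pulses:
        if pulse.resource == "fawn":
            rel = scalers[pulse.resource] - 1.0
            top = rel.max()
            fawn_rel = rel / top if top > 0 else rel

    items = list(FOOD_ITEMS)
    hw = config.hair_width_params
    scat_rows, score_rows, diet_rows = [], [], []
    scat_individual: dict[str, str] = {}
    deer_age: dict[str, str] = {}
    counter = 0
    for season in config.seasons:
        base = np.array([config.diet_base[season.label][i] for i in items])
        weeks = np.array(list(season.weeks))
        for ind in population.individuals.itertuples(index=False):
            pref = rng.dirichlet(base * config.diet_consistency)
            alpha_ind = pref * base.sum()
            n_scats = rng.poisson(config.scats_per_individual_per_season)
            for _ in range(n_scats):
                counter += 1
                sid = f"S{counter:04d}"
                week = int(rng.choice(weeks))
                dep_date = config.date_of_week(week) + _dt.timedelta(
                    days=int(rng.integers(0, 7)))
                est_age = int(rng.integers(0, season.scat_age_max_days + 1))
                coll_date = dep_date + _dt.timedelta(days=est_age)
                x = float(np.clip(
                    ind.home_x_km + rng.normal(0.0, config.home_scatter_km),
                    0.0, config.n_transects * config.transect_length_km - 1e-9))
                y = float(rng.normal(0.0, 0.05))
                transect = int(x // config.transect_length_km) + 1

                alpha = alpha_ind.copy()
                for pulse in config.pulses:
                    k = items.index(pulse.item)
                    alpha[k] += (scalers[pulse.resource][week] - 1.0) * base[k]
                props = rng.dirichlet(alpha)
                scores = np.array([score_from_proportion(p) for p in props])

                k_deer = items.index("deer")
                age = "n/a"
                widths: tuple[float, ...] = ()
                hooves = False
                if scores[k_deer] > 0:
                    p_fawn = 0.0
                    if season.label == "summer" and fawn_rel is not None:
                        p_fawn = config.fawn_fraction_peak * float(fawn_rel[week])
                    age = "fawn" if rng.random() < p_fawn else "adult"
                    mu, sd = ((hw.fawn_mean, hw.fawn_sd) if age == "fawn"
                              else (hw.adult_mean, hw.adult_sd))
                    widths = tuple(np.round(rng.normal(mu, sd, size=3), 1))
                    hooves = bool(age == "fawn" and rng.random() < 0.3)
                deer_age[sid] = age
                scat_individual[sid] = ind.individual_id

                # Fluorescent species-ID peaks: all scats are coyote, but
                # DNA quality varies so some fall below the 1000 threshold.
                coy = float(np.round(np.exp(rng.normal(np.log(3000.0), 0.9)), 1))
                bob = float(np.round(rng.uniform(0, 80), 1)) if rng.random() < 0.2 else 0.0
                fox = 0.0
                conf = rng.choice(["low", "medium", "high"], p=[0.15, 0.35, 0.5])
                scat_rows.append((
                    sid, ind.individual_id, transect, coll_date.isoformat(),
                    est_age, dep_date.isoformat(), week, season.label,
                    "coyote", conf, round(x, 4), round(y, 4), coy, bob, fox))
                for k, item in enumerate(items):
                    if item == "deer" and scores[k] > 0:
                        score_rows.append((sid, item, int(scores[k]),
                                           widths[0], widths[1], widths[2],
                                           hooves))
                    else:
                        score_rows.append((sid, item, int(scores[k]),
                                           np.nan, np.nan, np.nan, np.nan))
                    diet_rows.append((sid, item, props[k]))

    scats = pd.DataFrame(scat_rows, columns=[
        "sample_id", "individual_id_true", "transect", "date", "est_age_days",
        "deposition_date", "week", "season", "field_species",
        "field_confidence", "x_km", "y_km",
        "intensity_coyote", "intensity_bobcat", "intensity_fox"])
    diet_scores = pd.DataFrame(score_rows, columns=[
        "sample_id", "item", "score", "hair_w1", "hair_w2", "hair_w3", "hooves"])
    true_diets = pd.DataFrame(diet_rows, columns=["sample_id", "item", "proportion"])
    truth = GroundTruth(scat_individual=scat_individual, true_diets=true_diets,
                        deer_age=deer_age, availability=availability)
    truth.validate()
    return scats, diet_scores, truth


# ----------------------------------------------------------------------
def gen_replicates(
    true_genotype: Mapping[str, tuple[int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
    sex: str,
    sample_id: str = "S0001",
) -> pd.DataFrame:
    """PCR replicates for one sample under the genotyping-error model.

    Per replicate and autosomal locus: with ``locus_failure_rate`` the
    locus yields nothing; otherwise each allele of a heterozygote drops
    out independently with ``dropout_rate`` (one dropout gives a false
    homozygote; if both drop, the replicate records a homozygote for one
    true allele at random); with ``false_allele_rate`` a random allele
    from the locus's set replaces one true allele.  Sex loci share the
    failure model; the Y product exists only in males.
    """
    locus_map = config.locus_map()
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for locus in locus_map:
            if locus not in true_genotype:
                continue
            if rng.random() < config.locus_failure_rate:
                rows.append((sample_id, rep, locus, np.nan, np.nan, True))
                continue
            a1, a2 = true_genotype[locus]
            if a1 != a2:
                d1 = rng.random() < config.dropout_rate
                d2 = rng.random() < config.dropout_rate
                if d1 and d2:
                    keep = a1 if rng.random() < 0.5 else a2
                    pair = [keep, keep]
                elif d1:
                    pair = [a2, a2]
                elif d2:
                    pair = [a1, a1]
                else:
                    pair = [a1, a2]
            else:
                pair = [a1, a2]
            if rng.random() < config.false_allele_rate:
                alleles = locus_map[locus].alleles
                pair[int(rng.integers(0, 2))] = int(rng.choice(np.asarray(alleles)))
            pair.sort()
            rows.append((sample_id, rep, locus, pair[0], pair[1], False))
        # Sex loci: presence/absence products with the same failure model.
        x_fail = rng.random() < config.locus_failure_rate
        rows.append((sample_id, rep, X_LOCUS,
                     np.nan if x_fail else X_ALLELE,
                     np.nan if x_fail else X_ALLELE, x_fail))
        if sex == "M":
            y_fail = rng.random() < config.locus_failure_rate
            rows.append((sample_id, rep, Y_LOCUS,
                         np.nan if y_fail else Y_ALLELE,
                         np.nan if y_fail else Y_ALLELE, y_fail))
        else:
            rows.append((sample_id, rep, Y_LOCUS, np.nan, np.nan, True))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "locus",
                                       "allele1", "allele2", "missing"])


def gen_all_replicates(
    scats: pd.DataFrame,
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gmap = population.genotype_map()
    smap = population.sex_map()
    frames = []
    for row in scats.itertuples(index=False):
        ind = row.individual_id_true
        frames.append(gen_replicates(gmap[ind], config, rng, smap[ind],
                                     sample_id=row.sample_id))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "replicate", "locus",
                                     "allele1", "allele2", "missing"])
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    n_panel: int = 89,
) -> SyntheticDataset:
    """Generate a complete synthetic study (population, tissue reference
    panel, availability, scats, replicates, diet scores, truth); optionally
    write the CSV/JSON bundle to ``out_dir``."""
    from .config import default_config

    config = default_config() if config is None else config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    population = gen_population(config, rng=rng)
    panel = gen_population(config, rng=rng, n=n_panel, id_prefix="T")
    availability = gen_availability(config)
    scats, diet_scores, truth = gen_scats(config, population, availability, rng=rng)
    replicates = gen_all_replicates(scats, population, config, rng=rng)
    ds = SyntheticDataset(
        config=config, population=population, reference_panel=panel,
        availability=availability, scats=scats, replicates=replicates,
        diet_scores=diet_scores, truth=truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
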