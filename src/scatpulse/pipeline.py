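"""End-to-end orchestration: simulate -> genotype -> diet -> convergence
-> pulse response, with CSV outputs at every stage.

Deliberately thin: every scientific step lives in its own module; this
module wires them together in the order a field analysis would run them
and fixes the output file layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import convergence as conv
from . import pulse as pulse_mod
from .config import SimulationConfig, default_config
from .diet import apply_zeroing, placeholder_correction_factors
from .genetics import (cluster_individuals, consensus_from_replicates,
                       estimate_allele_frequencies, species_id)
from .population import run_sex_models, seasonal_summary
from .synthetic import SyntheticDataset, simulate_dataset

__all__ = ["PipelineResult", "run_all"]

#: Peak lengths (weeks) used when segmenting each within-summer pulse.
PEAK_LENGTHS = {"fawn": 3, "blackberry": 2}


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    species_calls: pd.DataFrame
    individuals: pd.DataFrame          # sample_id, individual_id, sex, n_loci, match_route
    audit: pd.DataFrame
    exclusions: pd.DataFrame
    diet_profiles: pd.DataFrame
    pulse_share: pd.DataFrame
    sex_models: pd.DataFrame
    retained_scats: pd.DataFrame
    periods: list[conv.PeriodDefinition]
    dissimilarity: pd.DataFrame        # period, id_a, id_b, bray_curtis
    period_tests: pd.DataFrame
    period_means: pd.DataFrame
    pulse_segments: pd.DataFrame
    segment_consumption: pd.DataFrame
    segment_model_table: pd.DataFrame

    def write(self, out_dir: str | Path, include_dataset: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if include_dataset:
            self.dataset.write(out)
        frames = {
            "species_calls.csv": self.species_calls,
            "individuals.csv": self.individuals,
            "match_audit.csv": self.audit,
            "exclusions.csv": self.exclusions,
            "diet_profiles.csv": self.diet_profiles,
            "pulse_share.csv": self.pulse_share,
            "sex_models.csv": self.sex_models,
            "retained_scats.csv": self.retained_scats,
            "dissimilarity.csv": self.dissimilarity,
            "period_tests.csv": self.period_tests,
            "period_means.csv": self.period_means,
            "pulse_segments.csv": self.pulse_segments,
            "segment_consumption.csv": self.segment_consumption,
            "segment_models.csv": self.segment_model_table,
        }
        for name, df in frames.items():
            df.to_csv(out / name, index=False, float_format="%.10g")
        periods = pd.DataFrame(
            [(p.label, p.start.isoformat(), p.end.isoformat())
             for p in self.periods],
            columns=["period", "start", "end"])
        periods.to_csv(out / "periods.csv", index=False)


def _species_stage(scats: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in scats.itertuples(index=False):
        call = species_id(r.sample_id, {
            "coyote": r.intensity_coyote,
            "bobcat": r.intensity_bobcat,
            "gray/red fox": r.intensity_fox,
        })
        rows.append((call.sample_id, call.species,
                     call.eligible_for_individual_id))
    return pd.DataFrame(rows, columns=["sample_id", "species", "eligible"])


def run_all(
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    correction_table: dict[str, float] | None = None,
    radius_km: float = 1.0,
) -> PipelineResult:
    """Run the complete analysis on a freshly simulated dataset.

    All randomness (simulation, independence filter, winter-window draw)
    derives from ``seed``; identical seeds give byte-identical outputs.
    """
    config = default_config() if config is None else config
    ds = simulate_dataset(config, seed=seed)
    analysis_rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    correction_table = correction_table or placeholder_correction_factors()

    # --- species screen and individual identification -----------------
    species_calls = _species_stage(ds.scats)
    eligible = set(species_calls.loc[species_calls["eligible"], "sample_id"])
    reps = ds.replicates[ds.replicates["sample_id"].isin(eligible)]
    genotypes, excluded = consensus_from_replicates(reps)
    freqs = estimate_allele_frequencies(ds.reference_panel.genotypes)
    order = (ds.scats[ds.scats["sample_id"].isin({g.sample_id for g in genotypes})]
             .sort_values(["date", "sample_id"])["sample_id"].tolist())
    by_id = {g.sample_id: g for g in genotypes}
    ordered = [by_id[s] for s in order]
    coords = {r.sample_id: (r.x_km, r.y_km) for r in ds.scats.itertuples(index=False)}
    groups, assignment, audit = cluster_individuals(
        ordered, freqs, coords, radius_km=radius_km)
    route = (audit[audit["outcome"].isin(["founder", "exact", "one-allele-rule"])]
             .set_index("sample_id")["outcome"])
    individuals = pd.DataFrame(
        [(g.sample_id, assignment[g.sample_id], g.sex, g.n_consensus_loci,
          route.get(g.sample_id, "exact")) for g in ordered],
        columns=["sample_id", "individual_id", "sex", "n_loci", "match_route"])
    exclusions = pd.DataFrame([(e.sample_id, e.reason) for e in excluded],
                              columns=["sample_id", "reason"])

    # --- population diet ----------------------------------------------
    zeroed = apply_zeroing(ds.diet_scores)
    seasons_map = dict(zip(ds.scats["sample_id"], ds.scats["season"]))
    diet_profiles, pulse_share = seasonal_summary(zeroed, seasons_map,
                                                  correction_table)
    sex_map = {g.individual_id: g.sex for g in groups}
    meta = ds.scats[["sample_id", "season"]].copy()
    meta["individual_id"] = meta["sample_id"].map(assignment)
    meta = meta[meta["individual_id"].notna()]
    meta["sex"] = meta["individual_id"].map(sex_map)
    sex_models = run_sex_models(zeroed, meta)

    # --- convergence across periods -----------------------------------
    scats_ind = ds.scats.merge(
        meta[["sample_id", "individual_id"]], on="sample_id")
    retained, _removed = conv.independence_filter(scats_ind, analysis_rng)

    avail = ds.availability
    periods: list[conv.PeriodDefinition] = []
    for resource in ("fawn", "blackberry"):
        if (avail["resource"] == resource).any():
            w0, _ = pulse_mod.peak_window(avail, 6, resource=resource)
            periods.append(conv.PeriodDefinition.from_start(
                resource, config.date_of_week(w0)))
    persim = pulse_mod.weekly_consumption(zeroed, retained, "persimmon")
    w0, _ = pulse_mod.consumption_proxy_window(persim, 6)
    periods.append(conv.PeriodDefinition.from_start(
        "persimmon", config.date_of_week(w0)))
    winter = next(s for s in config.seasons if s.label == "winter")
    w0 = int(analysis_rng.integers(winter.week_start,
                                   max(winter.week_start, winter.week_end - 5) + 1))
    periods.append(conv.PeriodDefinition.from_start(
        "winter", config.date_of_week(w0)))

    tagged = conv.assign_periods(retained, periods)
    sets: dict[str, conv.DissimilaritySet] = {}
    diss_frames = []
    for p in periods:
        prof = conv.individual_period_profiles(zeroed, tagged, p)
        if len(prof) < 2:
            continue
        dset = conv.pairwise_dissimilarity(prof, p.label)
        sets[p.label] = dset
        df = dset.values.copy()
        df.insert(0, "period", p.label)
        diss_frames.append(df)
    dissimilarity = (pd.concat(diss_frames, ignore_index=True) if diss_frames
                     else pd.DataFrame(columns=["period", "id_a", "id_b",
                                                "bray_curtis"]))
    comparison = conv.compare_periods(sets)
    period_tests = comparison.dunn.copy()
    period_tests.insert(0, "kruskal_h", comparison.kruskal_h)
    period_tests.insert(1, "kruskal_p", comparison.kruskal_p)

    # --- within-pulse segment response --------------------------------
    seg_frames, cons_frames, model_frames = [], [], []
    for resource, item in (("fawn", "deer"), ("blackberry", "blackberry")):
        if not (avail["resource"] == resource).any():
            continue
        L = PEAK_LENGTHS[resource]
        peak = pulse_mod.peak_window(avail, L, resource=resource)
        pdef = pulse_mod.segment_pulse(avail, peak, resource=resource)
        seg_frames.append(pd.DataFrame(
            [(resource, seg, *getattr(pdef, seg)) for seg in pulse_mod.SEGMENTS],
            columns=["resource", "segment", "week_start", "week_end"]))
        records = pulse_mod.segment_consumption(retained, zeroed, pdef, item)
        rec = records.copy()
        rec.insert(0, "resource", resource)
        cons_frames.append(rec)
        try:
            models = pulse_mod.segment_models(records)
        except ValueError:
            continue
        mt = models.contrasts.copy()
        mt.insert(0, "resource", resource)
        model_frames.append(mt)
    pulse_segments = pd.concat(seg_frames, ignore_index=True)
    segment_consumption = pd.concat(cons_frames, ignore_index=True)
    segment_model_table = (pd.concat(model_frames, ignore_index=True)
                           if model_frames else pd.DataFrame())

    result = PipelineResult(
        dataset=ds, species_calls=species_calls, individuals=individuals,
        audit=audit, exclusions=exclusions, diet_profiles=diet_profiles,
        pulse_share=pulse_share, sex_models=sex_models,
        retained_scats=retained.drop(columns=["individual_id_true"],
                                     errors="ignore"),
        periods=periods, dissimilarity=dissimilarity,
        period_tests=period_tests, period_means=comparison.means,
        pulse_segments=pulse_segments,
        segment_consumption=segment_consumption,
        segment_model_table=segment_model_table)
    if out_dir is not None:
        result.write(out_dir)
    return result
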