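"""Generator invariants: determinism, Hardy-Weinberg sampling, pulse
coupling, ordinal binning, and the genotyping-error model."""

import numpy as np
import pandas as pd
import pytest

from scatpulse.config import (AUTOSOMAL_LOCI, FOOD_ITEMS, ConfigError,
                              LocusSpec, default_config)
from scatpulse.synthetic import (gen_all_replicates, gen_availability,
                                 gen_population, gen_replicates, gen_scats,
                                 score_from_proportion, simulate_dataset)


# ----------------------------------------------------------------------
def test_same_seed_gives_identical_datasets(small_config):
    a = simulate_dataset(small_config, seed=7)
    b = simulate_dataset(small_config, seed=7)
    for attr in ("scats", "replicates", "diet_scores", "availability"):
        pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
    assert a.truth.scat_individual == b.truth.scat_individual


def test_single_allele_locus_yields_homozygotes():
    cfg = default_config()
    cfg.loci = (LocusSpec("mono", alleles=(100,), frequencies=(1.0,)),) + cfg.loci[1:]
    pop = gen_population(cfg, rng=np.random.default_rng(0), n=50)
    mono = pop.genotypes.query("locus == 'mono'")
    assert (mono["allele1"] == 100).all() and (mono["allele2"] == 100).all()


def test_invalid_frequencies_error_names_locus():
    cfg = default_config()
    bad = LocusSpec("FHBAD", alleles=(1, 2), frequencies=(0.7, 0.7))
    cfg.loci = (bad,) + cfg.loci[1:]
    with pytest.raises(ConfigError, match="FHBAD"):
        gen_population(cfg, rng=np.random.default_rng(0))


def test_hardy_weinberg_heterozygosity():
    """Biallelic locus p=0.3: heterozygote fraction ~ 2pq = 0.42."""
    cfg = default_config()
    cfg.loci = (LocusSpec("bi", alleles=(100, 102), frequencies=(0.3, 0.7)),)
    n = 10_000
    pop = gen_population(cfg, rng=np.random.default_rng(5), n=n)
    het = (pop.genotypes["allele1"] != pop.genotypes["allele2"]).mean()
    se = np.sqrt(0.42 * 0.58 / n)
    assert abs(het - 0.42) < 3 * se


# ----------------------------------------------------------------------
def test_availability_peak_and_zero_height():
    cfg = default_config()
    from scatpulse.config import PulseResourceSpec
    cfg.pulses = (
        PulseResourceSpec("berry", item="blackberry", peak_week=20,
                          sd_weeks=2.0, height=10.0),
        PulseResourceSpec("nothing", item="persimmon", peak_week=30,
                          sd_weeks=2.0, height=0.0),
    )
    av = gen_availability(cfg)
    berry = av.query("resource == 'berry'").set_index("week")["mean_count"]
    assert berry.idxmax() == 20 and berry.max() == pytest.approx(10.0)
    nothing = av.query("resource == 'nothing'")["mean_count"]
    assert (nothing == 0).all()


def test_birth_pulse_convolution_window():
    """Births in a single week w with a 3-week vulnerability window give
    availability at exactly weeks w..w+2."""
    cfg = default_config()
    from scatpulse.config import PulseResourceSpec
    cfg.pulses = (PulseResourceSpec("fawn", item="deer", peak_week=20,
                                    sd_weeks=1e-6, height=5.0,
                                    vulnerability_weeks=3),)
    av = gen_availability(cfg).query("resource == 'fawn'")
    nonzero = set(av.loc[av["mean_count"] > 0, "week"])
    assert nonzero == {20, 21, 22}


# ----------------------------------------------------------------------
@pytest.mark.parametrize("proportion, score", [
    (0.0, 0), (0.01, 1), (0.02, 2), (0.25, 2), (0.26, 3),
    (0.50, 3), (0.60, 4), (0.75, 4), (0.76, 5), (1.0, 5),
])
def test_ordinal_binning(proportion, score):
    assert score_from_proportion(proportion) == score


def _scat_setup(**overrides):
    cfg = default_config(n_individuals=20, **overrides)
    rng = np.random.default_rng(3)
    pop = gen_population(cfg, rng=rng)
    av = gen_availability(cfg)
    return cfg, pop, av, rng


def test_true_diets_sum_to_one_and_scores_consistent():
    cfg, pop, av, rng = _scat_setup()
    scats, scores, truth = gen_scats(cfg, pop, av, rng=rng)
    sums = truth.true_diets.groupby("sample_id")["proportion"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    merged = scores.merge(truth.true_diets, on=["sample_id", "item"])
    zero_prop = merged[merged["proportion"] == 0]
    assert (zero_prop["score"] == 0).all()
    assert set(scats["sample_id"]) == set(truth.scat_individual)


def test_pulse_effect_monotone_in_peak_score():
    """Stronger pulse coupling raises the expected pulse-item score in
    peak weeks (three effect levels)."""
    means = []
    for effect in (0.0, 2.0, 6.0):
        cfg, pop, av, rng = _scat_setup(pulse_effect=effect,
                                        scats_per_individual_per_season=6.0)
        scats, scores, _ = gen_scats(cfg, pop, av, rng=rng)
        peak_weeks = set(range(22, 27))  # around the blackberry peak
        in_peak = scats.loc[scats["week"].isin(peak_weeks), "sample_id"]
        bb = scores[(scores["item"] == "blackberry")
                    & scores["sample_id"].isin(set(in_peak))]
        means.append(bb["score"].mean())
    assert means[0] < means[1] < means[2]


def test_zero_pulse_effect_gives_flat_weekly_scores():
    cfg, pop, av, rng = _scat_setup(pulse_effect=0.0,
                                    scats_per_individual_per_season=8.0)
    scats, scores, _ = gen_scats(cfg, pop, av, rng=rng)
    summer = scats.query("season == 'summer'")
    bb = scores[scores["item"] == "blackberry"].set_index("sample_id")["score"]
    weekly = summer.assign(score=summer["sample_id"].map(bb)).groupby("week")["score"].mean()
    # No trend: early-summer and late-summer means statistically equal.
    early = weekly.iloc[: len(weekly) // 2].mean()
    late = weekly.iloc[len(weekly) // 2:].mean()
    assert abs(early - late) < 0.3


# ----------------------------------------------------------------------
def test_error_free_replicates_match_truth(small_config):
    cfg = default_config(dropout_rate=0.0, false_allele_rate=0.0,
                         locus_failure_rate=0.0, n_individuals=5)
    rng = np.random.default_rng(0)
    pop = gen_population(cfg, rng=rng)
    gmap = pop.genotype_map()
    ind = pop.individuals.individual_id.iloc[0]
    reps = gen_replicates(gmap[ind], cfg, rng, sex="M")
    auto = reps[reps["locus"].isin(AUTOSOMAL_LOCI)]
    assert not auto["missing"].any()
    for row in auto.itertuples(index=False):
        assert (row.allele1, row.allele2) == tuple(sorted(gmap[ind][row.locus]))


def test_total_failure_gives_all_missing():
    cfg = default_config(locus_failure_rate=1.0, n_individuals=2)
    rng = np.random.default_rng(0)
    pop = gen_population(cfg, rng=rng)
    ind = pop.individuals.individual_id.iloc[0]
    reps = gen_replicates(pop.genotype_map()[ind], cfg, rng, sex="F")
    assert reps["missing"].all()


def test_dropout_false_homozygote_rate():
    """Heterozygote, per-allele dropout 0.2: false-homozygote rate per
    replicate is 2(0.2)(0.8) + 0.04 = 0.36."""
    cfg = default_config(dropout_rate=0.2, false_allele_rate=0.0,
                         locus_failure_rate=0.0, n_replicates=1,
                         n_individuals=2)
    cfg.loci = (LocusSpec("bi", alleles=(100, 102), frequencies=(0.5, 0.5)),)
    rng = np.random.default_rng(42)
    true = {"bi": (100, 102)}
    n = 10_000
    hom = 0
    for _ in range(n):
        reps = gen_replicates(true, cfg, rng, sex="F")
        call = reps[reps["locus"] == "bi"].iloc[0]
        if call.allele1 == call.allele2:
            hom += 1
    se = np.sqrt(0.36 * 0.64 / n)
    assert abs(hom / n - 0.36) < 3 * se


def test_replicate_counts(dataset):
    per = dataset.replicates.groupby("sample_id")["replicate"].nunique()
    assert (per == dataset.config.n_replicates).all()
    assert gen_all_replicates(dataset.scats.iloc[:0], dataset.population,
                              dataset.config).empty
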