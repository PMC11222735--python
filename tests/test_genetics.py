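"""Species ID, consensus calling, sibling PID, and individual clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scatpulse.config import AUTOSOMAL_LOCI, X_LOCUS, Y_LOCUS, default_config
from scatpulse.genetics import (ConsensusGenotype, Exclusion, Individual,
                                cluster_individuals, consensus_genotype,
                                estimate_allele_frequencies, match_pair,
                                pid_sib, pid_sib_locus, replicate_qc,
                                resolve_one_allele_mismatch, species_id)
from scatpulse.experiments import identification_experiment


# ----------------------------------------------------------------------
# Independent oracle: enumerate parental genotype pairs under HWE and the
# Mendelian offspring distribution, and sum P(two full sibs identical).
def pid_sib_bruteforce(freqs: dict[int, float]) -> float:
    alleles = sorted(freqs)
    genotypes = [(a, b) for i, a in enumerate(alleles)
                 for b in alleles[i:]]

    def hwe(g):
        a, b = g
        return freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]

    total = 0.0
    for gm in genotypes:
        for gf in genotypes:
            offspring: dict[tuple[int, int], float] = {}
            for am in gm:
                for af in gf:
                    child = tuple(sorted((am, af)))
                    offspring[child] = offspring.get(child, 0.0) + 0.25
            total += hwe(gm) * hwe(gf) * sum(p ** 2 for p in offspring.values())
    return total


@pytest.mark.parametrize("freqs, expected", [
    ({1: 1.0}, 1.0),                    # monomorphic: sibs always identical
    ({1: 0.5, 2: 0.5}, 0.59375),        # biallelic, equal frequencies
])
def test_pid_sib_locus_known_values(freqs, expected):
    assert pid_sib_locus(freqs.values()) == pytest.approx(expected, abs=1e-12)
    assert pid_sib_bruteforce(freqs) == pytest.approx(expected, abs=1e-12)


def test_pid_sib_matches_enumeration_oracle():
    rng = np.random.default_rng(99)
    for _ in range(25):
        k = int(rng.integers(2, 6))
        p = rng.dirichlet(np.ones(k))
        freqs = {i: float(pi) for i, pi in enumerate(p)}
        assert pid_sib_locus(freqs.values()) == pytest.approx(
            pid_sib_bruteforce(freqs), abs=1e-12)


def test_pid_sib_product_rule_and_threshold():
    freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(10)}
    ten = pid_sib(freqs, list(freqs))
    assert ten == pytest.approx(0.59375 ** 10, rel=1e-12)
    assert ten < 0.01  # ten such loci clear the matching threshold


@given(st.integers(1, 9))
@settings(derandomize=True, max_examples=20, deadline=None)
def test_pid_sib_non_increasing_in_loci(n_loci):
    freqs = {f"L{i}": {1: 0.4, 2: 0.3, 3: 0.3} for i in range(10)}
    loci = [f"L{i}" for i in range(n_loci)]
    assert pid_sib(freqs, loci + [f"L{n_loci}"]) <= pid_sib(freqs, loci)


def test_pid_sib_empty_loci_errors():
    with pytest.raises(ValueError):
        pid_sib({"L0": {1: 1.0}}, [])


# ----------------------------------------------------------------------
@pytest.mark.parametrize("intensities, species, eligible", [
    ({"coyote": 1500, "bobcat": 0, "gray/red fox": 0}, "coyote", True),
    ({"coyote": 500, "bobcat": 0, "gray/red fox": 0}, "coyote", False),
    ({"coyote": 150, "bobcat": 150, "gray/red fox": 0}, "unknown", False),
    ({"coyote": 50, "bobcat": 40, "gray/red fox": 0}, "unknown", False),
    ({"coyote": 0, "bobcat": 2000, "gray/red fox": 0}, "bobcat", False),
])
def test_species_id(intensities, species, eligible):
    call = species_id("S1", intensities)
    assert (call.species, call.eligible_for_individual_id) == (species, eligible)


def _calls(n_amplified):
    calls = {}
    for i, locus in enumerate(AUTOSOMAL_LOCI):
        calls[locus] = (100, 102) if i < n_amplified else None
    return calls


@pytest.mark.parametrize("n_amplified, keep", [(3, False), (4, True), (10, True)])
def test_replicate_qc_threshold(n_amplified, keep):
    assert replicate_qc(_calls(n_amplified)) is keep


# ----------------------------------------------------------------------
def _replicate(genotype, sex="M", loci=AUTOSOMAL_LOCI):
    calls = {l: genotype.get(l) for l in loci}
    calls[X_LOCUS] = (101, 101)
    calls[Y_LOCUS] = (83, 83) if sex == "M" else None
    return calls


def test_consensus_two_identical_replicates():
    genotype = {l: (100 + i, 102 + i) for i, l in enumerate(AUTOSOMAL_LOCI[:8])}
    reps = [_replicate(genotype), _replicate(genotype)]
    result = consensus_genotype("S1", reps)
    assert isinstance(result, ConsensusGenotype)
    assert result.n_consensus_loci == 8
    assert result.sex == "M"


def test_consensus_below_seven_loci_excluded():
    genotype = {l: (100, 102) for l in AUTOSOMAL_LOCI[:6]}
    reps = [_replicate(genotype)] * 6
    result = consensus_genotype("S1", reps)
    assert isinstance(result, Exclusion)
    assert "6 loci" in result.reason


def test_consensus_sex_conflict_excluded():
    genotype = {l: (100, 102) for l in AUTOSOMAL_LOCI[:9]}
    reps = [_replicate(genotype, sex="M"), _replicate(genotype, sex="F"),
            _replicate(genotype, sex="M"), _replicate(genotype, sex="F")]
    result = consensus_genotype("S1", reps)
    assert isinstance(result, Exclusion)
    assert "sex" in result.reason


def test_consensus_rejects_dropout_contradicted_homozygote():
    """A homozygote seen twice is not called when a heterozygote carrying
    that allele was also observed (allelic-dropout signature)."""
    het = {AUTOSOMAL_LOCI[0]: (100, 102)}
    hom = {AUTOSOMAL_LOCI[0]: (100, 100)}
    full = {l: (200, 202) for l in AUTOSOMAL_LOCI[1:]}
    reps = [_replicate({**full, **hom}), _replicate({**full, **hom}),
            _replicate({**full, **het})]
    result = consensus_genotype("S1", reps)
    assert isinstance(result, ConsensusGenotype)
    assert AUTOSOMAL_LOCI[0] not in result.loci


def test_consensus_needs_two_usable_replicates():
    genotype = {l: (100, 102) for l in AUTOSOMAL_LOCI}
    result = consensus_genotype("S1", [_replicate(genotype)])
    assert isinstance(result, Exclusion)


# ----------------------------------------------------------------------
def _freqs(n_loci=10, alleles=(100, 102, 104, 106)):
    p = 1.0 / len(alleles)
    return {l: {a: p for a in alleles} for l in AUTOSOMAL_LOCI[:n_loci]}


def _cg(sample_id, loci, sex="M"):
    return ConsensusGenotype(sample_id, dict(loci), sex, n_replicates_used=2)


def test_match_pair_decisions():
    freqs = _freqs()
    g = {l: (100, 102) for l in AUTOSOMAL_LOCI[:7]}
    a, b = _cg("A", g), _cg("B", g)
    res = match_pair(a, b, freqs)
    assert res.is_match and res.n_matching_loci == 7 and res.pid < 0.01

    # only 4 jointly resolved loci: below the >=5 matching threshold
    c = _cg("C", {l: (100, 102) for l in AUTOSOMAL_LOCI[:4]})
    assert not match_pair(a, c, freqs).is_match

    # matching loci but PID above threshold (few, low-information loci)
    loose = {l: {100: 0.99, 102: 0.01} for l in AUTOSOMAL_LOCI}
    d1 = _cg("D1", {l: (100, 100) for l in AUTOSOMAL_LOCI[:6]})
    d2 = _cg("D2", {l: (100, 100) for l in AUTOSOMAL_LOCI[:6]})
    res = match_pair(d1, d2, loose)
    assert res.pid > 0.01 and not res.is_match

    # sex incompatibility blocks an otherwise perfect match
    e = _cg("E", g, sex="F")
    assert not match_pair(a, e, freqs).is_match


def test_one_allele_rescue_rules():
    freqs = _freqs()
    base = {l: (100, 102) for l in AUTOSOMAL_LOCI[:9]}
    ref = _cg("REF", base)
    group = Individual("C001", "M", ["REF"], "REF")
    genotypes = {"REF": ref}
    coords = {"REF": (0.0, 0.0), "CAND": (0.3, 0.0)}

    # one allele differs at one locus, 8 matching, same sex, 300 m away
    cand_loci = dict(base)
    cand_loci[AUTOSOMAL_LOCI[0]] = (100, 104)
    cand = _cg("CAND", cand_loci)
    genotypes["CAND"] = cand
    assert resolve_one_allele_mismatch(cand, group, genotypes, coords)

    # opposite sex
    cand_f = _cg("CAND", cand_loci, sex="F")
    assert not resolve_one_allele_mismatch(cand_f, group, genotypes, coords)

    # only 6 matching loci
    few = {l: (100, 102) for l in AUTOSOMAL_LOCI[:7]}
    few[AUTOSOMAL_LOCI[0]] = (100, 104)
    cand_few = _cg("CAND", few)
    assert not resolve_one_allele_mismatch(cand_few, group, genotypes, coords)

    # too far away
    coords_far = {"REF": (0.0, 0.0), "CAND": (5.0, 0.0)}
    assert not resolve_one_allele_mismatch(cand, group, genotypes, coords_far)


# ----------------------------------------------------------------------
def test_cluster_identical_and_distinct():
    freqs = _freqs()
    g = {l: (100, 102) for l in AUTOSOMAL_LOCI}
    a, b = _cg("A", g), _cg("B", g)
    other = dict(g)
    for l in AUTOSOMAL_LOCI[:3]:
        other[l] = (104, 106)
    c = _cg("C", other)
    groups, assignment, audit = cluster_individuals([a, b, c], freqs)
    assert assignment["A"] == assignment["B"] != assignment["C"]
    assert len(groups) == 2
    assert groups[0].reference_sample == "A"


def test_cluster_deterministic_given_order():
    freqs = _freqs()
    gs = [_cg(f"S{i}", {l: (100, 102) for l in AUTOSOMAL_LOCI})
          for i in range(4)]
    _, a1, _ = cluster_individuals(list(gs), freqs)
    _, a2, _ = cluster_individuals(list(gs), freqs)
    assert a1 == a2


def test_error_free_clustering_recovers_truth_exactly():
    res = identification_experiment(seed=5, dropout_rate=0.0,
                                    false_allele_rate=0.0,
                                    locus_failure_rate=0.0)
    assert res.recovery == 1.0
    assert res.n_merged_groups == 0
    assert res.n_groups == 30


def test_estimate_allele_frequencies_sums_to_one(dataset):
    freqs = estimate_allele_frequencies(dataset.reference_panel.genotypes)
    assert set(freqs) == set(AUTOSOMAL_LOCI)
    for locus, f in freqs.items():
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in f.values())
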