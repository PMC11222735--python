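# scatpulse

Non-invasive genetic individual identification and resource-pulse
diet-convergence analysis for carnivore scat surveys.

Repeated scat-transect surveys are a cheap window into carnivore ecology:
each scat yields (i) degraded DNA, enough to genotype a microsatellite
panel across replicate PCRs and assign the scat to an individual animal,
and (ii) undigested prey remains, scorable into ordinal diet categories.
`scatpulse` implements the full analysis chain for such a study of an
omnivorous canid (coyote) population exposed to brief, high-magnitude
food pulses — fawn births, blackberry and persimmon ripening — together
with a synthetic-data generator with known ground truth, so every stage
is testable without field data.

## What it computes

**Individual identification.** Species is screened from fluorescent peak
classes (peaks ≥100 only at coyote fragment lengths; ≥1000 to enter
individual ID). Replicate genotypes at 10 autosomal microsatellite loci
plus 2 sex loci are reduced to a consensus (a locus needs the identical
allele pair in ≥2 replicates, with dropout-aware rejection of
contradicted homozygotes; samples need ≥7/10 loci and a resolved sex).
Samples are clustered into individuals when they match at ≥5 loci with a
sibling probability of identity below 0.01 and compatible sexes, where
per locus

    PID_sib = 1/4 + (1/2)·S2 + (1/2)·S2² − (1/4)·S4,
    S2 = Σᵢ pᵢ², S4 = Σᵢ pᵢ⁴,

multiplied across loci (allele frequencies pᵢ from an independent tissue
reference panel). A one-allele mismatch is rescued when the sample
matches the group's reference at ≥7 loci, same sex, and was collected
nearby.

**Diet.** Per-scat 0–5 volume scores (0 absent, 1 trace <2%, 2 = 2–25%,
3 = 26–50%, 4 = 51–75%, 5 = 76–100%) over 11 food categories; trace
scores zeroed, grass-like level-2 scores zeroed; optional digestion
correction by feeding-trial factors. The percent weighted occurrence of
item *i* in a stratum is

    100 · Σₛ X_is·Y_is / Σᵢ Σₛ X_is·Y_is

with X presence and Y the scaled (0–5) or corrected (0–31.5) amount.
Deer age class comes from hair widths (mean <70 µm fawn, >90 µm adult,
70–90 µm ambiguous with a summer hoof override).

**Convergence.** After an independence filter (same individual, transect,
day, estimated ages within 1 day → one scat kept), each individual gets
a 4-food profile (deer, vegetation, small mammal, rabbit) per 6-week
pulse period; pairwise Bray–Curtis dissimilarity Σ|p−q| / Σ(p+q) is
compared across periods by Kruskal–Wallis plus Dunn tests with
Bonferroni correction. Within each summer pulse, pre/peak/post segments
from the weekly availability series feed a logistic and a Poisson mixed
model (segment fixed effect, individual random intercept, weighted by
scat count), fitted by adaptive Gauss–Hermite maximum likelihood.

## Worked example

```bash
python examples/04_dietary_convergence.py
```

prints, for the default simulated study (seed 1):

```
mean pairwise Bray-Curtis dissimilarity per 6-week period
(0 identical diets, 1 disjoint; winter is the pulse-free control):
    period  n_pairs  mean  lo95  hi95
      fawn      325 0.496 0.469 0.523
blackberry      231 0.476 0.445 0.507
 persimmon      190 0.429 0.402 0.456
    winter      253 0.610 0.578 0.642

Kruskal-Wallis H = 58.7, p = 1.1e-12
```

Individual diets are substantially less dissimilar during every resource
pulse than in the pulse-free winter (Dunn/Bonferroni p < 0.05 for each
pulse-vs-winter contrast): the population converges on whichever food is
pulsing, then diverges into individual specialisations when the pulse is
gone. `examples/01–05` walk through simulation, individual ID, seasonal
diet, convergence, and the within-pulse segment models; the `scatpulse`
CLI (`simulate`, `genotype`, `diet`, `all`) wraps the same stages for
shell use, e.g.

```bash
scatpulse all --config examples/fixture_config.yaml --seed 0 --out out/
```

## Caveats

Pairwise dissimilarities within a period share individuals, so the rank
tests applied to them (as is standard in this literature) are
anticonservative; `convergence.disjoint_pair_dissimilarity` provides an
independent-pairs alternative that restores nominal calibration at the
cost of fewer pairs. Digestion-correction factors bundled here are
labelled placeholders — supply measured values for real analyses. See
`docs/methods.md` for the full model description and limitations.
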