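# Methods

This note documents the models and procedures implemented in
`scatpulse`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic experiments do and do not demonstrate.

## 1. Synthetic study design

The generator (`scatpulse.synthetic`) emulates a multi-year scat-survey
study of an omnivorous canid population:

- **Population.** `n_individuals` (default 30) with sexes ~1:1,
  multilocus genotypes drawn in Hardy–Weinberg proportions at 10
  autosomal microsatellite loci (5–8 alleles each; frequency profiles
  typical of canid panels, chosen so that 5 matched loci sit near the
  sibling-identity threshold of 0.01 while the full panel is far below
  it), and a home coordinate on a 16-km transect line. An independent
  89-individual tissue panel supplies allele-frequency estimates, never
  the scat samples themselves.
- **Surveys.** Three seasons (winter weeks 1–9, summer 17–27, fall
  40–48 of a 52-week study year starting Monday 2020-01-06). Scat
  estimated age is uniform on 0–14 days in winter/fall and 0–7 in summer,
  matching the seasonal revisit cadence; collection date = deposition
  date + estimated age. Scats per individual per season are Poisson with
  mean 3.
- **Availability pulses.** Each pulsed resource follows a Gaussian bell
  over weeks (fawn births peak week 19, blackberry week 24, persimmon
  week 42). Fawn availability is the birth curve convolved with a 3-week
  box: the count of fawns at most 3 weeks old, the age window in which
  they are vulnerable.
- **Diet.** Scats are ordinal 0–5 scores over 11 food categories.
  True per-scat compositions are Dirichlet draws. Two deliberate
  departures from the simplest i.i.d. design:
  1. *Individual preference.* Each individual carries a seasonal
     preference vector drawn from the season's base Dirichlet
     (`diet_consistency` scales its sharpness, default 1). Scat-level
     concentrations are the preference rescaled to the season's total.
     Without this layer all individuals are exchangeable and winter
     between-individual dissimilarity collapses to sampling noise;
     with it, the pulse-free winter shows the individual specialisation
     (mean pairwise Bray–Curtis ≈ 0.6) that real populations show.
  2. *Additive pulse coupling.* An active pulse adds
     `pulse_effect × effect_scale × relative availability × base
     concentration` to the pulsed item's concentration for **every**
     individual. Averaged over individuals this equals multiplying the
     season base by the availability scaling, but the additive form lets
     the pulse override individual preference — which is precisely the
     hypothesised convergence mechanism. The fawn pulse uses
     `effect_scale = 2` (per unit availability a fawn is far more
     calorically rewarding than fruit).
  Season base concentrations total ≈ 1.5–1.7 so individual scats are
  dominated by one or two foods, as real carnivore scats are. They were
  set once so that the emergent quantities sit in the ranges reported
  for this study system: peak-segment consumption by ~60–90% of
  individuals, seasonal pulse shares ~20–30% of the diet, winter
  dissimilarity ~0.6 against ~0.43–0.50 in pulse periods.
- **Ordinal binning.** True proportion → score with inclusive upper
  edges: 0; (0, 0.02) → 1; [0.02, 0.25] → 2; (0.25, 0.50] → 3;
  (0.50, 0.75] → 4; (0.75, 1] → 5. Ties at an edge go to the lower bin;
  the rule is fixed for reproducibility.
- **Genotyping error.** Per replicate and locus: complete failure with
  `locus_failure_rate` (0.05); each allele of a heterozygote drops out
  independently with `dropout_rate` (0.10) — one dropout yields a false
  homozygote, and if both drop the replicate records a homozygote for
  one true allele at random (so the per-replicate false-homozygote rate
  at dropout d is 2d(1−d)+d²); a random allele replaces a true one with
  `false_allele_rate` (0.01). The error rates are standard magnitudes
  for non-invasive genotyping, not estimates from any particular field
  system. Sex loci: an X-linked product in all animals, a Y-linked
  product only in males, with the same failure model.
- **Deer age.** Summer deer-containing scats are fawns with probability
  `fawn_fraction_peak` (0.85) times the relative fawn availability that
  week, else adults. Hair widths are three Gaussian draws (fawn mean
  55 ± 8 µm, adult 105 ± 10 µm — separated enough that the 70/90 µm
  classifier is right most of the time but not always); fawn scats
  contain identifiable hooves with probability 0.3.

What the generator does **not** emulate: spatial movement or home-range
structure beyond a fixed home coordinate, camera or GPS data,
mis-scored diet items, field species misidentification (all simulated
scats are truly coyote; non-coyote screening is exercised through unit
tests), between-year variation, and availability measurement error.
Passing tests therefore demonstrate that the pipeline recovers truth
under its own stated error model, not that any field dataset meets that
model.

## 2. Consensus genotyping and individual identification

A replicate passes QC when ≥40% of the autosomal loci amplified. Per
locus, the consensus is the allele pair observed identically in ≥2
replicates (heterozygotes need both alleles seen together twice); when
two distinct pairs tie for support the locus is unresolved. Two
non-obvious choices:

- **All usable replicates are pooled** (capped at 6: the initial PCR
  pair plus up to four repeats). Replication is sequential in the lab,
  but discarding an already-run PCR would waste information.
- **Dropout-aware homozygote rejection.** A homozygote consensus is
  refused when any replicate showed a heterozygote carrying that allele
  — the classic dropout signature. This converts most would-be false
  homozygote calls into missing loci rather than wrong ones; at the
  default error rates it raises sample-level recovery by roughly ten
  percentage points without ever merging two true individuals in the
  validation experiments.

Samples with consensus at <7/10 loci or unresolved sex are excluded.
Sex is male iff the Y product appears in ≥2 replicates, female iff ≥2
replicates show X without Y, else unresolved.

Matching: two consensus genotypes match when they have no conflicting
locus, ≥5 matching loci, sibling probability of identity over the
matching loci < 0.01, and equal sexes. PID uses the matching loci only —
the evidence actually shared — though a whole-panel option exists
(`pid_loci="all"`). Clustering is greedy in collection order; the first
sample of a group is its reference, each new sample joins the group
whose reference it matches at the most loci (earliest group on ties).
A sample conflicting with a group by exactly one allele at one locus is
rescued when it matches the reference at ≥7 loci, has the same sex, and
lies within `radius_km` (default 1.0; no principled field value exists,
so it is configurable) of a group member. Greedy order-dependence is
real but only affects samples with ambiguous matches; the audit log
records every pairwise decision.

## 3. Diet statistics

Scores of 1 (trace) are zeroed for every item; scores of 2 are zeroed
for grass-like material (`grass_items`, default the fine-grained
`grass_leaves_pine_bark` label) because such material is often ingested
incidentally. Digestion correction multiplies scores by per-item
factors; deer and wild pig use the medium-mammal factor because feeding
trials did not include ungulates. The bundled factors are **synthetic
placeholders** preserving only the qualitative ordering (mammal remains
under-represented, fruit nearly unchanged) and the 0–31.5 corrected
scale; they are deliberately not presented as measured values.

Weighted occurrence is a ratio of summed amounts, so any uniform factor
cancels; profiles sum to 100 by construction and a stratum with no
nonzero amount has no defined profile and is excluded with a warning.

The four core analysis categories are deer, small mammal, rabbit, and
**vegetation = blackberry + persimmon + other fruit/vegetation pooled**
(per-scat amounts summed before the ratio). Pooling is what makes the
core set cover ~85% of the diet and lets fruit pulses register in the
4-food profiles; when a profile is restricted to the core set the
denominator is recomputed over those categories only.

The per-season pulse share counts the fruit pulses (blackberry,
persimmon) plus the deer occurrence attributable to fawn-classified
scats; the aggregate vegetation category is excluded because its grass
fraction cannot be separated.

## 4. Mixed models

Both comparison stages fit random-intercept GLMMs, implemented in
`scatpulse.glmm` by direct maximum likelihood: the per-group integral
over the Gaussian random effect is evaluated with adaptive Gauss–Hermite
quadrature (integrand re-centred at its per-group mode, scaled by its
curvature; 15 nodes), the marginal likelihood maximised by L-BFGS-B over
(β, log σ), and Wald intervals taken from the numerical Hessian. The
fitter reproduces `lme4::glmer` (nAGQ = 15) coefficients and standard
errors to ~1e-3 on both families (cross-checked in the test suite via
Rscript). Fits with estimates at the parameter bounds, exploding
standard errors, or a singular Hessian are flagged `converged = False`;
no silent fallback.

- **Sex comparisons:** one Poisson model per food × season (4 core foods
  × 3 seasons = 12 models), response = the per-scat 0–5 score treated as
  a count, fixed effect male vs female, random intercept per individual.
  A difference is significant when the Wald 95% CI excludes zero. The
  ordinal cap at 5 mildly attenuates large effects (a simulated log-rate
  of 1.0 is recovered at ≈ 0.85–1.0); the binarised-occurrence response
  is available via the `response` argument.
- **Segment models:** individuals' scats inside each pulse are collapsed
  per segment (pre/peak/post, peak length 3 weeks for fawns, 2 for
  blackberries, flanks equal to the peak length) to a binary
  consumed-any flag and to the weighted occurrence of the pulse item.
  The logistic model uses the binary flag; the Poisson model uses the
  percentage rounded to the nearest integer (a count-like 0–100 scale —
  the rounding rule is the implementation's choice and is documented
  here because the amount response's construction is otherwise
  underdetermined). Both take segment fixed effects (peak = reference)
  and frequency weights equal to the individual's scat count in the
  segment; weighting can be switched off (`weighted=False`).

**Calibration caveat — frequency weights.** Weighting a collapsed
binary record by its scat count duplicates a single Bernoulli draw and
therefore understates variance: with mean weight 1.5 the nominal 5%
type-I error inflates to ~15%. The calibration experiment accordingly
uses one-scat records (all weights 1), where the measured type-I error
is ~3–5%, isolating the correctness of the ML/Wald machinery; the
weighted/unweighted sensitivity is kept as an explicit regression
property because removing weights must change the fit.

## 5. Convergence analysis

Scats from the same individual on the same transect and collection day
with estimated ages within 1 day (chained) are one defecation bout; one
is retained by seeded draw and the rest removed globally. Period
assignment uses the **deposition date** (collection minus estimated
age), the biologically relevant moment; collection-date assignment is a
flag away.

Each 6-week period (42 inclusive days) yields per-individual 4-food
profiles; all n(n−1)/2 pairwise Bray–Curtis dissimilarities are compared
across periods with a tie-corrected Kruskal–Wallis test and Dunn's z
tests under Bonferroni correction, plus per-period means with
normal-approximation 95% CIs. The fawn and blackberry periods come from
the 6-week availability-maximising window, the persimmon period from the
6-week consumption-maximising window (availability was not measured for
persimmon; consumption is assumed to track it without lag), and the
winter control is a seeded random 6-consecutive-week draw inside the
winter season.

**Calibration caveat — shared individuals.** The pairwise values within
a period are not independent (each individual appears in n−1 pairs).
Applying rank tests to them follows standard practice in this
literature, but it is anticonservative: under a no-pulse null the
nominal 5% Dunn rate realises at ~50% in simulation. The output metadata
carries this note, and `disjoint_pair_dissimilarity` implements the
calibrated alternative — one random perfect matching, n/2 independent
pairs — which restores the ~5% null rate at a substantial cost in pairs
and hence power. The default remains the full pairwise matrix to match
field usage; conclusions that depend on exact p-values should use the
disjoint variant or treat the defaults as descriptive.

## 6. Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeded by the
  user; the full pipeline is byte-identical across reruns of the same
  seed and config (CSV floats written at 10 significant digits).
- Window searches (`peak_window`) break ties toward the earliest window;
  hair-width boundaries 70 and 90 µm classify as ambiguous (inclusive
  reading); ordinal bin edges are upper-inclusive; the one-allele rescue
  requires strictly one discordant allele at one locus.
- Degenerate inputs fail loudly: invalid frequencies name the locus,
  missing correction factors name the item, all-zero strata and all-zero
  profile pairs raise, models that cannot be fitted return flagged
  results.
- Problem sizes in the validation experiments (30–80 individuals,
  100–200 replicates, 10-seed identification batches) were chosen as the
  smallest sizes at which the binomial tolerances quoted in the tests
  are meaningful.

## 7. Known limitations

- The greedy reference-based clustering is order-dependent for ambiguous
  samples and does not revisit early decisions; a likelihood-based
  multi-pass assignment is out of scope.
- PID-sib assumes linkage equilibrium across loci and a well-estimated
  reference panel; small panels bias allele frequencies and hence the
  identity threshold.
- Treating ordinal 0–5 scores as Poisson counts is a pragmatic field
  convention, not a generative model; effects near the scale cap are
  attenuated.
- The convergence rank tests inherit the non-independence issue above;
  the package documents rather than silently fixes it.
- Synthetic validation bounds what can be claimed about field data: the
  generator's error model, preference structure, and pulse coupling are
  idealisations.
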