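# Methods

## The analysis problem

In multi-sire breeding pastures several bulls run with one cow group, so a
calf's sire is unknown until DNA testing resolves it. Once sires are
verified, three families of questions follow: how unevenly bulls
contribute calves (prolificacy), how the calf crop is distributed over the
calving season (21-day cycles), and how much crossbred vigor — measured as
retained heterozygosity from genomic breed composition — is associated
with fertility and production in the bulls' retained daughters. This
package implements that full pipeline plus a synthetic herd generator with
known ground truth so every stage can be validated quantitatively.

## Parentage by opposing-homozygote exclusion

A candidate sire is Mendelian-incompatible with a calf at a biallelic
locus when one is homozygous reference and the other homozygous alternate
(an *opposing homozygote*). The test counts opposing homozygotes over a
base panel (default 100 loci, the size commercial verification panels
use); candidates with at most `max_mismatches` (default 1) remain
compatible. A unique survivor is the assigned sire; several survivors are
re-tested on the base panel plus an extension (default 20 further loci in
panel order — a deterministic convention), with residual ties broken by
fewest mismatches and otherwise declared `no_sire_match`. Dams are known
from calving records and their genotypes are never used.

The tolerance of one mismatch per 100 loci admits a single genotyping
error without admitting random non-sires: for an unrelated pair the
per-locus opposing-homozygote probability is `2p²q²` under
Hardy–Weinberg, ≈ 0.125 at p = 0.5, so a non-sire accumulates ~12
mismatches over 100 informative loci. The closed form
`P(no opposing homozygote) = Π(1 − 2pᵢ²qᵢ²)` is checked empirically in
the test suite. Commercial laboratories' actual acceptance thresholds are
proprietary; this rule is a documented stand-in with the same structure
(base panel, extension, no-match outcome).

## Bull Prolificacy Index

`BPI = n·m/N` for a sire with `n` verified calves in a group-year of `m`
sires and `N` verified calves total. Only DNA-verified calves enter `n`
and `N` (unmatched calves are excluded from both), which makes the index
conserved: `Σ BPI = m` exactly within a group-year. The first-cycle
variant substitutes first-cycle calf counts for `n` and `N`, leaving `m`
unchanged; a group-year with no first-cycle calves is flagged undefined
rather than scored 0. Full precision is kept internally; printed tables
round to 1–2 decimals (half-up, the convention of published herd tables —
e.g. 6.75 grand calves/sire prints as 6.8).

Sires are stratified by *rank* into Bottom 25% / Average 50% / Top 25%
(quartile size = half-up n/4; ties broken by sire id), rather than by the
empirical 0.4 / 1.4 cutoffs, which are reported as descriptive quartile
boundaries only. Across-year repeatability uses Spearman's rank
correlation between use-year 1 and each later use-year with a permutation
p-value (999 permutations, seeded). Sire-age summaries are descriptive
(classes 1, 2, ≥ 3 years); no mixed-model inference is attempted — the
original REML analysis is a routine package fit outside this artifact's
scope.

Some published group-year extreme-BPI cells are arithmetically
inconsistent with `n·m/N` applied to the printed extreme calf counts; the
implementation follows the formula and makes no attempt to reproduce
those cells.

## Calving cycles

The season start is the date of the 3rd calving by a mature dam (≥ 3
whole years old at calving), computed per breeding group-year; same-day
calvings are ordered by calf id. An all-heifer group (dams calving at 2)
has no mature calvings, so it falls back to the herd-wide start for that
year, flagged. Cycles are half-open 21-day bins `[start + 21(k−1),
start + 21k)` — a calf born exactly 21 days after the start is cycle 2.
Births before the start (possible for early heifers) clamp to cycle 1
with a flag. Assignments are translation-invariant and per-group-year
shares sum to exactly 100%.

## Vigor score and breed-composition algebra

`VS = 1 − Σ Pᵢ²` over the breed-composition vector — the probability two
ancestry draws differ, 0 for purebreds and approaching `1 − 1/k` for an
even k-breed composite. The indeterminate fraction is included as one
pseudo-breed component by default (keeping `Σ P = 1`, consistent with how
composition tables account for the remainder); a switch excludes it with
renormalization, since the commercial formula's handling is not public.
Dam inference inverts the parental-mean inheritance rule,
`dam = 2·calf − sire`, clamping negative components to zero and
renormalizing with a flag — negatives can only arise because tested
calves merely approximate the parental mean; on simulated trios the round
trip is exact with no clamping.

## Cohort accounting and regressions

Daughters are attributed to sires by DNA-assigned parentage only. The
cohort table reports, per heifer crop and sire stratum: daughters sired
and retained, calves born to retained daughters per calving year, percent
of retained daughters still calving in the final tabulated year, total
calves weaned, average grand calves per sire (one decimal), average
weaning weight per grand calf, and total kg weaned per sire. The kg total
multiplies the *one-decimal-rounded* calf average by default — this is
how the published accounting composes its printed cells — with an
unrounded variant for real analyses.

Trait slopes are simple OLS of trait on vigor score, reported per +0.10
VS with a two-sided t-test. Conception is fit as a linear probability
model (matching the linear framing of the benchmarks; a logistic fit
would not be comparable in units). AFC is days from a heifer's birth to
her first calving; heifers that never calve are excluded from AFC but
count as failures in the conception outcome. Lifetime productivity is her
cumulative weaned calf weight. Both animal-level and 10%-bin-mean fitting
modes exist because grouped fitting is common in commercial reporting;
animal-level is the default. No multiple-testing correction is applied
across the four traits (raw p-values are reported). A sensitivity mode
refits after excluding records above the suggested 0.75 vigor-score
cutoff.

## The synthetic herd generator

Defaults emulate the structure of a six-season commercial herd: four
breeding groups per year — two mature-cow groups (6 sires × 150 dams
each), a 3-year-old group (3 × 70) and a replacement-heifer group
(3 × 80) — giving bull:cow ratios between 1:19 and 1:27. Mechanics:

* **Conception**: per-dam cascade over 4 cycles of 21 days with baseline
  probabilities (0.65, 0.55, 0.50, 0.45), chosen so the first-cycle share
  of conceptions lands near the high-60s percent typical of
  well-managed herds; the dam's vigor score shifts each probability by
  the configured conception slope (+2 pp per +0.10 VS by default).
* **Sire draw**: per-conception multinomial over the group's bulls with
  static positive weights (default Gamma(1.5) with unit mean, giving
  BPI dispersion of roughly 0.1–3.5, the spread observed in practice).
  Behavioral mechanisms (dominance, libido) are deliberately subsumed
  into these weights — the simplest model consistent with observed
  dispersion; the true weight distribution in real herds is unknown and
  is a configuration choice, not an inference.
* **Calving**: conception cycle k maps to a birth uniform in day window
  `[21(k−1), 21k)` of a season anchored on April 1 — no explicit
  gestation bookkeeping.
* **Inheritance**: calf breed composition is the parental mean; founder
  genotypes are drawn per locus at composition-weighted breed allele
  frequencies (base frequency U(0.25, 0.75) with breed drift σ = 0.15 —
  verification panels favor intermediate frequencies), offspring receive
  one Mendelian allele per parent, and genotyping errors perturb calls at
  a configurable rate (default 0).
* **Founder pools**: purebred-like sires (one breed ≥ 0.8, VS < 0.36),
  composite-like sires (≥ 5 breeds, none above 0.35, VS ≈ 0.8), dams
  drawn between the two pools.
* **Weights and noise**: weaning weight 200 ± 15 kg (Gaussian) plus the
  configured VS slope (+1.74 kg per +0.10 VS by default); birth weight
  38 ± 4 kg; 95% of calves are weaned.
* **Retention**: togglable named culling rules (third-cycle birth,
  overweight dam at 771 kg, never-weaned), then the heaviest 50% of
  eligible heifers by weaning weight are retained and enter the breeding
  herd at ~15 months; cows exit by age, openness and background hazard.

What the generator does *not* emulate: genetic linkage and maps, selection
response over generations, twinning, seasonal nutrition, behavioral sire
dominance, and — importantly — directly injected AFC and lifetime slopes.
In the full herd simulation those two traits *emerge* from the
conception-timing and longevity mechanics, so their realized per-10%-VS
slopes differ from the nominal constants. A separate generator,
`simulate_trait_records`, injects all four effects exactly (AFC −0.7 d
σ=10, WW +1.74 kg σ=15, conception +2 pp, lifetime +60.3 kg σ=50, per
+0.10 VS) and is the basis for the slope-recovery validation. Passing
tests therefore demonstrate correctness of the estimators under the
stated generating mechanisms, not that real herd data satisfy those
mechanisms.

## Numerical and design choices

* Dates are ISO-8601 calendar dates; ages are whole years at the relevant
  date (maturity is evaluated at calving).
* Display rounding is half-up via `decimal`; Python's bankers' rounding
  would disagree with printed herd tables on ties.
* Degenerate inputs are flagged, not silently zeroed: BPI with `N = 0`,
  first-cycle BPI with no first-cycle calves, Spearman pairs with < 3
  sires, strata with < 4 sires, slopes with zero VS variance.
* The herd book carries a companion sire-roster table (sire_id, group,
  year) because the sire count `m` must include zero-calf bulls and the
  parentage candidate list is the roster of the dam's group.
* Genotype I/O accepts a plain animals × loci TSV and a PLINK-style
  PED/MAP pair (A/B alleles), reflecting that different laboratories
  return different artifacts.
* The whole pipeline is a pure function of (inputs, config, seed):
  repeated runs write byte-identical outputs.

## Problem sizes

Validation uses a four-year, four-group herd (~1,500 animals) for
structural checks, the full six-year default herd (~3,000 animals,
~2,500 calves) for recovery properties, a single 6-sire group with
~2,000 calves for prolificacy-weight recovery (tolerance 3 binomial SE),
and 100 replicates of n = 500 heifer records for confidence-interval
coverage of the injected slopes (expecting ≥ 93/100 at the 95% level).
The default test suite completes in well under a minute.

## Known limitations

* No likelihood-based parentage (LOD scores), dam verification, or
  genotype imputation; exclusion counting only.
* Breed compositions are inputs (or simulated); estimating them from raw
  genotypes (ADMIXTURE-style) is out of scope.
* Descriptive statistics replace the original mixed-model (sire as random
  effect) inference for the age analysis.
* The cohort "percent remaining" reads as *calved in the final tabulated
  year*, the definition consistent with all published accounting cells,
  not *present in inventory*.
* Linear probability models for conception can produce fitted values
  outside [0, 1] at extreme vigor scores; the logistic alternative exists
  but reports slopes in different units.
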