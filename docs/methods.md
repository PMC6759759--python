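# Methods

This note documents the models, conventions and numerical choices behind
`phageres`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Experimental design model

A design is a set of ancestral clones (default `PAO1_FT1..FT3`, the three
fluctuation-test replicates) and phages with declared receptors (default
PA5P2 and PT7 binding the type IV pilus; PA10P2 and 14/1 binding LPS).
Three selection regimes are enumerated: first-step (one phage per
lineage), second-step (an ordered pair: first-step mutant re-selected
against a second phage) and simultaneous (an unordered pair, stored
sorted by phage name so (A, B) ≡ (B, A)). For a 3-ancestor × 4-phage
design this gives 12, 36 and 18 lineages respectively. Exclusion of
discarded phage treatments (PT7 by default, for which resistant mutants
were largely unrecoverable) is a design flag, not hard-coded: enumeration
drops excluded-phage treatments only when asked. Multiplicity of
infection is phage density over cell density; the resistance assay uses
~10⁸ phage/ml on ~10⁷ cells/ml, MOI ≈ 10.

## Growth curves and metrics

Input curves are OD600 time series sampled on [0, 48] h, by default every
0.5 h (the plate reader's 30-min shaking/reading cycle). Four parameters
are extracted, all on the linear OD scale:

- **maximum growth rate** (OD600/h): the largest least-squares slope over
  a sliding window of readings (default 5 points). The window smooths
  read noise at the cost of a deterministic underestimate of the true
  maximum derivative of a smooth curve: for a logistic with steepness *k*
  sampled at interval Δt, the centred 5-point slope is
  4·[tanh(u/2) + 2·tanh(u)]/(10u) of the true maximum (u = kΔt) — about
  6.5 % low at u = 0.5 and under 2 % for u ≤ 0.25. Ratios of rates
  (relative fitness) cancel most of this bias; the recovery tests bound
  the residual error at 6 % for the default assay sampling and 2 % at
  0.25-h sampling.
- **lag time**: tangent method — the line through the max-rate window's
  centroid with the max-rate slope is intersected with the baseline OD,
  clamped to [0, 48] h. A curve whose maximum rate is below 0.005 OD/h
  never grew; its lag is reported as the full duration with a
  `no_growth` flag (high-cost resistant mutants can fail to grow within
  the assay).
- **integral**: trapezoidal area of (OD − baseline), clipped below at 0.
- **yield**: maximum OD reached.

**Baseline convention.** The baseline is min(median of the first three
readings, first reading). The median protects against a single spuriously
high initial read; taking the min with the first reading keeps the
baseline at the starting OD for curves already growing at t = 0 (a pure
median of early readings would inflate the baseline on such curves and
shift lag and integral). Whether plates were blanked upstream does not
matter: all derived quantities are differences against this baseline.

## RBG and the endpoint rule

RBG is the ratio of the clone's OD gain under phage to its gain without
phage over the same window, endpoint readings linearly interpolated when
the sampling grid does not hit the endpoint exactly. Conventions:

- The control is the same clone without phage (not the ancestor), per the
  definition's control subscript; endpoint choice is made once per clone
  from its own no-phage control and applied to all of that clone's phage
  assays, because the 48-h fallback keys on slow growth of the mutant,
  not on the phage assayed.
- Endpoint: 48 h instead of 8 h when the control lag is ≥ 8 h or the
  control gain at 8 h is below 0.05 OD; otherwise 8 h. The endpoint is
  recorded on every record and used as a blocking factor downstream.
- A control gain below 0.02 OD makes the ratio numerically meaningless;
  such records carry a typed undefined marker (NaN with a reason) rather
  than a huge value.
- RBG is not clipped by default; values < 0 or > 1 are data. An optional
  clip-to-[0, 1] flag exists for presentation.

Trade-off deltas are differences of mean RBG against the first-step phage
between the second-step and first-step resistance matrices; negative
values are trade-offs, positive values strengthening.

## Relative fitness and cost additivity

Relative fitness divides each mutant technical replicate's maximum growth
rate by the mean ancestral maximum rate **of the same plate**
(plate-matching mandatory by default; disabling it pools all ancestral
measurements). Only the maximum growth rate enters fitness — it
correlates strongly with integral and yield, which remain available via
the metric-correlation report. The additive-cost prediction converts mean
single-mutation relative fitness per receptor category to costs
(cost = 1 − RF), sums them, and maps back: `1 − Σ costs`. It is symmetric
and reduces to the identity when one category is cost-free; a
non-positive prediction is reported with a floor flag.

## Variant filtering and SV calling

Quality filtering keeps records with depth **strictly** greater than 20
reads and alternative-allele fraction **strictly** greater than 0.8,
matching the ">" wording of the protocol; the boundary cases
(depth = 20, fraction = 0.80) are removed. Variant identity across
samples is (chrom, pos, ref, alt). Two background rules compose, in
either order (verified by a commutativity test):

1. a variant present in **every** sequenced mutant is a
   reference/ancestor mismatch and is discarded everywhere;
2. a variant present in every lineage of exactly one ancestor and absent
   from all others pre-dates selection (it arose before the fluctuation
   test); it is flagged `background`, kept in output, and excluded from
   mutation counts — the PA3676 SNP carried by all PAO1_FT3 descendants
   is the canonical case.

Remaining records are classified by gene via a receptor-category table
(the packaged table covers the LPS genes *wzy*, *galU*, *rmlA*, *wapH*,
*ssg*; the pilus genes *pilB*, *pilN*, *pilR*, *pilT*, *pilU*, *pilY1*,
*pilE*; *ssb* and PA3263 as OTHER; PA0429 and PA3676 as UNKNOWN);
unmapped genes are UNKNOWN.

Structural variants are called from binned coverage (100-bp bins)
normalized by the genome-wide median. Calling is seed-and-extend with
hysteresis: bins below 0.25× seed deletions and bins above 1.75× seed
duplications; events extend over neighbouring bins past the halfway
ratio to the unaffected copy number (0.5× / 1.5×), and same-type runs
separated by at most 2 bins merge. This prevents single-bin Poisson
excursions inside a real event from fragmenting it. Deletions shorter
than 100 bp and duplications shorter than 300 bp are dropped; the
duplication minimum suppresses lone high-depth noise bins, which at
realistic depths are expected a few times per genome. All thresholds are
configurable; they cleanly separate 0×/1×/2× Poisson depth at ≥ 20×
coverage. Coordinates: VCF input is 1-based; depth tracks and SV calls
are 0-based half-open (BED convention).

## Statistics

The ANOVA layer fits additive fixed-effects models with **sequential
(type-I) sums of squares** in the declared term order — blocks (ancestral
genotype, phage pair, RBG endpoint) first, treatment last, optional
treatment × phage-pair interaction — via orthogonal projection with a
rank-revealing QR per term. A term adding no rank beyond earlier terms
raises an aliasing error naming it; term degrees of freedom are the rank
actually added. Sequential SS is reproducible and well defined for the
mildly unbalanced designs produced here; for balanced designs it is
order-invariant (tested). The RBG endpoint (8 vs 48 h) is included as a
fixed blocking factor rather than a random effect: with two levels and
small n, a fixed block is the stable surrogate, and the choice is visible
in the output term list.

Tukey HSD reports raw level-mean differences, the SE of each difference
from the residual mean square with the Tukey–Kramer (per-pair
harmonic-mean cell size) correction, the studentized-range statistic
q = √2·|diff|/SE, and adjusted p-values from the studentized-range
distribution with (k, residual df) — computed by scipy's implementation.
With two levels this reduces exactly to the pooled two-sample t-test
(q = √2·|t|), which the tests verify. Welch's t uses the closed-form
statistic and Satterthwaite degrees of freedom; two zero-variance samples
give an undefined marker.

## Synthetic data: what it emulates, what it does not

The generator's defaults encode the study conditions: 3 ancestors ×
4 phages with PT7 discarded, one clone per treatment, three technical
replicates, 0–48 h curves every 0.5 h, and the 6,264,404-bp PAO1
chromosome.

**Growth model.** Three phases — baseline, logistic rise, saturation —
parameterized so the intrinsic maximum slope is μ·(1 − c) with μ = 0.30
OD600/h, capacity 1.0 OD, baseline 0.05 OD, lag 2 h; c is the planted
fitness cost, so extracted relative fitness targets 1 − c by
construction. Under phage p the growth increment above baseline is
scaled by the planted resistance r_p, making RBG's target value exactly
r_p at any endpoint — a deliberate modelling convention (no quantitative
suppression model exists for partially resistant clones), chosen to give
clean recovery tests. Gaussian read noise (sd 0.01 OD, a typical plate
reader's scale) is added and floored at 0 because absorbance is
non-negative. This is not a mechanistic phage–host model: no phage
population dynamics, no lysis kinetics, no evolution during the assay.
Passing recovery tests therefore show the estimators invert the assumed
observation model, not that real curves follow it.

**Mutational truth.** First-step mutants get one receptor-specific
mutation; second-step and simultaneous mutants get two (one per selection
step / one-or-two receptor targets), plus a cost-free hitchhiker in a
gene of unknown function with probability 0.15. Per-mutation costs are
drawn around category means of 0.114 (LPS) and 0.120 (type IV pilus) —
equivalently, mean single-mutation relative fitness 0.886 and 0.880 —
with sd 0.03, and add across mutations. Planted resistance is 0.95 to
selected phages, 0.85 same-receptor cross-resistance, 0.05 otherwise.
One simultaneous LPS-pair lineage carries a 250-kbp deletion spanning
*galU* (≈ 4 % of the genome); one different-receptor simultaneous lineage
carries 4-kb duplications at *ssb* and PA3263. Gene coordinates are
invented but genome-plausible. Variant tables add the three artifact
classes the filters must handle: shared reference mismatches (3 per run),
the FT3-private PA3676 SNP, and low-alt-fraction noise records.

**Coverage.** Per-bin depths are Poisson(mean 50×), scaled by each bin's
overlap with planted events (0× deletions, 2× duplications). Reads are
not simulated; mapping artefacts, GC bias and dispersion beyond Poisson
are absent, so SV-caller tests demonstrate correctness of the
segmentation logic, not robustness to alignment pathology.

**Determinism.** Every stochastic quantity draws from a generator seeded
by a stable hash of (root seed, stage, lineage, condition, replicate), so
one seed fixes every output byte-for-byte regardless of evaluation order;
the pipeline records the seed and a config hash in every output header.

## Problem sizes and runtimes

The test suite and acceptance script run at desk scale by choice of
problem size: full 39-lineage pipeline runs for end-to-end checks,
100-replicate noise batches for RBG recovery, 100 seeded tracks on a
400-kb genome for SV boundary calibration (full-length genome for the
250-kbp deletion checks), 200-run power simulations and a 2000-run
type-I-error calibration for the ANOVA layer. The complete suite runs in
well under a minute on one CPU.

## Known limitations

- The growth model cannot represent diauxie, death phases or
  lysis-then-regrowth dynamics; RBG > 1 or < 0 can occur in real data
  and are passed through unclipped.
- The additive-cost prediction sums costs on the relative-fitness scale,
  following the definition used for the two-receptor comparison;
  multiplicative cost composition would differ in the second decimal for
  the planted cost magnitudes.
- "Present in all replicates" for the reference-mismatch rule means all
  sequenced mutants of the run; with very few lineages (N = 2) the rule
  still applies and may discard genuine parallel mutations.
- The blocked ANOVA is fixed-effects only; no REML/mixed machinery, and
  p-values on the synthetic designs are not meant to reproduce any
  package-specific values on real data.
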