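# phageres

Analysis pipeline for quantifying how bacteria evolve resistance against
**combinations of phages** — applied simultaneously or sequentially — from
plate-reader growth curves, called-variant tables and read-depth tracks.
It is written for experimental-evolution studies of the type where
spontaneous phage-resistant mutants of *Pseudomonas aeruginosa* PAO1 are
selected against pairs of phages binding either the LPS or the type IV
pilus, and each mutant is then phenotyped and genome-sequenced.

## What it computes

**Strength of resistance (RBG).** For phage *i* and bacterial clone *j*,
relative bacterial growth over the assay window [0, *e*] is

```
RBG_ij = [Abs600(e) − Abs600(0)]_ij / [Abs600(e) − Abs600(0)]_control_j
```

where the control is the same clone without phage. RBG = 1 means equal
growth with and without phage (complete resistance); RBG = 0 means no
growth above the starting OD. The endpoint *e* is 8 h for normal growers
and 48 h for slow-growing, high-cost mutants (lag ≥ 8 h or negligible
8-h gain).

**Growth parameters and fitness cost.** Each OD600 curve yields lag time,
maximum growth rate (largest sliding-window least-squares slope, OD600/h
on the linear scale), curve integral and yield. Relative fitness is the
mutant's maximum growth rate divided by the mean ancestral rate measured
on the same plate; the additive-cost prediction for a double mutant
hitting two receptors is `1 − Σ_k (1 − RF_k)` over the mean single-mutation
relative fitness per receptor category.

**Mutational basis.** Starting from called variants, the pipeline applies
the study's filters (depth > 20 reads, alternative-allele fraction > 80 %),
discards variants present in every sequenced mutant (reference mismatches),
flags variants universal within one ancestral clone's descendants
(pre-existing background, e.g. a PA3676 SNP), classifies the rest by
receptor category (LPS / type IV pilus / other / unknown), and calls
deletions > 100 bp and duplications from median-normalized coverage depth.

**Statistics.** Blocked ANOVAs (sequential sums of squares; ancestral
genotype, phage pair and RBG endpoint as blocks) with post-hoc Tukey HSD,
and Welch's *t* for single- vs multi-mutation fitness.

A synthetic-data generator emulates the full 3-ancestor × 4-phage design
(PT7 treatments discarded) with known planted resistance, costs, mutations
and structural variants, so the whole pipeline runs and is testable at
desk scale. Real data in the same formats (long-format curve CSV, minimal
VCF, bedgraph-like depth TSV) are read by the same functions.

## Worked example

```sh
phageres run --outdir demo --seed 1
```

runs simulate → growth → resistance → fitness → variants/SV → stats and
writes one TSV per stage. With the default design, seed 1:

`tukey_mutation_count.tsv` — mutation counts per regime (Tukey on the
regime factor after blocking by ancestor):

```
    level_a      level_b    diff     se      q  p_adj
 first_step  second_step  1.1111 0.1684 9.3283 0.0000
 first_step simultaneous  0.8889 0.1945 6.4628 0.0002
second_step simultaneous -0.2222 0.1684 1.8657 0.3955
```

Single-phage selection yields ~1 mutation per mutant and both two-phage
regimes ~2, so the two-phage regimes differ from first-step selection but
not from each other.

`fitness_by_burden.tsv` — Welch's *t* comparing relative fitness of
single- vs multi-mutation mutants:

```
 n_single  n_multiple  mean_single  mean_multiple      t     df      p
        9          27       0.8867         0.8254 4.2334 20.977 0.0004
```

Multi-mutation mutants are significantly less fit, as planted.

`sv_calls.tsv` — the planted 250-kbp deletion in one simultaneous
LPS-pair mutant is recovered with exact boundaries:

```
                             lineage     type   start     end  length_bp  fraction_of_genome
PAO1_FT1|simultaneous:14/1+PA10P2|r1 DELETION 2095400 2345400     250000               3.991
```

i.e. about 4 % of the 6,264,404-bp genome.

`summary/cost_vs_genotype.tsv` — observed mean relative fitness per
mutated genotype next to the additive two-receptor prediction:

```
        genotype  mean_rf  n  additive_prediction_two_receptors
     PA0429+rmlA   0.8777  2                             0.7745
PA0429+rmlA+wapH   0.7914  1                             0.7745
      PA0429+wzy   0.8983  3                             0.7745
 PA3263+pilR+wzy   0.8417  1                             0.7745
```

Individual stages are also exposed (`phageres growth`, `phageres
resistance`, `phageres fitness`, `phageres variants`, `phageres sv`,
`phageres design enumerate`, `phageres design moi`), and everything is
importable from Python (`phageres.rbg`, `phageres.blocked_anova`, …).

## Layout

- `phageres.design` — phages, receptors, selection regimes, lineage
  enumeration, MOI arithmetic
- `phageres.synthetic` — ground-truth generator (curves, variant tables,
  coverage tracks)
- `phageres.growth` — growth-curve metrics and plate-reader CSV I/O
- `phageres.resistance` — RBG, endpoint rule, resistance matrices,
  trade-off deltas
- `phageres.fitness` — relative fitness, additive-cost prediction, burden
  comparison
- `phageres.variants` — variant filters, background rules, receptor
  classification, coverage-based SV calling, minimal-VCF I/O
- `phageres.stats` — blocked ANOVA (type-I SS), Tukey HSD, Welch's *t*
- `phageres.pipeline` / `phageres.cli` — orchestration, summary tables,
  command-line interface

See `docs/methods.md` for the modelling choices and their rationale.
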