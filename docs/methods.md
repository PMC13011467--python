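# Methods

## Differential LC-MS feature calling

The metabolomics workflow treats an untargeted LC-MS feature table from a
balanced 2 (salinity) × 3 (time) × 3 (replicate) culture experiment as a
features × samples matrix of non-negative signals plus per-sample design
metadata. The statistical model is a two-way fixed-effects ANOVA on
log₁₀-transformed, pseudocounted signals: a feature responds to the
treatment when its salinity × time interaction is significant after BH
adjustment *and* the effect size is large (the span of the six group
means is at least 100-fold). The earlier stages are screens: the blank
ratio and retention-time window remove contaminants and column artefacts,
the 10⁷ signal floor removes features never measured above instrument
noise, and the 10× prefilter removes features with no meaningful
between-group movement before any test is run.

Decisions where the procedure's prose left room:

* "below the floor in all samples" is read as *removed only when below
  10⁷ in every biological sample* — one strong sample keeps a feature;
* the 10× prefilter and the 100× gate both compare the maximum to the
  minimum of the six condition × time group means (the most inclusive
  reading consistent with per-group mean comparison); the one-way ANOVA
  groups by the same six cells;
* the blank comparison is max-over-blanks vs max-over-biological-samples,
  which is conservative against carry-over;
* all threshold boundaries ("at least", "between") are inclusive;
* BH adjustment at each testing stage runs only over the features that
  reached that stage, matching the sequential narrative of the workflow,
  and positive/negative ionisation modes are adjusted separately;
* the Levene check uses the median-centred (Brown–Forsythe) variant and
  is recorded per feature, never used as a filter;
* degenerate features (zero total variance on the log scale) get p = 1
  and a flag; perfectly separated features (zero within-group variance,
  non-zero between) get F = ∞ with p floored at 1e-300 so log-scale
  reporting stays finite.

The one-way and balanced two-way ANOVAs are computed as closed-form
sum-of-squares decompositions vectorised over features (for a complete
balanced design the type I/II/III decompositions coincide, so
SS_A + SS_B + SS_AB + SS_E = SS_total exactly); the test suite checks
them against `scipy.stats.f_oneway`, `scipy.stats.levene` and
`statsmodels` `anova_lm`, and against explicit summation oracles. BH
adjustment and Fisher's exact test are delegated to statsmodels/scipy
and checked against naive enumeration.

## TSS calling

All four stages use one chaining rule: positions on the same strand join
a cluster while the gap to the nearest member is ≤ the window (5 nt by
default). Single-linkage chaining is order-independent and matches the
pairwise "within 5 nt" phrasing; its one caveat is transitive linking of
two sites > window apart through an intermediate, which at bacterial TSS
densities is rare. Representatives are always the member with the
greatest count, ties broken to the smallest genomic coordinate, and a
cluster's count is the sum over members, so read counts are conserved
through every stage. Consensus requires a representative from *every*
replicate in the chain (3 by default, configurable); merging across
conditions records the exact detection subset per unique TSS, whose
tally is the UpSet-plot input.

Classification priority is upstream > internal > antisense > orphan, so
the categories partition the unique TSS set; "upstream" means 1–400 nt
5′ of a same-strand gene start, inclusive, with the strand-aware distance
measured to the annotated start codon end of the gene. A TSS inside gene
A but ≤ 400 nt upstream of gene B counts once, as upstream of B.
Coordinates are 1-based inclusive internally; BED6 I/O (0-based
half-open) converts at the boundary: a plus-strand fragment's 5′ end is
BED start + 1, a minus-strand fragment's is the BED end field.

## Expression rules

Comparisons run on the log₂ scale with threshold log₂ 5 ≈ 2.3219;
"≥ 0.05" and "5-fold or greater" boundaries are inclusive as printed.
Missing adjusted p-values (independent-filtering artefacts of upstream DE
tools) are treated as non-significant, zeroing the lfc — the conservative
choice. The reference condition enters the 7-condition span as exactly 0.
The salinity classification is evaluated only among DE genes. Note the
max-of-max rule is *not* symmetric under negating all lfcs (max(−x) =
−min(x)); the symmetry that does hold, and is tested, is that swapping
the salt and no-salt column blocks exchanges salt_up and salt_down.
Fisher's exact enrichment is two-sided (depletion is as interesting as
enrichment) against a background of all annotated genes, BH-adjusted
across categories with a 0.1 FDR display threshold. Conservation
histograms use ten equal-width bins on [0, 1], left-inclusive with a
right-inclusive last bin.

## Synthetic data

The generator emulates the study design, not the raw instruments: it
produces feature tables, not spectra, and fragment intervals, not reads.
One seed feeds a `numpy.random.SeedSequence` whose children drive each
dataset, so outputs are deterministic and adding one dataset never
perturbs another.

* **LC-MS**: per-feature baselines are log-normal around 10^7.5 (so most
  features clear the 10⁷ floor), replicate noise is log-normal with CV
  0.2 by default (0.1 in the power setting), and planted features have
  one (salinity, time) cell multiplied by 200 — comfortably above the
  100× gate so the planted truth is recoverable by design. Blanks sit at
  1/10 of each baseline, passing the 3× blank filter. m/z is uniform on
  100–1000 Da, RT uniform on 0.5–8 min, modes split evenly.
* **TSS**: 200 sites on a 1-Mb linear chromosome, placed on a 50-nt grid
  so sites never merge at a 5-nt window; ~40% of sites are active in all
  four conditions, the rest in a random non-empty subset. Counts are
  Poisson with mean 50 per replicate, 5′ ends jittered by a rounded
  normal of sd 1 nt; the background is Poisson-uniform at 1e-4 ends per
  nt per strand — dense enough to exercise the consensus filter, sparse
  enough that three-replicate background coincidences are negligible.
* **Expression**: planted salt-up genes have one strong significant salt
  column (lfc 2.5–5) and null no-salt cells; other planted DE genes have
  the same lfc in one salt and one no-salt column (DE but not
  salt-responsive); nulls are non-significant everywhere, so recovery is
  exact by construction.

What passing on this data does **not** show: robustness to unbalanced or
missing samples, retention-time drift, heteroscedastic or heavy-tailed MS
noise, correlated features (adducts/isotopes), TSS clusters closer than
the chaining window, condition-dependent library depth, or any upstream
alignment/peak-picking error. The synthetic data validates the decision
rules and their boundary behaviour, not the instruments.

## Problem sizes and numerics

The default validation sizes — 2,000 features × 50 null seeds for the
false-call control, 1,000 random instances for the clustering oracle, 500
cases per statistical oracle, the full 8⁶ grid for the expression rules —
were chosen so the whole suite runs in well under a minute while keeping
binomial noise on estimated rates small relative to the thresholds
checked. Group means use plain arithmetic means; ANOVA F-statistics agree
with independent summation to 1e-9 relative; Fisher p-values are checked
against exact rational-arithmetic enumeration to 1e-10. Ties in
clustering and matching are always broken deterministically (greatest
count, then smallest coordinate), and greedy catalogue matching orders
candidate pairs by distance then coordinates, so all outputs are
byte-reproducible under a fixed seed.

## Known limitations

* The 100× effect-size gate is applied to the ratio of the extreme
  condition × time group means; other defensible definitions of a
  100-fold change across conditions and time points (specific pairwise
  contrasts, replicate-wise extremes) are not implemented.
* Single-linkage chaining can, in principle, link sites further apart
  than the window through intermediates; cluster width is unbounded in
  pathological inputs.
* The enrichment background is all annotated genes; restricting to
  DE-tested genes is supported by passing an explicit background set.
* One chromosome is assumed throughout the TSS machinery (the target
  organisms carry a single linear chromosome).
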