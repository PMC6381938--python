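# Methods

This note documents the models and procedures `novallele` implements,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinates and counting

All germline and observed V sequences live in IMGT unique numbering:
character `i` (1-based) of the gapped string is IMGT position `i`, `.`
is a numbering gap.  Analysis is restricted to positions 1–312 (the V
region upstream of the CDR3 junction).  A position counts as mutated
only when both the observed and germline characters are unambiguous
nucleotides and differ; `.`, `N`, and any indel-like character are
masked, never counted.  Duplicate detection in the germline database
and all exact-match tests compare only positions 1–312, since nothing
downstream of 312 is analyzed.

Input records are kept when productive with a non-empty junction, and
deduplicated on (V region 1–312, junction) keeping the first occurrence
(configurable to the full observed sequence).  Records whose assigned
gene is absent from the germline database are dropped with a logged
count.  When an aligner reports tied V calls, the first listed allele
is used for grouping; ties created by reassignment are stored
comma-joined in alphabetical order.

## Novel-allele detection

For one allele group, the per-bin position frequencies `f_p(x)` are
computed from the raw integer mutation-count histogram (no smoothing —
the bins are the model).  Window placement:

* primary window `[m, m+9]`, `m` = most frequent positive mutation
  count (ties resolved to the smallest count, deterministically);
* one additional window per positive count `c ≠ m` with
  `hist[c] ≥ hist[m]/8`, whether above or below `m` (no cap on the
  number of windows);
* evaluation point `x = m − 1` (window start minus one).

Within a window, an unweighted ordinary least-squares line is fitted
per position through the occupied bins having at least
`min_seqs_per_bin = 10` sequences; at least `min_occupied_bins = 3`
such bins are required, otherwise the verdict is `insufficient_data`.
The fit is closed-form and vectorized across all 312 positions.  A
position is polymorphic when the predicted frequency at the evaluation
point exceeds `y_threshold = 0.125`.  The unweighted fit and the
occupancy floors are deliberate: weighting is unspecified by the
method's definition, and the floors keep single-sequence bins from
steering an extrapolation.

All polymorphic positions of one window are substituted into the base
allele as a single candidate (multi-SNP alleles are one germline, not
several single-SNP ones).  The substituted base at a position is the
modal non-germline nucleotide among the window's sequences; a tie
breaks lexicographically (A<C<G<T) with a logged warning.  Candidates
are discarded when (i) identical to an existing database entry over
1–312, (ii) not matched exactly by any observed sequence
(`supporting_unmutated_count = 0`), or (iii) — with the clonality guard
on, the default — supported by a single (J gene, junction length)
combination, since one expanded clone can mimic a polymorphism.
Candidates from different groups implying the same sequence are
reported once, keeping the best-supported one.  `min_group_size`
defaults to 50 sequences; the sensitivity figures quoted below assume
groups of ≥500, and smaller groups simply yield fewer occupied bins and
more `insufficient_data` verdicts.

### Legacy mode

`legacy_mode=True` reproduces the original fixed-window behaviour:
window `[min(L, 5), 10]` with `L` the most frequent *positive* count
among sequences with ≤10 mutations, evaluated at the y-intercept
(x = 0).  Two definitional choices here were open:

* `L` is restricted to positive counts; allowing `L = 0` would
  contradict the documented equivalence of the two algorithms at
  `m = 1` whenever unmutated sequences dominate a group.
* The legacy fit includes **every** integer count in its window, empty
  bins entering as zero-frequency points.  This is what makes the
  original method structurally blind beyond five SNPs — a group from a
  more distant allele leaves the window's low bins empty and those
  zeros drag the y-intercept below threshold — and it reproduces the
  documented five-SNP detection boundary exactly.  Updated-mode fits
  use occupied bins only.

## Bayesian genotyping

Evidence per gene is the count vector `X` of the top four alleles among
apparently-unmutated unique sequences (zero mismatches over 1–312
against the assigned allele); allele rank ties break by name.  The
seven usage models and `ε = (1,1,1,1)/100` are fixed; since a
multinomial parameter must lie on the simplex, `θ_v = (H_v + ε)`
is renormalized (the raw sum is 1.04).  Each variant is scored by its
posterior *ordinate* under a uniform Dirichlet(1,1,1,1) prior:

    log10 p(θ_v | X) = log10 [ Multinom(X | θ_v) · Dir(θ_v; 1) / DirMult(X; 1) ]

with the multinomial coefficient cancelling between likelihood and
marginal.  Families aggregate variants by summation (Bayesian model
averaging; a `family_mode="max"` alternative exists because the
aggregation rule is not uniquely determined by the model description).
The winning family sets the allele count; `log K` is the log10 gap to
the runner-up family and is always ≥ 0.  Reported per-family values are
ordinates of densities, so even the winner's value is not near zero —
for `X = (334, 295, 209, 1)` the defaults give `(−620.9, −216.3, −3.4,
−103.2)` for the 1/2/3/4-allele families and `log K = 99.8`.

Numerical choices:

* Everything is computed in log space; values are floored at −1000,
  the scale at which the corresponding probability underflows double
  precision.
* Model priors are a configuration surface (`BayesConfig.model_priors`)
  with flat unit weights by default.  Fitted, cohort-specific priors
  would shift the per-family values by their log weights (and the
  worked-example figures above would move by up to a few units in
  log10); with no principled basis to choose them, the package ships
  neutral weights and exposes the knob.  A normalized prior vector only
  shifts all values by a constant, which cancels in every reported
  ratio, so unit weights are used verbatim.
* Normalized variant posteriors (summing to one across the seven
  variants) are exposed alongside the ordinates; both orderings agree.

The frequency method needs no model: alleles are added in descending
count order until ≥ 7/8 of the gene's unmutated sequences are covered
(boundary inclusive: 0.88 covers).  On clean simulated draws from any
of the seven usage vectors at depth ≥200, the two methods agree on the
allele set in ≥95% of draws.

## Reassignment and iterative inference

Reassignment gives every record the database allele(s) at minimal
Hamming distance over 1–312 (`N`/gaps ignored), computed as a chunked
vectorized distance table.  Iterative inference from a sparse database
(seeded per family with the most frequently assigned allele) loops:
detect → provisionally reassign to database+candidates → accept the
candidates that enter the frequency-method genotype (7/8 rule) →
reassign to the grown database.  The acceptance gate is what keeps the
loop sound: the database grows strictly while iterations continue, is
bounded by the number of distinct candidate sequences, and the loop
stops at the first iteration accepting nothing (`max_iter = 10` as a
backstop; synthetic runs converge in ≤3).

## Genotype distance

Per gene, the Jaccard distance `1 − |A∩B|/|A∪B|` between allele sets;
genes present in only one genotype are excluded.  The genotype distance
is the weighted mean over shared genes with weight
`mean(clip(log10 K, 0, 100))` per gene.  Using `log K` rather than raw
`K` is a deliberate deviation from a literal "mean of the two Bayes
factors": raw `K` at the magnitudes the model produces (`log10 K`
routinely > 100) overflows floating point and would make every
comparison degenerate.  A `raw-k` weighting is provided for small-`K`
use.  Frequency-method calls carry unit weight; an all-zero weight
vector falls back to an unweighted mean.

## The simulator

`simulate_repertoire` emulates the data structure the detection model
assumes, per gene and allele:

* usage: deterministic largest-remainder allocation of
  `sequences_per_gene` records across the genotype's usage vector, so
  per-allele depth is exact, not multinomial;
* mutation load: zero-inflated Poisson — unmutated with probability
  `unmutated_fraction` (default 0.3), else Poisson(`poisson_mean`,
  default 4).  These defaults are the package's standing choice of a
  realistic memory-inclusive repertoire (a substantial unmutated naive
  mass plus a mutated tail);
* substitutions: uniform over non-gap positions 1–312, never to the
  same base;
* junctions: 5 distinct (J gene, junction length) classes per record
  drawn uniformly, with random junction strings — enough diversity that
  the clonality guard never suppresses a true allele, and unique keys
  for deduplication.

`random_germline_database` builds a coarse synthetic locus (random
312-nt gapless family roots; genes ≥20 SNPs apart within a family;
alleles 1–4 SNPs apart within a gene).  It is a stand-in for a real
reference with realistic *distance structure* only; real loci have
gaps, length variation, hotspot-biased SHM and correlated gene
similarity that it does not model.  Consequently the synthetic
benchmarks demonstrate the algorithmic properties (window placement,
exact germline reconstruction, convergence, separation) under the
stated noise model — not performance under hotspot-targeted SHM,
indels, sequencing error, or strong clonal expansion.

## Benchmarks and problem sizes

The test suite and `scripts/acceptance.py` run everything at sizes
chosen to exercise the stated study conditions while keeping a laptop
run short:

* sensitivity: 5 single-allele groups × 500 unique sequences,
  `n ∈ {1..5, 10, 20, 30}`, 20 replicates per (allele, n).  Observed:
  100% recovery at every `n`, zero false positives.
* sparse start: 10 genes × 2 alleles over 3 families, mixed usage
  (1:1, 2:1, 3:1), 1000 sequences per allele, seeded with one allele
  per family.  Observed: 85% of true alleles recovered, convergence in
  3 iterations.
* separation: 3 subjects × 5 resampled repertoires at 1000 sequences
  per gene.  Observed: maximal within-subject distance 0.0, minimal
  between-subject distance ≈ 0.53.
* specificity: ≥100 groups simulated purely from database alleles at
  varied SHM levels yield zero candidates.

## Known limitations

* Detection is V-gene only; D, J and light-chain loci pass through
  untouched, and indel-containing alleles are out of scope (indel
  characters are masked like `N`).
* Two distinct novel alleles at the same distance from the same base
  allele share every window and can shadow each other for an iteration;
  iterative reassignment usually resolves them, low-usage alleles least
  reliably.
* The Bayesian model considers at most four alleles per gene and its
  per-family values depend on the prior weights (see above).
* Temporary novel-allele names (`base_SNPs…`) are not automatically
  reconciled with official database names once one exists;
  `GermlineDatabase.rename` is the manual hook.
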