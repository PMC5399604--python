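# Methods

This note documents the models and numerical choices behind `tagarray`, in
the spirit of a statistical-software methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

Panels are biallelic SNPs only.  Variants are keyed by
`chrom:pos:ref:alt`; the VCF ID column is ignored for matching, which keeps
alignment robust to absent rsIDs.  Internally all coordinates are 0-based
column indices into the site list; VCF 1-based positions survive only as
site metadata, so windowed computations never do off-by-one arithmetic on
genomic coordinates.  Multiallelic records are rejected by default (an
explicit `split` policy emits one biallelic site per alt allele; split
sites share a position, so site order is required to be non-decreasing
rather than strictly increasing).  Missing genotypes are excluded pairwise
from frequency and LD computations; no imputation happens at the I/O
layer.

The merge of single-sample, variant-only VCFs backfills absent sites as
homozygous reference.  The invariant checked in tests is that per-sample
heterozygous and homozygous-alternate counts are identical before and
after the merge — backfilling can only add hom-ref cells.

## Filters

Candidate exclusion reasons are assigned in a fixed precedence order:
scaffold membership > design score > MAF > explicit list.  The order makes
each excluded site carry exactly one reason, so funnel reports partition
the input; the choice of precedence affects only attribution, never the
retained set.  Defaults: MAF cutoff 0.01 (below which sequencing-derived
calls are also least reliable), design-score floor 0.5.  Design scores are
consumed as an input annotation; the toolkit never computes them.

## LD estimation

Phased input: r² is computed from directly counted two-locus haplotype
frequencies, `D² / (pA(1−pA) pB(1−pB))`, which equals the squared Pearson
correlation of the two allele columns (cross-checked to 1e-9 in tests).

Unphased input: the classic two-locus EM.  Only the double-heterozygote
class is phase-ambiguous; the E step splits its count between coupling and
repulsion phase by relative likelihood, the M step renormalizes.
Initialization is at linkage equilibrium (product of observed marginals),
which preserves the single-site allele frequencies at every iteration.
Tolerance 1e-8 on the max frequency change, cap 1000 iterations.  A known
caveat, asserted in tests rather than hidden: a dataset consisting only of
double heterozygotes is a fixed point of this initialization and returns
r² = 0.

Bulk computation windows pairs at 250 kb by default.  That bounds the
quadratic pair set while comfortably exceeding the useful single-marker
tagging range in African-ancestry panels, whose LD blocks are short; the
same window serves the coverage module.  Monomorphic sites are skipped
with a log notice; on unphased input, pairs with fewer than 10
pairwise-complete samples are skipped rather than estimated unstably.

## Tag selection

The thresholded LD graph decomposes into precincts (connected components,
via networkx).  Within a precinct, a valid tag set is a dominating set:
every member is a tag or adjacent to one at r² ≥ 0.8.  Precincts of at
most 15 sites are solved exactly by enumerating subsets in increasing
cardinality — at 15 nodes that is at most 2^15 subsets, well under a
second — and the first optimum in lexicographic id order is returned, so
selection is deterministic.  Larger precincts use the standard greedy
cover; ties are broken by higher MAF (better expected genotyping
performance for the chosen probe), then smaller id.  Tests compare exact
sizes against an independent bitmask enumeration oracle on hundreds of
random graphs and verify greedy never beats exact.

Single-marker tagging only; haplotype-combination tags are out of scope.

## Capacity trim

When the selected tag count exceeds the probe budget, the MAF floor is
raised from the base cutoff in 0.001 (0.1% MAF) steps until the retained
count fits — thinning by frequency is unbiased with respect to genomic
location.  Must-include tags are never dropped; a budget below the
must-include count is an error.  The returned floor is the smallest on the
scan grid meeting capacity (checked against a linear-scan oracle), and the
procedure is monotone in capacity.

Plain trimming accepts coverage loss: a dropped low-MAF tag can orphan
sites above the floor.  `apply_capacity(..., reselect=True)` therefore
re-covers floor-eligible orphans with substitute tags drawn from
floor-eligible sites (every orphan can tag itself, so the repair always
succeeds), and the substitutes count against the budget during the floor
scan.  The end-to-end pipeline enables this repair by default, which is
what makes its audit guarantee ("every post-filter candidate at or above
the final floor is covered or imputable") hold unconditionally; the bare
`apply_capacity` default keeps the classic trim-only semantics.

## Imputation screen

The screen asks whether a candidate is already recoverable from scaffold
genotypes plus an external reference panel, in which case it needs no tag.
The copying model is Li–Stephens: hidden states are the K reference
haplotypes; emissions mismatch with probability theta = 0.001; the
probability of switching template across d bp is
`1 − exp(−4·Ne·r·d / K)` with Ne = 10,000 and r = 1e-8 per bp.  One
forward–backward pass over the scaffold sites is shared by all study
haplotypes (vectorized across haplotypes, float32 state arrays with
per-site normalization); imputing any target then costs a single posterior
interpolation between its flanking scaffold sites, which keeps the screen
linear rather than quadratic in candidate count.  Targets with no scaffold
site within 500 kb fall back to the allele-frequency dosage and are
flagged.

Quality is the *empirical* leave-one-out dosage r²: the candidate is
imputed without ever entering the model and scored by squared Pearson
correlation against the true sequenced genotype (truth is available
because candidates come from the sequenced study cohort).  A model-based
estimated r² would also satisfy the screen's contract, but the empirical
version is directly verifiable against held-out truth.  Candidates
strictly above 0.8 are screened out; candidates absent from the reference
score 0 and stay in the pool.  A constant dosage scores 0 by convention;
constant truth makes quality undefined and the site is left unscreened.

A documented behavior of the copying posterior: the imputed dosage of a
site adjacent to an observed perfect proxy can still deviate from the
proxy genotype for a study haplotype whose flanking context the reference
panel associates with the other allele — emission evidence at one site
(likelihood ratio ≈ 1/theta) can be outweighed by accumulated flank
evidence.  With study and reference drawn from the same pool this is rare
(all 50 perfect-proxy candidates in the test construction score above
0.95); with a diverged reference a few haplotypes of admixed samples hit
it, which is the realistic cost of reference mismatch.

## Coverage reports

Coverage is single-marker: a target counts as covered at a threshold when
some panel site within the window reaches that r² (self-coverage is 1).
Tables stratify by MAF bins [0.01, 0.02), [0.02, 0.05), [0.05, 0.10),
[0.10, 0.50] plus an overall row, and accept several panels side by side —
a union passed under its own label evaluates a combined array.  Structural
invariants (coverage non-increasing in threshold, union dominating its
components, self-coverage) are asserted over seeded regions.  The MAF
spectrum report is a plain histogram over [0, 0.5], half-open bins with
the last closed.  No plotting; figures are reproduced as tabular data.

## Synthetic data

`simdata` emulates the study design end to end: an admixed target cohort,
an external single-pool reference, and a common-variant-biased scaffold.
Haplotypes come from an msprime coalescent simulation — two ancestral
pools of Ne 10,000 splitting 3,000 generations ago, the study population
formed 10 generations ago by 80/20 admixture, the reference sampled from
the majority pool; recombination 1e-8/bp with three 2 kb hotspots at 15×;
strictly biallelic mutations at 6.5e-9/bp per generation, a rate chosen so
the default 2 Mb / 300-study-diploid setting yields roughly 5,000 sites
segregating in the study catalog.  Study and reference panels keep the
sites segregating in their own samples, so private study variants exist,
as with a real external reference.  Scaffold membership is Bernoulli with
a logistic-in-MAF probability (midpoint 0.15, scale 0.04, plateau 0.9),
reproducing the common-variant bias of commodity arrays in synthetic form;
design scores are Beta(7, 1.5), putting a few percent of probes below the
0.5 floor.  All randomness derives from the single mandatory seed.

What the generator does *not* emulate: genotyping error, variant-calling
artifacts, realistic human recombination maps, population-specific allele
ages, or the true site-frequency spectrum of deep-coverage cohorts beyond
a qualitative rare-variant skew.  Passing tests therefore demonstrate the
pipeline's internal correctness and its qualitative behavior (coverage
monotonicity, low-MAF skew of the designed complement), not calibrated
real-data coverage numbers.

## Problem sizes

The default synthetic setting — 2 Mb, 300 study and 200 reference
diploids, capacity 500 (about two thirds of the untrimmed tag pool,
mirroring a realistic budget-to-pool ratio) — runs the full pipeline in
well under a minute on one core with peak memory around 2.5 GB, dominated
by the stored forward/backward state arrays of the imputation screen.
Unit and property tests use smaller regions (60–400 kb) chosen so each
oracle comparison stays in seconds.

## Known limitations

- Windowed LD assumes a single chromosome per panel for position searches;
  multi-chromosome inputs should be processed per chromosome.
- The exact tag solver is exponential and refuses precincts above its cap
  rather than degrading silently.
- The imputation screen requires pre-phased study haplotypes; phasing is
  out of scope and unphased input is rejected there.
- The "too similar in probe design" manufacturability removal has no
  public rule; it is modeled only as an explicit exclusion list hook.
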