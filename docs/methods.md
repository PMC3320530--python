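# Methods

## Scope and data model

The package analyses diploid biallelic SNP-array genotypes from a
clonally propagated, strongly stratified gene pool (the *Citrus*
situation: three to four ancestral cultivated species, interspecific
hybrid lineages fixed by apomixis and grafting, and markers ascertained
in a single heterozygous genotype).  Calls live on the alphabet
`{AA, AB, BB, A0, B0, 00, --}` where `0` is a **null allele** — an
allele yielding no array signal (deletion or primer-site polymorphism).
`00` is a called state (a consistent no-signal cluster); `--` is assay
failure.  The storage layer keeps null heterozygotes explicit; every
analysis first applies the *array-observable* collapse `A0 → AA`,
`B0 → BB`, because heterozygous null carriers are indistinguishable
from the expected homozygotes on the platform.  This split between
stored truth and observable state is what lets the synthetic generator
supply exact truth labels while the analyses see only what an array
would report.

## Synthetic generator

The generator reproduces the statistical structure the analyses
assume; it makes no attempt at sequence-level realism.

* **Taxon divergence.** Ancestral allele-B frequency p ~ Uniform(0.05,
  0.95) per locus; each taxon's frequency is Beta-distributed with mean
  p and variance F·p(1−p) (Balding–Nichols).  F is the per-taxon
  divergence knob; the default F = 0.5 for all four taxa produces
  multi-locus Weir–Cockerham Fst ≈ 0.5 between basic taxa, inside the
  0.4–0.8 range typical of strongly stratified perennial gene pools.
* **Default panel.** 600 loci; 12 mandarin-like, 10 pummelo-like, 5
  citron-like and 5 papeda-like accessions drawn under HWE within
  taxon; named hybrids built from one gamete per parent taxon and then
  cloned (fixed heterozygosity), including the discovery genotype
  ("clementine-like", an individual of the mandarin-like taxon), its
  wide-cross partner ("chandler-like", pummelo-like), and
  orange-, lemon- and lime-like hybrid clones; a 52-member F1 progeny
  of the wide cross; a haploid control for duplicated-locus
  confirmation; seed 42.
* **Null alleles.** A null-prone fraction of loci (default 0.2 ≈ the
  observed ~145/828 candidate-locus share) carries a null allele at
  taxon-specific frequencies (defaults 0.80 citron-like, 0.78
  pummelo-like, 0.69 papeda-like, 0.33 mandarin-like, chosen so HWE
  null-homozygote frequencies land near the observed 0.64 / 0.61 /
  0.47 / 0.11 taxon profile).  Nulls are inherited as ordinary alleles.
* **Artefacts.** A duplicated-locus fraction (0.03) is emitted as
  fixed `AB` for every sample including the haploid control; a
  low-quality fraction (0.05) gets 50% missingness to exercise the
  call-rate filter; optional symmetric allele-swap genotyping error
  (default 0 — the reference scenario is error-free); uniform missing
  rate 0.02.
* **Linkage.** Loci are unlinked.  Germplasm LD therefore arises from
  population structure only, which is the contrast under study.  An
  optional per-adjacent-pair recombination fraction can impose linkage
  in the progeny; it is off by default.

What the generator does **not** emulate: intensity-space clustering
(category C1 exists only via its call-rate proxy), mutation,
within-taxon substructure, linked loci in germplasm, and triallelic
sites.  Passing tests therefore demonstrate correctness of the
estimators and the qualitative ascertainment/LD/parentage phenomena
under this model, not performance on any particular real array.

## Marker classification

Categories: C1 call-rate failure; C2 expected segregation of the
heterozygous discovery genotype (1:1 or 1:2:1); C3 heterozygous
discovery genotype with a null allele revealed elsewhere (0B×AB or
00×AB segregation, or a `00` cluster in the germplasm); C4 heterozygous
null in the discovery genotype itself (00×0A and related patterns);
C5 germplasm SNP polymorphism without segregation; C6 null
presence/absence polymorphism only; C7 fixed heterozygous-like
(suspected duplication, confirmed by a heterozygous-like haploid
control); C8 monomorphic.

Numerical choices:

* C1 is operationalized as call rate < 0.8 over all samples — a
  documented proxy, since the underlying phenomenon (no separable
  intensity clusters) is invisible downstream of genotype calls.
* Segregation models are chi-square goodness-of-fit tests on
  observable progeny classes, α = 0.01 per locus without
  multiple-testing correction: this is QC screening, mirroring
  per-locus visual confirmation, not inference.  A model whose state
  space does not contain every observed class is inadmissible (p = 0).
  The best model maximizes the p-value; exact ties prefer a model
  without null alleles (parsimony).
* For a homozygous-looking discovery genotype whose progeny contains
  `00`, the null-het cross family {0A×00, 0A×0A, 0A×0B} is fitted, so
  a null-carrying second parent does not mask C4.
* Conflicting evidence yields `unassigned` with a diagnostic note,
  never a silent guess.
* Valid sets: WONA = C2+C5 and WNA = C3+C4+C6, each restricted to loci
  with ≤ 5% missing data.

Truth labels are assigned by the generator with full knowledge of the
simulated alleles; a null allele visible to truth but hidden from any
observable signal (no `00` anywhere, no informative segregation) is
genuinely unidentifiable and is the principal, small, source of
classification disagreement.  On the default error-free scenario
recovery is ≈ 98%; the C3/C4 component degrades gracefully with
progeny size.

## Diversity statistics

He is the plain Nei form 1 − Σp² (the small-sample 2n/(2n−1)
correction is available behind a flag but off by default, matching the
convention in which the biallelic maximum is exactly 0.5).  Ho is the
fraction of heterozygous calls among typed calls; in null-aware
summaries `00` is excluded from the denominator and its frequency
reported separately, since the null-homozygote class is not a failed
assay but not a heterozygosity observation either.  GD = 1 − Σg² over
observed genotype-state frequencies serves the null-allele sets where
allele frequencies are unobservable.  F = 1 − Ho/He on the pooled
sample; the Weir–Cockerham route gives Fis/Fit/Fst from per-locus
variance components (a, b, c) summed over loci, so the Wright
decomposition (1−Fit) = (1−Fis)(1−Fst) holds exactly.  "±" values are
standard errors over loci; for the F-statistics they come from a
delete-one-locus jackknife.  Cells carrying null alleles are excluded
locus-wise from F-statistics.

## Distances, trees, ordination

Simple matching: d = 1 − mean(m/2) with m the multiset intersection
(0–2) of the two allele pairs, over loci typed in both accessions.
Null-allele sets use genotype-state matching (`00` matches only `00`)
behind a flag; the default distance is meant for the no-null set.
Neighbor-joining is classical Saitou–Nei; ties in the Q-criterion
resolve to the lowest-index pair, and a negative branch length is
clamped to zero with its magnitude transferred to the sister edge (the
cross-check against an independent NJ implementation is part of the
test suite).  Bootstrap support resamples loci with replacement and
counts internal bipartitions; figures conventionally display supports
above 60%, but all values are retained.

PCA operates on the individual × allele-frequency matrix (0/0.5/1 per
locus; one column per locus since the two allele columns are
complementary), centered — not variance-scaled, the columns already
share a scale — on the **active** individuals only.  Supplementary
individuals are projected onto the fixed axes and cannot influence
them, which is what makes hybrid placement relative to parental pools
interpretable.  `00` and missing cells are imputed with the active
column mean.  The cos² of a locus on an axis is its squared
correlation with the axis scores; on a two-taxon active PCA it tracks
the locus' pairwise Fst (r² ≈ 0.9 on the default scenario).

## Linkage disequilibrium

r² is the squared Pearson correlation of 0/1/2 dosage vectors over
pairwise-complete accessions — composite, phase-free LD, the default
because genotypes are unphased.  A classical two-locus EM
haplotype-frequency r² (double heterozygotes phase-resolved
iteratively, D²-based r²) is available behind ``method="em"``; note
its random-mating assumption is dubious for the clonal germplasm
panel, which is why it is not the default.  Significance is a seeded
Monte-Carlo permutation test of one dosage vector, using the same
statistic as the point estimate.  Pairs with fewer than 5 complete observations or zero
variance are skipped with a log entry.  The null expectation of r²
for unlinked loci is ≈ 1/n, so panel means must be compared at equal
or stated sample sizes.

## Parentage

A locus is genotype-incompatible when no gamete pair drawn from the
two parents' observable genotypes reproduces the hybrid's observable
genotype, and orphan-allele when the hybrid carries an allele observed
in neither parent.  The orphan counter is deliberately the lenient
one (orphan ⇒ incompatible), because null alleles make apparent
homozygotes unreliable witnesses of absence: null-aware mode lets any
homozygous parental call `XX` transmit a hidden null, and never
increases either counter.  Hypotheses are ranked by incompatible
count, then orphan count, then name.  Percent agreement is
100·(1 − incompatible/tested) over loci typed in all three members.

## Comparative mapping

A locus is mappable within a species when ≥ 2 observable genotype
states occur there (null sets also count the `00`-vs-called contrast);
for a single accession, mappable = heterozygous.  The pairwise matrix
counts loci mappable in both species.  Because the shared-polymorphism
definition is symmetric, the package emits two explicitly labeled
symmetric matrices (WONA, WNA) plus their sum, rather than packing two
triangles into one table.

## Pipeline and reproducibility

`run_all` derives one 31-bit seed per stage from the root seed by
hashing the stage name, writes every stage output with a SHA-256
digest into `manifest.json`, and aborts-with-partial-manifest on stage
failure.  Reruns with the same config and seed reproduce every digest.
Problem sizes in the shipped analysis scripts (600 loci, 500 bootstrap
replicates, 200 ranking replicates in the tests) keep a full run in
the order of seconds to a minute on one CPU while leaving Monte-Carlo
noise well below the asserted margins.

## Known limitations

* The C2 subcategory with "not totally clear" clustering has no
  genotype-level signature; it is handled only through the
  missing-data filter.
* C4 loci whose second parent carries no null and no `00` progeny
  class are unidentifiable by design; they surface as C5/C8 calls.
* The F column of pooled-sample summaries is Wright's 1 − Ho/He;
  Weir–Cockerham Fis is reported separately rather than silently
  substituted.
* Distances involving accession pairs with no shared typed loci are
  NaN (or an error in strict mode); trees require complete matrices.
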