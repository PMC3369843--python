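# Methods

## The mapping problem

A cis-regulatory site *R* with ancestral allele R and derived allele r makes
Rr heterozygotes express the regulated transcript unequally from their two
chromosomes (allelic imbalance, AI).  AI status is observable per individual;
the *R* site itself is not.  Mapping proceeds by testing every genotyped SNP
(*A* site, alleles A/a) for association with AI status.  The key structural
fact is that under complete LD between a SNP and the *R* site, the two-site
haplotypes form a *trio* — exactly three of the four possible haplotypes are
present, which one is missing identifying the order of the two mutations on
the genealogy (`below`: the A mutation arose on an r background; `above`:
the A mutation came first; `parallel`: disjoint branches).  Any trio forces
the A-site genotype distribution to differ between AI (Rr) and non-AI
(RR, rr) individuals, and in particular at most one A-site homozygote class
can occur among AI individuals.

## The three tests

**Contingency genotype test.**  Counts of {AI, non-AI} × {AA, Aa, aa} in a
2×3 table; exact p by full enumeration over margin-preserving tables under
the multivariate hypergeometric null.  The two-sided p sums the
probabilities of all tables at most as probable as the observed one
(point-probability rule, ties included within a relative tolerance of 1e-7;
log-space binomial coefficients, cached per table).  Individuals with a
missing genotype are dropped from that SNP's table; a degenerate margin
(one phenotype class, or a single nonzero genotype column) gives p = 1 with
a `degenerate` flag.  Cohorts here are at most ~120 individuals, so
enumeration (≤ a few hundred tables) is cheap and unambiguous; no
asymptotic fallback is provided.

**Binomial haplotype test.**  Among AI individuals heterozygous at the
tested SNP, k = number carrying the derived allele on the up-regulated
chromosome, tested against Binomial(n, ½) with the same two-sided
point-probability rule (at p = ½ this equals the doubled-tail rule, a fact
asserted in the tests).  Only AI-and-heterozygous individuals contribute;
n = 0 is degenerate with p = 1.

**Linear regression test.**  Response y ∈ {−1, 0, +1}: the sign of the AI
direction for AI individuals, 0 otherwise.  Predictor x = (derived-allele
indicator on chromosome 1) − (indicator on chromosome 2) ∈ {−1, 0, +1}.
Ordinary least squares slope with a two-sided t-test (n − 2 df).  Any affine
recoding of this ordered-genotype contrast yields the same t-test p, so the
choice of numeric coding is immaterial; the antisymmetric contrast is the
natural partner of the antisymmetric response.  Zero-residual fits with a
nonzero slope are reported at a p-value floor of 1e-300 so that log(1/p)
stays finite; constant predictors give p = 1.

Direction convention: the derived allele r is taken as the up-regulating
one.  The convention is global and arbitrary; flipping it (and/or the A/a
labels) provably changes no p-value, which the suite asserts.  The central
design property — the contingency test's p is bit-identical under any
per-individual chromosome swap or switch-error injection — is asserted on
random fixtures and end-to-end in the hotspot experiment.

## Coalescent simulation framework

Panels of 2n haplotypes are generated with msprime on a unit-length
continuous sequence (infinite-sites binary mutation model, so every site is
bi-allelic with known ancestral state).  One haploid population of size 1
gives pairwise coalescence rate 1, so per-unit mutation and recombination
rates Θ/2 and ρ/2 reproduce the standard coalescent scaling
E[S] = Θ·H(2n−1); the Watterson identity is an oracle test.  Standard
ms-format output is parsed and written, so externally generated panels drop
in bit-for-bit.  Positions live on [0, 1]; base-pair coordinates derive from
Θ/(4·Ne·μ) when Ne and μ are given (Θ = 50, Ne = 12 500, μ = 2e-8 per bp
per generation give a 50 kb segment).  A recombination hotspot is a
three-interval rate map placing `mass_fraction` of the total map into a
central window (default 1 kb of the sequence carrying 90% of ρ).

**Regulatory-site selection.**  The benchmark experiments select, per
replicate, the leftmost segregating site whose derived-allele frequency
lies within a window of the target (±0.10 for targets 0.35/0.5/0.85,
±0.05 for 0.15); replicates with no qualifying site are dropped.  Because
site positions are independent of site frequencies, "leftmost" is a
frequency-unbiased draw from the qualifying set; with the window above it
reproduces the benchmark's achieved-frequency distributions (means
≈ 0.14/0.33/0.49/0.84 with SD ≈ 0.03–0.06) and replicate retention
(≈ 100/97/83/44% of 2000 replicates).  A deliberately narrower
nearest-to-target rule is available (`rule="nearest"`, the library default
for single-site lookups) but concentrates achieved frequencies far more
tightly than the benchmark distributions.  The property test on achieved
means uses max(3·SE, 0.01) as its equivalence scale: 0.01 in allele
frequency is the resolution at which the under-specified selection rule
itself moves the means, so asserting tighter would test the rule choice,
not the code.

**Cohorts and AI assignment.**  Chromosomes are paired uniformly at random
into diploids; the order within a pair defines "chromosome 1/2" for the
phased tests.  AI individuals are the R-site heterozygotes, direction
toward the r-carrying chromosome.  For false-positive rates, AI status is
assigned to a random subset of individuals of fixed size — 12/22/25/13 for
frequency targets 0.15/0.35/0.5/0.85, the expected heterozygote counts at
the achieved frequencies — with independent fair-coin directions (the
haplotype tests need a direction under the null; a fair coin is the
natural null for it).

**Tri-allelic regulatory sites.**  Two SNPs combine into three expressed
haplotype classes at frequencies 0.4/0.3/0.3 (±0.05 per class, ordered site
pairs scanned left to right, first qualifying pair wins).  Two mutation-order
configurations exist without recombination: the second mutation on the
background of the first (`below`; classes {R1R2, r1R2, r1r2}, a nested
trio) or on the ancestral background (`parallel`; {R1R2, r1R2, R1r2},
disjoint).  Expression ranks are 0/1/2 for ancestral/intermediate/derived;
in the disjoint case the more frequent single-mutant class is taken as the
intermediate (the older mutation), ties to the left site.  AI = the two
haplotypes carry different ranks (≈ 66% of individuals at these
frequencies, ~33 of 50), direction toward the higher rank.  The nested
configuration is the higher-power one for all three tests (the up-regulated
chromosome always carries more derived alleles, so A sites tracking either
mutation stay consistent); in the disjoint configuration A sites tracking
the intermediate haplotype point up in (ancestral, intermediate) pairs but
down in (intermediate, derived) pairs, which costs the phased tests most of
their signal at those sites.

**Switch errors.**  The synthetic injector swaps chromosome-1/2 alleles past
a breakpoint for chosen individuals (involutive, asserted).  True phase is
recorded before corruption via a tracking SNP — a site in the terminal 10%
of the sequence opposite the R site, heterozygous in every AI individual,
farthest from the R site when several qualify — and a switch error is
counted for an AI individual when the rephased data link the wrong tracking
allele to the r-carrying chromosome (reported in classes 0/1/2/3+).
External phasing programs plug in through the `PhaserAdapter` contract
(genotypes in, haplotypes out); running them is outside this package's
scope, and the injector is a synthetic stand-in, not an emulation of any
particular tool's error process.

## Benchmark experiments and their scales

All power/FPR figures are pooled over SNPs: the fraction of A-site SNPs
with sample MAF ≥ 5% (the R site itself excluded) reaching p < 0.01,
pooling counts across retained replicates.  Defaults: α = 0.01,
MAF ≥ 0.05.

* **Power/FPR grid** (`run_table1`): 2000 replicates, Θ = 50, 50 diploids,
  ρ = 0 (a ρ = 25 uniform-recombination variant is available); four
  frequency targets; power under causal AI and FPR under random AI in the
  same pass.
* **Hotspot crossing** (`run_table3`): 1000 replicates, Θ = 100, ρ = 50,
  central 1 kb hotspot with 90% of the map; the R site is the leftmost
  qualifying site within the first 10% of the sequence, putting the hotspot
  (≈ 0.1 cM) between it and the rest of the segment.  Reported: the
  proportion of significant SNPs lying across the hotspot midpoint from the
  R site, with true phase or after switch-error corruption (the corruption
  draw is consumed in both modes so the two runs are comparable
  replicate-for-replicate; the contingency cells are bit-identical by
  construction).  SNPs inside the 1 kb window are assigned a side by the
  midpoint — 1 kb of 100 kb, a negligible convention.
* **Tri-allelic grid** (`run_table4`): 2000 replicates as in the power grid;
  both configurations searched per replicate; FPR with 33 random AI
  individuals on qualifying replicates.

These scales run in well under a minute each on one CPU (the 2×3 test is
memoised across identical tables, and the binomial/regression tests are
vectorised across SNPs), so the shipped experiments and the acceptance
script use the full replicate counts rather than scaled-down versions.
Monte-Carlo agreement with reference values is asserted at
max(3·SE, 4 percentage points), SE being the binomial standard error on the
pooled SNP count: pooled SNPs within a replicate share one genealogy, so
the raw pooled SE understates replicate-level noise and the 4-point floor
carries the comparison; reference cells are themselves single stochastic
realizations of a partially specified selection procedure.

Two benchmark cells sit away from our computed values in a way replication
noise does not explain, and are reported as computed rather than adjusted:
the binomial test's null rejection rate at the 0.5 target computes to
≈ 0.1–0.2% (under independent fair-coin directions the rejection region at
n informative heterozygotes has probability ≤ 2^(1−n) plus boundary terms,
which averages well below the nominal 1%), and the hotspot-crossing cell
at the 0.35 target fluctuates between ≈ 4 and 5.5% across master seeds.

## Empirical AI calling and genome scans

Array-style records carry raw two-channel intensities and a per-marker AI
index (|Δ het ratio|).  Informative markers are heterozygous; under the
`significant_only` policy they must also clear a combined-intensity
threshold (default 1000 on the raw X+Y scale — conventionally written as a
log expression, but a log exceeding 1000 is not meaningful, so the
threshold is applied on the raw scale with an optional log transform).  An
individual is AI when the mean absolute index over selected markers exceeds
0.1; markers disagreeing in direction are averaged by magnitude (the call
is directionless — for phased tests the direction must come from the assay
and enters through the AI-status table).  Count-style records are tested
per marker with an exact two-sided binomial against a null reference
fraction (default 0.5; supply per-marker or global values to encode a
mapping-bias correction); one marker with p < 0.01 makes the individual AI,
deliberately without multiple-testing correction across markers.  No
usable markers gives a third state, `undetermined`.

Genome scans read phased or unphased VCF (phase from the standard `|`
separator), HapMap-style genotype TSVs, or a simple phased
haplotype-matrix TSV (round-tripping writer included).  Positions are
1-based in files, 0-based internally.  Per SNP, individuals with missing
genotypes are dropped; monomorphic, MAF-filtered and degenerate SNPs are
returned with reason codes so that output rows plus exclusions equal the
input SNP count.  Unphased records run the contingency test only, with the
phased tests marked not computable.  Raw p-values are reported without
genome-wide correction: true signals appear as LD clusters of significant
SNPs whereas false positives occur alone, and that judgement is left to
the user.

## Known limitations

* The simulation study is the package's evidence base; it assumes a
  constant-size panmictic population, infinite-sites mutation, perfect
  genotyping, complete AI ascertainment, and a single (or single tri-allelic)
  causal site.  Real cohorts violate all of these to some degree, so the
  benchmark power values are upper bounds on field performance;
  the phase-invariance property, being algebraic, transfers exactly.
* Incomplete or noisy AI ascertainment is not modelled.
* The hotspot model is a single central window; arbitrary recombination
  maps beyond it, and demographies other than constant size, are out of
  scope.
* Array-based AI calling averages absolute per-marker indices; signed
  averaging (markers cancelling) is deliberately not offered.
* Exact enumeration of the 2×3 test is designed for cohort-scale tables
  (total ≤ a few hundred); no chi-square fallback exists for very large
  tables.
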