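# Methods

## The problem being modelled

A germline de novo mutation (DNM) is present in an offspring's
constitutive genome but in neither parent's. In trio whole-genome
sequencing, DNMs appear as sites where the child shows a balanced
heterozygous signal and both parents show none; everything else at such
sites — undercalled inherited variants, strand-biased errors, mapping
artifacts in repetitive sequence, parental mosaicism — is noise that a
calling pipeline must remove. The package models the specific study
design of a macaque pedigree in which one dam is homozygous for an
*MBD4* loss-of-function allele. MBD4 excises the thymine from G·T
mismatches produced by deamination of 5-methyl-cytosine; losing it in
the maternal germline produces offspring whose excess DNMs are
maternal-origin C>T at methylated CpG (and, in oocytes, CpA) contexts.

## Synthetic cohorts

The generator is first-class, tested code: it defines the study
conditions under which every downstream module is exercised.

**Reference.** A single random autosomal contig (default 20 Mb,
GC = 0.41) indexed by trinucleotide context so mutations can be placed
at positions matching a sampled substitution channel. Burden is
parameterized per offspring, not per base: the 1.32 Gb nominal callable
genome is carried alongside for rate computation, so desk-scale
runtime coexists with genome-scale statistics.

**Burden.** Control offspring draw Poisson counts around
λ = 10.5 + 1.5·(paternal_age − 10) + 0.4·(maternal_age − 7) mutations.
The slopes are the literature's paternal (~1.5–2/yr) and maternal
(~0.3–0.5/yr) age effects; centering them at the default age-range
midpoints keeps the cohort mean at the configured 10.5. Default
paternal ages are drawn from (7, 13) years: together with the 1.5/yr
slope this reproduces the reported per-offspring count dispersion
(sd ≈ 4.2 vs the study's 4); a wider range would overdisperse the
cohort. Maternal ages are drawn from (4, 10), the dam's reproductive
span.

**Spectrum.** Baseline mutations sample a 96-channel distribution
built from the packaged two-signature catalog — a synthetic stand-in
with the qualitative structure of SBS1 (92% of mass on N[C>T]G,
deamination of methylated CpG) and SBS5 (flat with a mild C>T tilt) —
renormalized from uniform trinucleotide composition to the reference's
own, then mixed 0.2/0.8. A real 96-row catalog can be supplied by
file anywhere the default is used. Hypermutator offspring (exactly
those whose dam is −/−) add Poisson(30) CpG C>T and Poisson(15) CpA
C>T mutations, always maternal; control mutations are paternal with
probability 0.742 (α = 0.742/0.258 ≈ 2.87). Expected hypermutator
means: burden ≈ 55.5 (≈ 5.3-fold over control), CpA C>T share ≈ 28%.
Mutations are sampled independently per offspring; an optional
`shared_mutation_rate` can duplicate mutations across siblings for
testing sharing statistics, but defaults to zero because real cohorts
show near-zero sharing.

**Read evidence.** Depth at each site is Poisson around 23.6× (the
study's mean coverage); heterozygous alt counts are Binomial(DP, 1/2)
(hemizygous male-X sites draw near 1), strand splits Binomial(alt, 1/2),
and parental alt reads are pure sequencing error at 0.002/read — a
post-QC Illumina error rate; at 0.005 the parental-evidence filter
would eat several percent of true DNMs at high depth from error reads
alone. The de novo posterior written for each true site (the emulated
upstream caller's output) is computed from this evidence with a
permissive screening prior of 1e-4: candidate callers are deliberately
permissive — thousands of candidates per genome against ~10 true DNMs
— and their specificity is delegated to the hard filters. The strict
1e-8 site prior remains the analysis-side default of
`denovo_posterior`.

**Artifacts.** Seven configurable classes, each constructed so that
every predicate except its target is satisfied: low-depth sites
(DP < 4), allele-biased sites (VAF ~0.2), strand-biased errors (all
alt reads on one strand), repeat-region sites (placed inside the
simulated repeat mask), common population variants (AF drawn in
(0.02, 0.5) and written to the AF table), undercalled inherited
variants (2–3 parental alt reads at depth 35–60), and parental mosaic
signal (Binomial(DP, 0.15) parental alt reads). The last two both
target the parental-evidence stage, through its two clauses. Artifact
candidates carry an assigned upstream posterior in (0.5, 1] — they
represent the upstream caller's false positives. Default rates are
zero; tests enable one class at a time.

**Phaseability.** Informative sites appear around each DNM as a
Poisson process (default density 1.16e-3/bp within a ±500 bp fragment
window; 30% of generated sites are both-parent-het, hence
uninformative), and each alt-carrying read links to a site with
probability 1 − distance/fragment_length. The density default was
calibrated once so that ~53% of DNMs are phaseable at the default
depth, matching the study's 50–53% phased, and then frozen. Phased
truth is recorded, so concordance is checkable exactly.

## Calling and filtering

`denovo_posterior` enumerates the 27 diploid genotype configurations
with binomial read likelihoods, Hardy–Weinberg parental priors at
population alt frequency 1e-3, Mendelian transmission for the child,
and a flat mutation prior (default 1e-8) for Mendelian-impossible
configurations; the posterior sums configurations where the child
carries an allele absent from both parents. It is a simplified
re-implementation of the class of model used by trio de novo callers;
only the > 0.5 gate semantics matter downstream.

The cascade applies, in order: posterior gate, depth [4, 80] in all
three samples (inclusive, per the protocol's "between"), VAF
[0.35, 0.70] inclusive (male X strict > 0.70; Y excluded), strand
(≥ 2 alt reads, ≥ 1 per strand), repeat mask then segdup mask (BED,
0-based half-open, containment of the single mutated base), population
AF (strictly > 0.01 removed; absent = novel = kept), parental evidence
(> 1 alt read or > 10% VAF in either parent), and a two-sided exact
binomial test of alt count vs DP at p = 1/2 with Benjamini–Hochberg
adjustment grouped per offspring (adjusted p < 0.05 removed; per-
offspring grouping is the smallest reading consistent with the
protocol's "zero to three removed per sample"). Multi-allelic records
are rejected at I/O; candidates are bi-allelic SNVs.

**Sensitivity vs depth.** With Binomial(DP, 1/2) allele sampling, the
inclusive VAF window passes ~89% of true heterozygous sites at
DP ~ Poisson(23.6) (exact tail sums; ~92% at DP = 20, ~97.6% at
DP = 40). Cascade survival of true DNMs therefore sits near 0.89 at
the study's coverage and exceeds 0.95 only for DP ≳ 32; the sensitivity
property test runs at simulated 40×. This is a property of the
thresholds themselves, not of the implementation: an end-to-end control
cohort at 23.6× averages ≈ 9.4 filtered DNMs per offspring against a
true burden of 10.5.

**Stage order.** The site predicates, masks and AF filter are
per-candidate and commute (tested); the binomial/FDR stage is
set-dependent through the BH adjustment and is always terminal.

## Phasing

Trio genotypes classify each nearby heterozygous site: when exactly one
gamete assignment explains the child's two (distinct) alleles, each
allele maps to the parent that transmitted it. Reads carrying the DNM
alt allele vote for the parent implied by their linked informative
allele; unanimity phases the call, any conflict or absence of votes
leaves it unphased (conservative: the tool whose role this logic fills
does not document its conflict handling). Mendelian-inconsistent sites
are logged and skipped rather than raised — they occur at low rate in
real data. α is the paternal:maternal ratio of phased calls, reported
as undefined (None) when the maternal count is zero.

## Spectra and signatures

Spectra are 96-channel counts with purine-centered substitutions
reverse-complemented onto pyrimidine-centered channels. Catalog
renormalization multiplies each channel weight by the ratio of target
to source frequency of its trinucleotide context and renormalizes each
signature column to unit sum; the operation is exactly invertible
(tested to 1e-9) and leaves single-context signatures unchanged.
Exposures are fitted by nonnegative least squares against a chosen
catalog subset — a constrained refit against known signatures, chosen
over de novo factorization because NMF is not reproducible at a
handful of genomes. With ≥ 2000 pooled control mutations the 0.2/0.8
generating mixture is recovered within 0.05. Note that the synthetic
SBS1-like signature is strictly CpG-focused, so hypermutator spectra
(with their CpA excess) fit to a blend rather than loading entirely on
it; with real catalogs the CpA mass would partially load on signature
1's non-CpG channels. Per-context enrichment uses a log-link Poisson
GLM of per-offspring counts on a group indicator (Wald test),
Bonferroni-adjusted across the 16 C>T contexts by default
(conservative; no procedure is dictated by the design), with degenerate
zero-count patterns flagged rather than erroring. The CpA model adds
dam-genotype and parental-age covariates.

## Burden models

Depth quantization uses half-open bins [0,1), [1,4), [4,80), [80,∞)
(depth 4 is callable, 80 is not), applied per base or per BedGraph
interval weighted by span. The mutation rate divides each trio's count
by its callable bases — a haploid denominator, the only convention
under which 10.5 DNMs / 1.32 Gb reproduces the published ~0.8e-8 per
bp per generation — and averages per-trio rates (the pooled alternative
is also reported). Burden GLMs are Poisson with log link, fitted by
IRLS (statsmodels); covariates enter untransformed, and callable bases
enter as a covariate rather than an offset because the study treats it
as a modelled effect and reports it non-significant. Constant
covariates raise a named identifiability error; the pipeline drops
structurally constant terms (e.g. the heterozygous-dam indicator in a
cohort with no carriers) before fitting. The interaction model adds
hypermutator × maternal-age.

## Gene screens

Both screens consume pre-annotated variant tables (annotation is an
input, not computed here). The private-homozygote screen keeps
variants homozygous-alternate in the proband with population AF
strictly below 1% and not homozygous in any other parent. The
biallelic-damaging screen restricts to high/moderate-impact variants
in a supplied gene list and reports (gene, parent) pairs with either a
homozygous damaging variant or ≥ 2 heterozygous damaging variants —
unphased compound hets count as candidates and are flagged as such,
since rare pairs cannot be phased statistically in small pedigrees.

## Problem sizes, determinism, numerical choices

Default end-to-end analyses run 200 control and 50 hypermutator trios
on a 20 Mb reference — enough for cohort means with standard errors of
a few percent while completing in well under a minute. One integer
seed feeds a root generator whose spawned substreams drive reference,
pedigree, masks, truth and evidence; identical seeds give identical
outputs byte for byte. The posterior is computed in log space with a
max-shift; NNLS comes from scipy; exact binomial p-values from scipy's
`binomtest`; ties at VAF bin edges are resolved by the inclusive-bound
convention above.

## What passing tests do and do not show

The generator emulates read-count statistics, not reads: there is no
alignment, mapping ambiguity, base-quality structure, indel error,
GC-coverage bias, or linkage disequilibrium, and the reference is a
random sequence whose CpG density is not depleted as in real genomes.
Consequently, passing tests establish that the pipeline's decision
logic is correct under its stated statistical model — filter semantics,
phasing logic, renormalization algebra, estimator calibration — not
that the thresholds would achieve the same sensitivity/specificity on
real alignments. Sex chromosomes are exercised at the filter level
only; the default cohorts are autosomal. Overdispersed (negative
binomial) burden models and indel/doublet signatures are out of scope.
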