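# Methods

## Model

`methylsnp` genotypes one reference position at a time.  The sample is
assumed diploid, sites independent, reads independent given the
genotype, and the two alleles equally likely to be sequenced.  The
posterior over the ten unordered allele pairs is computed in log space
as π(G)·Pr(D|G), normalized over all ten genotypes; the reported score
is 10·log₁₀ of the best/next-best posterior ratio (a phred-scaled odds
ratio, matching VCF QUAL conventions; ties score 0 and break in
canonical lexicographic genotype order).  The per-allele likelihoods
shared by all genotypes containing an allele are computed once per
locus, which is mathematically identical to the naive 10-genotype loop.

The observation model works entirely in reference-forward space.  For a
cytosine allele, reads whose original template is the strand carrying
the C are bisulfite-affected: the template base is C with probability
p_C = β(1−γ) + (1−β)α and T otherwise, then a symmetric ε-error layer
is applied (matching base 1−ε, each other base ε/3).  This two-stage
generative form normalizes exactly over the four observable bases,
which the test suite verifies against exhaustive enumeration of the
latent (methylated, converted, error) states.  Guanine alleles are the
mirror image on reverse-template reads, where conversion appears as
G→A.  With α = γ = 0 and β = 1 the cytosine model reduces exactly to
the plain error model.

Orientation normalization exploits a SAM property: reverse-strand
alignments are stored reverse-complemented, so both mates of a fragment
already display the template strand's substitution class (C→T for
original-top, G→A for original-bottom) in aligned coordinates.  Mate 2
therefore needs no extra complementing; what it needs is the correct
template-strand label (the reverse of its own mapped strand) and its
original sequencing cycle (counted from the instrument's 5' end).

### Genotype priors

Published descriptions of this prior family tie π(G) to the reference
base and population data without printing numbers, so the allocation is
defined here explicitly and is fully configurable: the reference homozygote
receives 1−θ with θ = 10⁻³ at novel sites and 0.1 at known-variant
sites (classical nuclear heterozygosity and the common prior for known
polymorphic sites); the variant mass θ is spread over the other nine
genotypes with transition alleles weighted 2:1 over transversions,
reference-containing heterozygotes weighted 2:1 over non-reference
homozygotes, and double-novel-allele heterozygotes carrying an extra
factor of θ (two mutation events).  When a known-site record carries
allele frequencies, listed alleles absorb the variant mass
proportionally (mixed 95:5 with the transition weights so unlisted
alleles keep support).  An unresolvable reference base (N) yields a
uniform prior.

### Methylation priors (β)

Three modes: `naive` fixes β = 0.5; `context` learns per-IUPAC-context
means (default contexts CG and CH) in a two-round procedure — a naive
first round, selection of non-known-variant loci whose homozygous
cytosine genotype has posterior > 0.9999, per-context averaging of
c/(c+t), then a second calling round — and `locus` (the default) uses
the same pileup's c/(c+t) directly, which is the only mode that can
track the strongly bimodal CpG distribution.  All modes fall back to
0.5 where no information exists.  Context matching respects user order
for overlapping patterns; reverse-strand cytosines match against the
reverse-complemented window.  For candidate cytosine alleles at
non-cytosine reference bases, context mode matches the flanking bases
with the center requirement waived.

### Methylation reporting

Methylation is c/(c+t) over the cytosine strand only (forward-template
C vs T for a C allele; reverse-template G vs A for a G allele).  Two
genotypes are flagged not-measurable and omitted from methylation
output: C/T hets (the T allele's forward-strand reads are
indistinguishable from converted C reads) and, by the same strand
symmetry, A/G hets.  Phasing reads to alleles, which would recover
allele-specific methylation at such sites, is out of scope.

## Recalibration

Empirical mismatches against the reference are binned by reported
quality, cycle, and mate end, skipping known-variant sites.  The
bisulfite-ambiguous class — T at a reference C on forward-template
reads, A at a reference G on reverse-template reads — is the "fifth
base": it increments a bin's observation count but never its mismatch
count, and its own quality is passed through unchanged.  Removing the
class from the denominator as well would bias bins upward in error: a
converted cytosine would then surface only through its sequencing
errors, two thirds of which are mismatches; under the test conditions
(true error 1%) that inflates rich bins from ~Q20 to ~Q18.7.  New
qualities are Laplace-smoothed, −10·log₁₀((mm+1)/(n+2)), capped at Q60;
bins below 100 observations fall back to the per-quality marginal, then
to the reported value.  Covariates stop at (quality, cycle, mate end);
dinucleotide context is deliberately not modeled.

## Filters

Read prefilters drop unmapped/secondary reads, mapping quality < 30
(strict, as printed), multi-mapped reads, marked duplicates, and
improper pairs.  The 5′ non-conversion mask walks each read from its
sequencing 5′ end and removes unconverted bisulfite-strand cytosines at
reference cytosines until the first converted one; it is switchable off
for RRBS, whose informative cytosines sit at fragment starts.

Site filters label, never delete: depth > 120; strand bias > −0.02;
quality-by-depth < 1.0 (variant calls with alt support only); ≥ 2
variant calls within a 10 bp window (all members labeled); and ≥ 40
raw reads with > 10% at mapping quality 0 (tallied before prefilters).

The strand-bias score is a per-depth log₁₀ likelihood ratio: the best
"alt confined to one strand" binomial model (residual rate 10⁻³ on the
clean strand) against a strand-free alt fraction, divided by depth.
Balanced alt evidence scores well below −0.02; one-sided alt evidence
scores near or above 0.  Two bisulfite-specific design choices make the
score meaningful on converted data: the counts fed to it exclude any
strand on which conversion smears the ref/alt distinction (forward when
a C is involved, reverse for a G), and a site whose informative
evidence lives entirely on one strand returns a sentinel (never
filtered) — otherwise every newly created unmethylated cytosine allele,
whose evidence is structurally single-stranded, would be discarded and
heterozygote sensitivity would collapse.  The −0.02 cutoff is honored
against this reconstruction; the historical formula it stands in for is
not recoverable from the published description.

## Simulator

The generator emulates mammalian directional WGBS: a first-order Markov
reference at GC 0.41 with a configurable CpG dinucleotide factor;
SNPs placed per-base at 10⁻³ with 67% heterozygous, transitions
weighted 2:1 (quadrupled at CpG sites, where deamination of methylated
cytosines concentrates C>T variation); CpG methylation drawn from a
0.7/0.3 mixture of Beta(8,2) and Beta(1,20) (the observed bimodality of
mammalian CpGs), CpH from Beta(1,99) (mean 0.01), with the two
cytosines of a CpG dyad sharing one level; fragments placed uniformly
on both haplotypes and template strands (Poisson per-locus coverage),
default 75 bp single-end at mean 30×, flat Q30 error, optional
paired-end with proper FR flags; conversion applied per template
cytosine via (β, α, γ) before the error layer; reported qualities
offset from truth by a single `miscalibration` parameter.  Every read
records its latent draws (haplotype, window, conversions, errors), so
the truth set can replay any read byte-identically; all randomness
flows from one seed.

What it does not emulate — and therefore what passing tests cannot
certify on real data: mapping and alignment error, indels, PCR
duplicates and amplification bias, quality decay along cycles and other
non-flat error profiles, context-dependent error, RRBS fragment-end
chemistry, and non-directional protocols.  Results on simulation are
statements about the model arithmetic and pipeline plumbing under
clean alignments, not about robustness to artifacts upstream of the
caller.

Per-locus downsampling keeps z = round(m·n/N) of m observations (N the
dataset mean coverage, n the target), seeded; the CLI's read-level
`downsample` achieves the same expectation by independent thinning with
probability n/N.

## Evaluation harness

Sensitivity and FDR are swept over the call score per truth stratum:
homozygous cytosines, all heterozygotes, C/T-like heterozygotes (C/T
and its strand mirror A/G), and the remaining heterozygotes.  A true
positive requires the exact truth genotype; false positives are counted
over all evaluated loci, so the two het sub-strata share the het FP
pool.  The operating point is the least stringent threshold with
FDR < 0.05.  The k-allele, reference-cytosine (Berman-style), and
Shoemaker-style baselines are reimplemented from their published
descriptions; the Shoemaker Fisher-test expectations are a
reconstruction (observed allele counts tested against each genotype's
implied counts, the two allele p-values multiplied and normalized), as
the original supplement's exact arithmetic is not public here.  The
k-allele "n ≥ 10" branch reads its threshold as ceil(n·K/10); the
Berman-style default k is 10%.

Two evaluation-design choices matter for interpreting the acceptance
checks.  The ROC comparison against k-allele is computed over the
identical universe of site-filter-passing loci for both methods, since
the filter stack is shared preprocessing that a bare count rule never
sees — at ~70 truth hets a single cluster-filtered true SNP would
otherwise decide the verdict.  The C/T-vs-other heterozygote ordering
is read out at 8× (downsampled from the same 30× run): at full
coverage both strata saturate near sensitivity 1.0 and their order is
single-locus noise, while at sub-saturating coverage the conversion
ambiguity that makes C/T hets harder is actually expressed.

## Problem sizes and numerical choices

The acceptance analyses use a 100 kb genome at 30× (≈ 40 000 reads,
≈ 100 000 loci, ~100 true SNPs) — large enough that homozygous-cytosine
sensitivity is measured on ~40 000 loci while the full pipeline runs in
a few minutes; recalibration recovery uses 50 kb at 30× with 50 bp
reads so every (quality, cycle) bin holds ~30 000 observations and the
±1 phred check is far outside sampling noise.  Heterozygote strata hold
only ~60–70 loci at this scale, so het sensitivities carry ~±4%
binomial noise; genome-scale analogues of these numbers would be
measured on hundreds of thousands of sites.  Per-locus methylation recovery
is scored against the conversion-adjusted expected C fraction
p* = β(1−γ) + (1−β)α (error-adjusted), since c/(c+t) estimates p*, not
β, and at β ∈ {0,1} a raw ±3·SE(β) band has zero width; consistency is
judged by the exact binomial central region equivalent to the 3 SE
normal band (two-sided p ≥ 0.0027), the correct discrete analogue at
small expected counts.  Likelihoods are evaluated in log space;
empty pileups return the prior; observations with base N or ε ≥ 1 are
excluded before the model; β outside [0,1] raises.

## Known limitations

Single-sample, SNV-only (no indels), no read-backed phasing and hence
no allele-specific methylation; local realignment is assumed done
upstream; duplicate marking is honored, not performed; the strand-bias
formula and the Shoemaker scoring are reconstructions calibrated to
their published cutoffs rather than recovered source; `--threads` is
accepted for interface compatibility but contigs are processed
serially (results are independent of it by construction).
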