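# methylsnp

Simultaneous SNP genotyping and DNA methylation calling from directional
bisulfite sequencing (WGBS/RRBS) alignments.

Bisulfite treatment converts unmethylated cytosines to thymines, which
breaks two assumptions every conventional SNP caller makes: the two
strands of a read pileup are no longer complementary, and a C→T
substitution can be either a real SNP or a conversion event.  Getting
this wrong corrupts both outputs: unrecognized C/T SNPs masquerade as
unmethylated cytosines, and methylation-aware pipelines that only score
reference cytosines miss every cytosine the sample gained.  `methylsnp`
addresses both problems with a single Bayesian model evaluated per
reference position, for anyone analyzing directional bisulfite data —
methylation consumers who want SNP-cleaned methylation levels, and
variant consumers who want genotypes out of an existing WGBS run.

## The model

At each position with base calls D = (D₁, …, D_r), the posterior over
the ten diploid genotypes G = AB is

    Pr(G | D) = π(G) · Pr(D | G) / Σ_G' π(G') Pr(D | G'),
    Pr(D | G = AB) = ∏ⱼ [ ½ Pr(Dⱼ | A) + ½ Pr(Dⱼ | B) ]

with π(G) built from the reference base, a heterozygosity θ (raised at
known-variant sites), and transition/transversion weighting.  For A and
T alleles, Pr(Dⱼ | allele) is the usual error model (1 − ε for a match,
ε/3 otherwise, ε from the phred quality).  For a C allele, reads from
the strand carrying the C pass through the conversion chemistry first:
the template is read as C with probability

    p_C = β(1 − γ) + (1 − β)α,        p_T = 1 − p_C

where β is the methylation prior, α the under-conversion rate (default
0.0025) and γ the over-conversion rate (default 0); sequencing error is
applied on top.  Reads from the opposite strand are untouched by
conversion and use the plain error model.  G alleles mirror this with
reverse-template reads (G→A in reference-forward space).  β can be
fixed at 0.5 (`naive`), learned per sequence context (`context`, a
two-round procedure over high-confidence homozygous cytosines), or taken
per locus as c/(c+t) (`locus`, the default).  The emitted score is the
phred-scaled odds ratio 10·log₁₀ of best versus second-best genotype,
and methylation is reported as C/(C+T) over the cytosine strand only.

Around the model sit the standard production pieces: bisulfite-aware
base-quality recalibration (T at a reference C is a "fifth base" that
never counts as a mismatch), a 5′ non-conversion read mask, read
prefilters, site filters (depth, strand bias, quality-by-depth, SNP
cluster, MQ0 regions), VCF 4.1 / BED6+2 / wiggle writers, a fully seeded
read simulator that generates truth sets, and reimplementations of three
published baseline callers with a sensitivity/FDR evaluation harness.

## Worked example

Simulate a 20 kb diploid genome with directional 30× reads, then call
it:

```bash
methylsnp simulate --outdir sim --genome-length 20000 --coverage 30 --seed 42
# simulated 8000 reads over 20000 bp (21 variants), seed 42
methylsnp call --input-bam sim/reads.sam --reference sim/reference.fa \
    --out-vcf calls.vcf --out-methylation-dir meth
# [chr1] 19994 loci, 21 variant calls
```

The VCF carries the genotype, score, filter labels and annotations, plus
methylation in the FORMAT fields:

```text
#CHROM  POS   ID  REF  ALT  QUAL    FILTER  INFO                      FORMAT          sample
chr1    603   .   T    C    166.40  PASS    DP=29;QD=23.77            GT:DP:CM:CU:MP  0/1:29:.:.:.
chr1    1777  .   T    A    78.24   PASS    DP=34;SB=-1.4118;QD=2.30  GT:DP:CM:CU:MP  1/1:34:.:.:.
chr1    2195  .   G    C    220.48  PASS    DP=27;QD=220.48;CX=CH     GT:DP:CM:CU:MP  0/1:27:0:6:0.00
```

Position 603 is a T/C heterozygote called with QUAL 166.4 (the
best/next-best odds ratio in phred); its methylation fields are `.`
because a C/T-style het has no measurable methylation.  Position 1777 is
a homozygous T→A substitution; SB is its strand-bias score (well below
the −0.02 cutoff, so it passes).  Position 2195 gained a cytosine allele
relative to the reference; its six informative C-strand reads were all
converted, so the new cytosine is 0% methylated (CM:CU = 0:6).

One BED6+2 file is written per cytosine context (`meth/methylation.CG.bed`,
`meth/methylation.CH.bed`), with the methylation percentage in the score
column and the C+T coverage and percentage as the two extra columns:

```text
chr1  56  57  CG  70.00  +  10  70.00
chr1  57  58  CG  71.43  -   7  71.43
chr1  61  62  CG   0.00  +  12   0.00
```

The first two lines are the two strands of one CpG dyad, measured
independently at 70% and 71% — the simulator assigns dyads a shared
methylation level, and the two strand estimates agree to sampling noise.

`methylsnp recalibrate` rewrites base qualities from empirical mismatch
tables, `methylsnp compare` runs the caller plus the k-allele baseline
against a truth VCF and writes a threshold/sensitivity/FDR table, and
`methylsnp downsample` thins reads toward a target coverage.

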