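"""Synthetic-data generator for directional bisulfite sequencing.

Generates a random reference, a diploid sample genome with SNPs, a
per-cytosine methylation truth table, and directional bisulfite reads
with controlled under/over-conversion and sequencing error.  Only the two
original bisulfite-converted template strands are sequenced (directional
protocol); paired-end mode emits mate 2 as the complementary strand of
the same template, which in aligned reference-forward space shows the
template's own substitution class.

Defaults emulate mammalian whole-genome bisulfite sequencing: GC content
0.41, SNP rate 1e-3 with two thirds heterozygous and a 2:1
transition:transversion ratio (boosted toward C>T/G>A at CpG sites, whose
deamination of methylated cytosines dominates mammalian variation),
bimodal CpG methylation (a 70:30 mixture of Beta(8,2) and Beta(1,20)),
near-zero CpH methylation (mean 0.01), 75 bp single-end reads at Q30 and
mean coverage 30.  Coverage is Poisson per locus via uniform fragment
placement; alignment is bypassed (reads carry their true coordinates).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .beta import reverse_complement
from .model import (
    BASES,
    Genotype,
    PileupLocus,
    TRANSITION,
    make_genotype,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated dataset (see module docstring
    for what the defaults emulate)."""

    genome_length: int = 100_000
    gc_content: float = 0.41
    cpg_enrichment: float = 1.0
    snp_rate: float = 1e-3
    het_fraction: float = 0.67
    titv_ratio: float = 2.0
    cpg_titv_boost: float = 4.0
    cg_high_weight: float = 0.7
    cg_high: tuple[float, float] = (8.0, 2.0)
    cg_low: tuple[float, float] = (1.0, 20.0)
    beta_ch: float = 0.01
    alpha: float = 0.0025
    gamma: float = 0.0
    coverage: float = 30.0
    read_length: int = 75
    paired: bool = False
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    true_quality: float = 30.0
    miscalibration: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "snp_rate", "het_fraction", "alpha", "gamma"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")


@dataclass
class Variant:
    position: int  # 0-based
    ref: str
    hap_alleles: tuple[str, str]

    @property
    def genotype(self) -> Genotype:
        return make_genotype(*self.hap_alleles)

    @property
    def alts(self) -> list[str]:
        seen: list[str] = []
        for a in self.hap_alleles:
            if a != self.ref and a not in seen:
                seen.append(a)
        return seen


@dataclass
class SimRead:
    """One simulated aligned read plus its latent provenance."""

    name: str
    start: int
    length: int
    haplotype: int
    template: str  # '+' or '-'
    is_reverse: bool
    mate_end: int
    seq: str
    quals: list[int]
    conversions: list[int] = field(default_factory=list)  # offsets converted
    errors: list[tuple[int, str]] = field(default_factory=list)
    mate_start: int = -1


@dataclass
class TruthSet:
    """Simulated genome, methylation truth, variants, and reads."""

    params: SimParams
    contig: str
    reference: str
    haplotypes: tuple[str, str]
    variants: list[Variant]
    methylation: dict[tuple[int, str], tuple[float, str]]
    reads: list[SimRead] = field(default_factory=list)

    def genotype_at(self, position: int) -> Genotype:
        return make_genotype(self.haplotypes[0][position], self.haplotypes[1][position])

    def variant_positions(self) -> set[int]:
        return {v.position for v in self.variants}

    # -- file emission ----------------------------------------------------

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.contig}\n")
            for i in range(0, len(self.reference), 70):
                fh.write(self.reference[i : i + 70] + "\n")
        pysam.faidx(path)

    def write_truth_vcf(self, path: str) -> None:
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("##fileformat=VCFv4.1\n")
            fh.write(f"##contig=<ID={self.contig},length={len(self.reference)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
            for v in sorted(self.variants, key=lambda v: v.position):
                alts = v.alts
                alleles = [v.ref] + alts
                gt = "/".join(str(alleles.index(a)) for a in v.hap_alleles)
                fh.write(
                    f"{self.contig}\t{v.position + 1}\t.\t{v.ref}\t{','.join(alts)}"
                    f"\t.\tPASS\t.\tGT\t{gt}\n"
                )

    def write_methylation_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\tstrand\tcontext\tbeta\n")
            for (pos, strand), (beta, context) in sorted(self.methylation.items()):
                fh.write(f"{self.contig}\t{pos}\t{strand}\t{context}\t{beta:.6f}\n")

    def sam_header(self) -> dict:
        return {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.contig, "LN": len(self.reference)}],
        }

    def write_sam(self, path: str) -> None:
        header = pysam.AlignmentHeader.from_dict(self.sam_header())
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for rec in sorted(self.reads, key=lambda r: r.start):
                out.write(self._to_segment(rec, header))

    def _to_segment(self, rec: SimRead, header) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment(header)
        seg.query_name = rec.name
        seg.query_sequence = rec.seq
        seg.query_qualities = rec.quals
        seg.reference_id = 0
        seg.reference_start = rec.start
        seg.cigartuples = [(0, rec.length)]
        seg.mapping_quality = 60
        flag = 0
        if rec.is_reverse:
            flag |= 0x10
        if rec.mate_start >= 0:
            flag |= 0x1 | 0x2  # paired, proper
            flag |= 0x80 if rec.mate_end == 2 else 0x40
            if not rec.is_reverse:
                flag |= 0x20  # mate is on the opposite strand
            seg.next_reference_id = 0
            seg.next_reference_start = rec.mate_start
            tlen = (
                rec.mate_start + rec.length - rec.start
                if rec.mate_start >= rec.start
                else -(rec.start + rec.length - rec.mate_start)
            )
            seg.template_length = tlen
        seg.flag = flag
        return seg


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _draw_sequence(p: SimParams, rng: np.random.Generator) -> str:
    """First-order Markov sequence with the requested GC content and CpG
    dinucleotide enrichment factor."""
    base_p = np.array(
        [(1 - p.gc_content) / 2, p.gc_content / 2, p.gc_content / 2, (1 - p.gc_content) / 2]
    )
    # transition rows: after C, scale G by the enrichment factor
    after_c = base_p.copy()
    after_c[2] *= p.cpg_enrichment
    after_c /= after_c.sum()
    seq = np.empty(p.genome_length, dtype=np.int8)
    draws = rng.random(p.genome_length)
    cum = np.cumsum(base_p)
    cum_c = np.cumsum(after_c)
    prev = -1
    for i in range(p.genome_length):
        c = cum_c if prev == 1 else cum
        seq[i] = int(np.searchsorted(c, draws[i], side="right"))
        prev = seq[i]
    return "".join(BASES[b] for b in seq)


def _is_cpg_site(reference: str, pos: int) -> bool:
    b = reference[pos]
    if b == "C":
        return pos + 1 < len(reference) and reference[pos + 1] == "G"
    if b == "G":
        return pos > 0 and reference[pos - 1] == "C"
    return False


def simulate_genome(p: SimParams, rng: Optional[np.random.Generator] = None):
    """Reference plus diploid sample genome and its variant list."""
    rng = rng or np.random.default_rng(p.seed)
    reference = _draw_sequence(p, rng)
    hap = [list(reference), list(reference)]
    variants: list[Variant] = []
    snp_positions = np.nonzero(rng.random(p.genome_length) < p.snp_rate)[0]
    for pos in snp_positions:
        ref = reference[pos]
        others = [b for b in BASES if b != ref]
        ts_weight = p.titv_ratio
        if _is_cpg_site(reference, pos):
            ts_weight *= p.cpg_titv_boost
        weights = np.array(
            [ts_weight if b == TRANSITION[ref] else 1.0 for b in others]
        )
        alt = others[int(rng.choice(3, p=weights / weights.sum()))]
        if rng.random() < p.het_fraction:
            which = int(rng.integers(2))
            alleles = (alt, ref) if which == 0 else (ref, alt)
        else:
            alleles = (alt, alt)
        for h in (0, 1):
            hap[h][pos] = alleles[h]
        variants.append(Variant(int(pos), ref, alleles))
    return reference, ("".join(hap[0]), "".join(hap[1])), variants


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _draw_cg_beta(p: SimParams, rng: np.random.Generator) -> float:
    if rng.random() < p.cg_high_weight:
        return float(rng.beta(*p.cg_high))
    return float(rng.beta(*p.cg_low))


def _draw_ch_beta(p: SimParams, rng: np.random.Generator) -> float:
    if p.beta_ch <= 0.0:
        return 0.0
    if p.beta_ch >= 1.0:
        return 1.0
    # Beta(1, b) with mean beta_ch
    return float(rng.beta(1.0, 1.0 / p.beta_ch - 1.0))


def assign_methylation(
    haplotypes: tuple[str, str],
    p: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> dict[tuple[int, str], tuple[float, str]]:
    """Per-cytosine-per-strand truth methylation (beta, context).

    Every position carrying a C on either strand of either haplotype gets
    a beta drawn from its context distribution; the two cytosines of a CpG
    dyad share a single beta (biological strand symmetry).
    """
    rng = rng or np.random.default_rng(p.seed + 1)
    table: dict[tuple[int, str], tuple[float, str]] = {}
    for hap in haplotypes:
        n = len(hap)
        for i, b in enumerate(hap):
            if b == "C" and (i, "+") not in table:
                if i + 1 < n and hap[i + 1] == "G":
                    beta = _draw_cg_beta(p, rng)
                    table[(i, "+")] = (beta, "CG")
                    table.setdefault((i + 1, "-"), (beta, "CG"))
                else:
                    table[(i, "+")] = (_draw_ch_beta(p, rng), "CH")
            elif b == "G" and (i, "-") not in table:
                if i > 0 and hap[i - 1] == "C":
                    beta = _draw_cg_beta(p, rng)
                    table[(i, "-")] = (beta, "CG")
                    table.setdefault((i - 1, "+"), (beta, "CG"))
                else:
                    table[(i, "-")] = (_draw_ch_beta(p, rng), "CH")
    return table


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _apply_bisulfite(
    window: list[str],
    start: int,
    template: str,
    methylation,
    p: SimParams,
    rng: np.random.Generator,
) -> list[int]:
    """Convert the template strand's cytosines in place; returns converted
    offsets."""
    converted = []
    target, product = ("C", "T") if template == "+" else ("G", "A")
    for i, b in enumerate(window):
        if b != target:
            continue
        entry = methylation.get((start + i, template if template == "+" else "-"))
        beta = entry[0] if entry is not None else 0.0
        meth = rng.random() < beta
        conv = (rng.random() < p.gamma) if meth else (rng.random() >= p.alpha)
        if conv:
            window[i] = product
            converted.append(i)
    return converted


def _apply_errors(
    window: list[str],
    is_reverse: bool,
    p: SimParams,
    rng: np.random.Generator,
) -> list[tuple[int, str]]:
    e_true = 10.0 ** (-p.true_quality / 10.0)
    errors = []
    hits = np.nonzero(rng.random(len(window)) < e_true)[0]
    for i in hits:
        old = window[i]
        window[i] = rng.choice([b for b in BASES if b != old])
        errors.append((int(i), window[i]))
    return errors


def simulate_reads(
    truth_or_haps,
    methylation=None,
    p: Optional[SimParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SimRead]:
    """Directional bisulfite reads over the diploid sample genome.

    Accepts either a TruthSet (methylation/params taken from it) or the
    (hap1, hap2) pair plus explicit methylation table and params.
    Fragments are placed uniformly on both haplotypes and both template
    strands; conversion is applied on the template strand, then per-base
    sequencing error at the true quality, with reported qualities offset
    by the miscalibration parameter.
    """
    if isinstance(truth_or_haps, TruthSet):
        truth = truth_or_haps
        haplotypes, methylation, p = truth.haplotypes, truth.methylation, truth.params
    else:
        haplotypes = truth_or_haps
        if methylation is None or p is None:
            raise ValueError("methylation table and params required")
    if p.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = rng or np.random.default_rng(p.seed + 2)

    L = len(haplotypes[0])
    rl = p.read_length
    reported_q = int(round(min(93, max(2, p.true_quality + p.miscalibration))))
    reads: list[SimRead] = []

    if not p.paired:
        n_reads = int(round(p.coverage * L / rl))
        for k in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            hap = int(rng.integers(2))
            template = "+" if rng.random() < 0.5 else "-"
            window = list(haplotypes[hap][start : start + rl])
            conv = _apply_bisulfite(window, start, template, methylation, p, rng)
            is_reverse = template == "-"
            errors = _apply_errors(window, is_reverse, p, rng)
            reads.append(
                SimRead(
                    name=f"sim{k}",
                    start=start,
                    length=rl,
                    haplotype=hap,
                    template=template,
                    is_reverse=is_reverse,
                    mate_end=1,
                    seq="".join(window),
                    quals=[reported_q] * rl,
                    conversions=conv,
                    errors=errors,
                )
            )
        return reads

    n_frags = int(round(p.coverage * L / (2 * rl)))
    for k in range(n_frags):
        flen = max(rl, int(round(rng.normal(p.fragment_mean, p.fragment_sd))))
        flen = min(flen, L)
        start = int(rng.integers(0, L - flen + 1))
        hap = int(rng.integers(2))
        template = "+" if rng.random() < 0.5 else "-"
        frag = list(haplotypes[hap][start : start + flen])
        conv = _apply_bisulfite(frag, start, template, methylation, p, rng)
        left = frag[:rl]
        right = frag[flen - rl :]
        # mate 1 sits at the template's 5' end; mate 2 at the other end on
        # the opposite mapped strand
        if template == "+":
            mates = [(left, start, False, 1), (right, start + flen - rl, True, 2)]
        else:
            mates = [(right, start + flen - rl, True, 1), (left, start, False, 2)]
        positions = [m[1] for m in mates]
        for idx, (window, mstart, is_rev, end) in enumerate(mates):
            window = list(window)
            errors = _apply_errors(window, is_rev, p, rng)
            conv_local = [c - (mstart - start) for c in conv if 0 <= c - (mstart - start) < rl]
            reads.append(
                SimRead(
                    name=f"sim{k}",
                    start=mstart,
                    length=rl,
                    haplotype=hap,
                    template=template,
                    is_reverse=is_rev,
                    mate_end=end,
                    seq="".join(window),
                    quals=[reported_q] * rl,
                    conversions=conv_local,
                    errors=errors,
                    mate_start=positions[1 - idx],
                )
            )
    return reads


def rebuild_read(truth: TruthSet, rec: SimRead) -> str:
    """Reconstruct a read's sequence from its recorded latent draws.

    Replays the haplotype window, the recorded conversion offsets, and the
    recorded error substitutions; byte-identity with rec.seq is the
    provenance invariant of the simulator.
    """
    window = list(truth.haplotypes[rec.haplotype][rec.start : rec.start + rec.length])
    product = "T" if rec.template == "+" else "A"
    for off in rec.conversions:
        window[off] = product
    for off, base in rec.errors:
        window[off] = base
    return "".join(window)


def simulate_truth_set(p: SimParams, contig: str = "chr1") -> TruthSet:
    """One-call generator: genome + methylation + reads under p.seed."""
    rng = np.random.default_rng(p.seed)
    reference, haplotypes, variants = simulate_genome(p, rng)
    methylation = assign_methylation(haplotypes, p, rng)
    truth = TruthSet(
        params=p,
        contig=contig,
        reference=reference,
        haplotypes=haplotypes,
        variants=variants,
        methylation=methylation,
    )
    truth.reads = simulate_reads(truth, rng=rng)
    return truth


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample_pileup(
    locus: PileupLocus,
    n: float,
    N: float,
    seed: int | np.random.Generator = 0,
) -> PileupLocus:
    """Randomly retain z = round(m n / N) of the locus's m observations.

    N is the dataset's mean coverage before downsampling, n the target
    mean coverage; loci already at or below z are returned unchanged.
    """
    if N <= 0 or not (0 < n <= N):
        raise ValueError("need N > 0 and 0 < n <= N")
    m = locus.depth
    z = int(round(m * n / N))
    if m <= z:
        return locus
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = sorted(rng.choice(m, size=z, replace=False))
    return PileupLocus(
        contig=locus.contig,
        position=locus.position,
        ref_base=locus.ref_base,
        observations=[locus.observations[i] for i in idx],
        total_reads=locus.total_reads,
        mq0_reads=locus.mq0_reads,
    )
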