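"""Readers and writers for the standard formats the caller touches.

SAM/BAM ingestion and pileup construction are built on pysam; known
variants are read from VCF (standing in for a dbSNP dump); outputs are
VCF 4.1 (genotypes, scores, filters, methylation), BED6+2 (one file per
cytosine context, score column = methylation percentage, extra columns =
C/T coverage and the percentage repeated numerically) and wiggle
(methylation percentage only).  Internal coordinates are 0-based
half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import gzip
import math
import sys
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .beta import _fetch
from .filters import FilterThresholds, five_prime_nonconversion_mask
from .model import GenotypeCall, ModelParams, PileupLocus, phred_to_prob
from .recalibration import normalize_read_orientation
from .filters import read_prefilters


def _opener(path: str, mode: str = "wt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


# ---------------------------------------------------------------------------
# known sites
# ---------------------------------------------------------------------------

@dataclass
class KnownSiteRecord:
    contig: str
    position: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    alt_frequencies: dict[str, float]


class KnownSites:
    """Queryable known-variant set keyed by (contig, 0-based position)."""

    def __init__(self) -> None:
        self._sites: dict[tuple[str, int], KnownSiteRecord] = {}

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._sites

    def __len__(self) -> int:
        return len(self._sites)

    def get(self, contig: str, position: int) -> Optional[KnownSiteRecord]:
        return self._sites.get((contig, position))

    def add(self, rec: KnownSiteRecord) -> None:
        key = (rec.contig, rec.position)
        prev = self._sites.get(key)
        if prev is not None:  # multi-allelic split across records
            alts = tuple(dict.fromkeys(prev.alts + rec.alts))
            freqs = {**prev.alt_frequencies, **rec.alt_frequencies}
            rec = KnownSiteRecord(rec.contig, rec.position, rec.ref, alts, freqs)
        self._sites[key] = rec


def load_known_sites(path: str) -> KnownSites:
    """Load a VCF of known variants (all alt alleles retained; AF INFO
    values kept when present)."""
    sites = KnownSites()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            freqs: dict[str, float] = {}
            info_af = rec.info.get("AF") if "AF" in rec.info else None
            if info_af is not None:
                if not isinstance(info_af, (tuple, list)):
                    info_af = (info_af,)
                for alt, af in zip(alts, info_af):
                    if af is not None:
                        freqs[alt] = float(af)
            sites.add(
                KnownSiteRecord(rec.chrom, rec.pos - 1, rec.ref, alts, freqs)
            )
    return sites


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def pileup_iterator(
    alignments,
    reference,
    t: FilterThresholds | None = None,
    params: ModelParams | None = None,
    contig: Optional[str] = None,
    five_prime_filter: bool = True,
    recal_table=None,
) -> Iterator[PileupLocus]:
    """Stream PileupLocus objects in coordinate order.

    Applies, in order: read prefilters, orientation normalization, the 5'
    non-conversion mask (switchable off for RRBS), and the exclusive
    base-quality cutoff.  Raw depth and MAPQ-0 counts are tallied before
    prefiltering so the MQ0-region site filter can see them.  When a
    RecalTable is supplied, base qualities are recalibrated on the fly.

    ``alignments`` may be a path or an open pysam.AlignmentFile whose
    reads are coordinate-sorted.
    """
    t = t or FilterThresholds()
    params = params or ModelParams()
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments

    from .recalibration import apply_recalibration

    pending: dict[int, PileupLocus] = {}
    raw_depth: dict[int, list[int]] = {}  # pos -> [total, mq0]
    current_contig: Optional[str] = None
    last_start = -1

    def flush(upto: Optional[int]) -> Iterator[PileupLocus]:
        for pos in sorted(pending):
            if upto is not None and pos >= upto:
                break
            locus = pending.pop(pos)
            raw = raw_depth.pop(pos, [0, 0])
            locus.total_reads, locus.mq0_reads = raw
            if locus.observations:
                yield locus

    try:
        reads = af.fetch(contig) if contig is not None else af
    except ValueError:
        reads = af

    for read in reads:
        if read.is_unmapped:
            continue
        if current_contig is not None and read.reference_name != current_contig:
            yield from flush(None)
            raw_depth.clear()
            last_start = -1
        elif read.reference_start < last_start and current_contig == read.reference_name:
            raise ValueError(
                "input alignments are not coordinate-sorted; sort the BAM/SAM "
                "(samtools sort) and retry"
            )
        current_contig = read.reference_name
        last_start = read.reference_start
        yield from flush(read.reference_start)

        # raw-depth tallies (before prefilters)
        for pos in range(read.reference_start, read.reference_end or read.reference_start):
            raw = raw_depth.setdefault(pos, [0, 0])
            raw[0] += 1
            if read.mapping_quality == 0:
                raw[1] += 1

        keep, _ = read_prefilters(read, t)
        if not keep:
            continue
        if recal_table is not None:
            read = apply_recalibration(read, recal_table, reference)
        obs_list = normalize_read_orientation(read)
        if not obs_list:
            continue
        span_start = read.reference_start
        span = _fetch(
            reference, read.reference_name, span_start,
            read.reference_end or span_start,
        )
        if span is None:
            raise ValueError(
                f"reference lookup failed at {read.reference_name}:"
                f"{span_start}; check the FASTA and its .fai index"
            )
        ref_bases = []
        valid = []
        for rpos, obs in obs_list:
            ref_bases.append(span[rpos - span_start])
            valid.append((rpos, obs))
        if five_prime_filter:
            mask = five_prime_nonconversion_mask(valid, ref_bases)
        else:
            mask = [False] * len(valid)
        for (rpos, obs), masked, rb in zip(valid, mask, ref_bases):
            if masked:
                continue
            q = -10.0 * math.log10(obs.epsilon)
            if q <= params.min_base_quality:  # "greater than 5" is exclusive
                continue
            locus = pending.get(rpos)
            if locus is None:
                locus = PileupLocus(
                    contig=read.reference_name, position=rpos, ref_base=rb
                )
                pending[rpos] = locus
            locus.observations.append(obs)

    yield from flush(None)
    if own:
        af.close()


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_FILTER_DEFS = [
    ("HighDepth", "Coverage depth above the maximum"),
    ("StrandBias", "Strand bias score above the cutoff"),
    ("LowQD", "Quality by depth below the minimum"),
    ("SnpCluster", "Two or more variant calls within the cluster window"),
    ("MQ0Region", "Excess fraction of mapping-quality-zero reads"),
]


def _format_genotype(call: GenotypeCall, ref: str, alts: list[str]) -> str:
    alleles = [ref] + alts
    idx = []
    for a in call.best:
        idx.append(alleles.index(a) if a in alleles else ".")
    return "/".join(str(i) for i in sorted(idx, key=str))


def write_vcf(
    calls: Sequence[GenotypeCall],
    params: ModelParams | None = None,
    thresholds: FilterThresholds | None = None,
    path: str = "-",
    sample: str = "sample",
    contig_lengths: Optional[dict[str, int]] = None,
    command_line: Optional[str] = None,
    emit: str = "variants+cytosines",
) -> None:
    """Write calls as VCF 4.1.

    QUAL carries the phred-scaled best/next-best odds-ratio score, GT the
    best genotype, INFO the depth/strand-bias/quality-by-depth
    annotations plus cytosine context, and FORMAT the methylation
    percentage with its C/T depth.  ``emit`` selects 'variants',
    'variants+cytosines' (default) or 'all'.
    """
    params = params or ModelParams()
    thresholds = thresholds or FilterThresholds()
    fh = sys.stdout if path == "-" else _opener(path)
    try:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write("##source=methylsnp\n")
        if command_line:
            fh.write(f"##methylsnp_command={command_line}\n")
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for name, desc in _VCF_FILTER_DEFS:
            fh.write(f'##FILTER=<ID={name},Description="{desc}">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">\n')
        fh.write('##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias score">\n')
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=CX,Number=1,Type=String,Description="Cytosine context">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">\n')
        fh.write('##FORMAT=<ID=CM,Number=1,Type=Integer,Description="Methylated (C) reads on the cytosine strand">\n')
        fh.write('##FORMAT=<ID=CU,Number=1,Type=Integer,Description="Unmethylated (T) reads on the cytosine strand">\n')
        fh.write('##FORMAT=<ID=MP,Number=1,Type=Float,Description="Methylation percentage">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")

        for call in calls:
            ref = call.locus.ref_base.upper()
            is_cytosine = "C" in call.best or "G" in call.best
            if emit == "variants" and not call.is_variant:
                continue
            if emit == "variants+cytosines" and not (call.is_variant or is_cytosine):
                continue
            alts = sorted({a for a in call.best if a != ref})
            alt_field = ",".join(alts) if alts else "."
            filt = ";".join(sorted(call.filters)) if call.filters else "PASS"
            info = [f"DP={call.locus.depth}"]
            sb = getattr(call, "sb", None)
            qd = getattr(call, "qd", None)
            if sb is not None and sb != float("-inf"):
                info.append(f"SB={sb:.4f}")
            if qd is not None:
                info.append(f"QD={qd:.2f}")
            if call.context:
                info.append(f"CX={call.context}")
            gt = _format_genotype(call, ref, alts)
            if call.methylation_fraction is not None:
                mp = f"{100.0 * call.methylation_fraction:.2f}"
                sample_field = f"{gt}:{call.locus.depth}:{call.c_reads}:{call.t_reads}:{mp}"
            else:
                sample_field = f"{gt}:{call.locus.depth}:.:.:."
            fh.write(
                f"{call.locus.contig}\t{call.locus.position + 1}\t.\t{ref}\t{alt_field}"
                f"\t{call.score:.2f}\t{filt}\t{';'.join(info)}"
                f"\tGT:DP:CM:CU:MP\t{sample_field}\n"
            )
    finally:
        if fh is not sys.stdout:
            fh.close()


# ---------------------------------------------------------------------------
# methylation output
# ---------------------------------------------------------------------------

@dataclass
class MethylationRecord:
    """BED6+2 methylation record: score = methylation percentage, plus
    C/T coverage and the percentage repeated as a numeric column."""

    contig: str
    start: int
    end: int
    name: str
    score: float  # 0..100
    strand: str
    coverage: int
    methylation_percent: float

    def bed_line(self) -> str:
        return (
            f"{self.contig}\t{self.start}\t{self.end}\t{self.name}"
            f"\t{self.score:.2f}\t{self.strand}\t{self.coverage}"
            f"\t{self.methylation_percent:.2f}\n"
        )


def methylation_records(
    calls: Iterable[GenotypeCall], context: str
) -> Iterator[MethylationRecord]:
    for call in calls:
        if call.context != context:
            continue
        if call.methylation_fraction is None:
            continue
        pct = 100.0 * call.methylation_fraction
        yield MethylationRecord(
            contig=call.locus.contig,
            start=call.locus.position,
            end=call.locus.position + 1,
            name=context,
            score=pct,
            strand=call.methylation_strand or "+",
            coverage=call.c_reads + call.t_reads,
            methylation_percent=pct,
        )


def write_methylation(
    calls: Sequence[GenotypeCall],
    contexts: Sequence[str],
    fmt: str = "bed",
    outdir: str = ".",
    prefix: str = "methylation",
) -> list[str]:
    """One methylation file per cytosine context; returns the paths.

    C/T-heterozygous (and mirrored A/G) loci, where methylation is not
    measurable, are omitted by construction (their fraction is None).
    """
    import os

    if fmt not in ("bed", "wig"):
        raise ValueError("format must be 'bed' or 'wig'")
    paths = []
    for context in contexts:
        ext = "bed" if fmt == "bed" else "wig"
        path = os.path.join(outdir, f"{prefix}.{context}.{ext}")
        with _opener(path) as fh:
            if fmt == "bed":
                for rec in methylation_records(calls, context):
                    fh.write(rec.bed_line())
            else:
                fh.write(f'track type=wiggle_0 name="{prefix}.{context}"\n')
                current = None
                for rec in methylation_records(calls, context):
                    if rec.contig != current:
                        fh.write(f"variableStep chrom={rec.contig}\n")
                        current = rec.contig
                    fh.write(f"{rec.start + 1}\t{rec.methylation_percent:.2f}\n")
        paths.append(path)
    return paths
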