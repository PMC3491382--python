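"""Read prefilters, the 5' non-conversion mask, and the pre-call site
filter stack.

Site filters label calls rather than deleting them; the labels surface in
the VCF FILTER column (HighDepth, StrandBias, LowQD, SnpCluster,
MQ0Region).  Thresholds follow the boundary semantics as printed: depth
strictly above 120 fails, mapping quality strictly below 30 drops a read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import binom

from .model import GenotypeCall, PileupLocus, ReadObservation

FILTER_HIGH_DEPTH = "HighDepth"
FILTER_STRAND_BIAS = "StrandBias"
FILTER_LOW_QD = "LowQD"
FILTER_SNP_CLUSTER = "SnpCluster"
FILTER_MQ0 = "MQ0Region"

SB_SENTINEL = -math.inf


@dataclass(frozen=True)
class FilterThresholds:
    min_mapping_quality: int = 30
    max_depth: int = 120
    sb_cutoff: float = -0.02
    min_qd: float = 1.0
    cluster_window: int = 10
    cluster_min: int = 2
    mq0_fraction: float = 0.10
    mq0_min_reads: int = 40
    remove_duplicates: bool = True
    require_proper_pair: bool = True


def read_prefilters(read, t: FilterThresholds | None = None) -> tuple[bool, Optional[str]]:
    """Keep/drop decision for an aligned read, with the drop reason.

    Drops unmapped and secondary/supplementary alignments, reads below the
    mapping-quality cutoff, multi-mapping reads (XT:A:R or mapping quality
    0), marked duplicates, and improperly paired mates of paired data.
    """
    t = t or FilterThresholds()
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False, "unmapped_or_secondary"
    if read.mapping_quality < t.min_mapping_quality:
        return False, "mapq"
    try:
        if read.has_tag("XT") and read.get_tag("XT") == "R":
            return False, "multimap"
    except (KeyError, AttributeError):
        pass
    if t.remove_duplicates and read.is_duplicate:
        return False, "duplicate"
    if t.require_proper_pair and read.is_paired and not read.is_proper_pair:
        return False, "not_proper_pair"
    return True, None


def five_prime_nonconversion_mask(
    observations: Sequence[tuple[int, ReadObservation]],
    reference_bases: Sequence[str],
) -> list[bool]:
    """Mask of leading unconverted cytosines of one read.

    ``observations`` are a single read's (position, observation) pairs in
    reference order with ``reference_bases`` the matching reference bases.
    Walking from the read's 5' end (left for forward templates, right for
    reverse), every bisulfite-strand C at a reference C is masked until the
    first reference C observed as converted (T); a read with no converted
    C keeps all its reference-C cytosines masked.  Returns True where the
    observation must be excluded.
    """
    n = len(observations)
    mask = [False] * n
    if n == 0:
        return mask
    template = observations[0][1].template_strand
    order = range(n) if template == "forward" else range(n - 1, -1, -1)
    # in forward-normalized space, the bisulfite strand's C/T pair is
    # C/T at reference C (forward template) or G/A at reference G (reverse)
    ref_c, read_c, read_t = ("C", "C", "T") if template == "forward" else ("G", "G", "A")
    for i in order:
        if reference_bases[i].upper() != ref_c:
            continue
        base = observations[i][1].base
        if base == read_t:
            break
        if base == read_c:
            mask[i] = True
    return mask


def strand_bias(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """Per-depth log10 likelihood-ratio strand-bias score.

    Compares the best "alt confined to one strand" binomial model against
    a strand-free alt fraction; strongly negative for strand-balanced alt,
    near or above zero when the alt evidence sits on one strand.  Zero alt
    reads (or no coverage on one strand, where confinement is
    unassessable) return the -inf sentinel, which is never filtered.
    """
    for c in (ref_fwd, ref_rev, alt_fwd, alt_rev):
        if c < 0:
            raise ValueError("counts must be non-negative")
    alt = alt_fwd + alt_rev
    n_fwd = ref_fwd + alt_fwd
    n_rev = ref_rev + alt_rev
    depth = n_fwd + n_rev
    if depth == 0:
        raise ValueError("depth must be positive")
    if alt == 0 or n_fwd == 0 or n_rev == 0:
        return SB_SENTINEL

    p0 = alt / depth
    l0 = binom.logpmf(alt_fwd, n_fwd, p0) + binom.logpmf(alt_rev, n_rev, p0)

    floor = 1e-3  # residual error rate on the alt-free strand
    p_f = min(1.0, alt / n_fwd)
    l_fwd = binom.logpmf(alt_fwd, n_fwd, p_f) + binom.logpmf(alt_rev, n_rev, floor)
    p_r = min(1.0, alt / n_rev)
    l_rev = binom.logpmf(alt_rev, n_rev, p_r) + binom.logpmf(alt_fwd, n_fwd, floor)

    return float((max(l_fwd, l_rev) - l0) / math.log(10.0) / depth)


def quality_by_depth(score: float, alt_supporting_reads: int) -> float:
    """QD = call score per alt-supporting read (variant calls only)."""
    if score < 0:
        raise ValueError("score must be non-negative")
    return score / max(1, alt_supporting_reads)


def _strand_informative(ref: str, alt: str) -> tuple[bool, bool]:
    """(forward usable, reverse usable) for distinguishing ref vs alt.

    Bisulfite conversion smears C->T on forward-template reads and G->A on
    reverse-template reads, so a strand whose reads cannot separate the two
    alleles is excluded from strand-bias/alt counting.
    """
    fwd = "C" not in (ref, alt)
    rev = "G" not in (ref, alt)
    return fwd, rev


def informative_allele_counts(
    locus: PileupLocus, ref: str, alt: str
) -> tuple[int, int, int, int]:
    """(ref_fwd, ref_rev, alt_fwd, alt_rev) over bisulfite-informative
    strands only; an uninformative strand contributes zero counts."""
    use_fwd, use_rev = _strand_informative(ref, alt)
    rf = rr = af = ar = 0
    for o in locus.observations:
        fwd = o.template_strand == "forward"
        if fwd and not use_fwd:
            continue
        if not fwd and not use_rev:
            continue
        if o.base == ref:
            rf, rr = (rf + 1, rr) if fwd else (rf, rr + 1)
        elif o.base == alt:
            af, ar = (af + 1, ar) if fwd else (af, ar + 1)
    return rf, rr, af, ar


def _variant_annotations(call: GenotypeCall) -> tuple[float, float, int]:
    """(SB, QD, alt_reads) for a variant call."""
    ref = call.locus.ref_base.upper()
    alts = [a for a in call.best if a != ref]
    best_sb = SB_SENTINEL
    alt_total = 0
    for alt in set(alts):
        rf, rr, af, ar = informative_allele_counts(call.locus, ref, alt)
        alt_total += af + ar
        if af + ar + rf + rr > 0:
            sb = strand_bias(rf, rr, af, ar)
            best_sb = max(best_sb, sb)
    qd = quality_by_depth(call.score, alt_total)
    return best_sb, qd, alt_total


def site_filters(
    calls: Sequence[GenotypeCall],
    pileups=None,
    t: FilterThresholds | None = None,
) -> Sequence[GenotypeCall]:
    """Annotate position-sorted calls with the site filter labels.

    Labels (never deletes): HighDepth (depth > max_depth), StrandBias
    (SB > cutoff), LowQD (QD < minimum; variant calls only), SnpCluster
    (>= cluster_min variant calls within cluster_window bp; every member
    labeled), MQ0Region (>= mq0_min_reads raw reads with more than
    mq0_fraction at mapping quality 0).  Also records sb/qd annotations on
    each call.
    """
    t = t or FilterThresholds()
    prev = None
    for call in calls:
        key = (call.locus.contig, call.locus.position)
        if prev is not None and key < prev:
            raise ValueError("calls must be sorted by (contig, position)")
        prev = key

    for call in calls:
        locus = call.locus
        if locus.depth > t.max_depth:
            call.filters.add(FILTER_HIGH_DEPTH)
        if locus.total_reads >= t.mq0_min_reads and locus.total_reads > 0:
            if locus.mq0_reads / locus.total_reads > t.mq0_fraction:
                call.filters.add(FILTER_MQ0)
        if call.is_variant:
            sb, qd, alt_reads = _variant_annotations(call)
            call.sb = sb
            call.qd = qd
            if sb > t.sb_cutoff:
                call.filters.add(FILTER_STRAND_BIAS)
            if alt_reads > 0 and qd < t.min_qd:
                call.filters.add(FILTER_LOW_QD)
        else:
            call.sb = None
            call.qd = None

    # SNP cluster: sliding window over variant positions per contig
    variants = [c for c in calls if c.is_variant]
    by_contig: dict[str, list[GenotypeCall]] = {}
    for c in variants:
        by_contig.setdefault(c.locus.contig, []).append(c)
    for group in by_contig.values():
        pos = [c.locus.position for c in group]
        for i, c in enumerate(group):
            neighbours = 0
            j = i - 1
            while j >= 0 and pos[i] - pos[j] < t.cluster_window:
                neighbours += 1
                j -= 1
            j = i + 1
            while j < len(group) and pos[j] - pos[i] < t.cluster_window:
                neighbours += 1
                j += 1
            if neighbours + 1 >= t.cluster_min:
                c.filters.add(FILTER_SNP_CLUSTER)
    return calls
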