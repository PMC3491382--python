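"""Bisulfite-aware empirical base-quality recalibration.

Reported instrument qualities are compared with empirical mismatch rates
against the reference, binned by reported quality R and sequencing cycle C
(and mate end).  The bisulfite twist: a thymine observed where the
reference has a cytosine cannot be distinguished from a legitimate
bisulfite conversion, so such bases are treated as a fifth base "X":
they are never counted as mismatches (they increment a bin's observation
count like any non-error base) and their own qualities are never
rewritten — the X group is estimated separately, here by passing the
reported value through.  Excluding X from the denominator as well would
bias the bins: a converted cytosine would then contribute only its
sequencing errors, two thirds of which are mismatches.  In aligned
reference-forward space the X class is T-at-ref-C on reads whose
template is the forward strand, and the mirrored A-at-ref-G on
reverse-template reads (which is where the "second end" adenine rule of
paired-end data lands once mate 2 is orientation-normalized).

Sites present in the known-variant set are skipped: a mismatch there may
be a real allele, not a sequencing error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .beta import _fetch
from .model import ReadObservation, phred_to_prob, prob_to_phred

MAX_QUALITY = 60.0


@dataclass
class RecalTable:
    """Empirical (observations, mismatches) counts per
    (reported quality, cycle, mate end) bin."""

    bins: dict[tuple[int, int, int], list[int]] = field(default_factory=dict)
    min_bin_count: int = 100
    stats: dict[str, int] = field(default_factory=dict)

    def add(self, reported_q: int, cycle: int, end: int, mismatch: bool) -> None:
        bin_ = self.bins.setdefault((reported_q, cycle, end), [0, 0])
        bin_[0] += 1
        bin_[1] += int(mismatch)

    def marginal(self, reported_q: int, end: int) -> tuple[int, int]:
        n = mm = 0
        for (r, _c, e), (bn, bmm) in self.bins.items():
            if r == reported_q and e == end:
                n += bn
                mm += bmm
        return n, mm

    def recalibrated_quality(self, reported_q: int, cycle: int, end: int) -> float:
        """Empirical quality of the (R, C, end) bin, falling back to the
        (R, end) marginal below min_bin_count, else the reported value."""
        bin_ = self.bins.get((reported_q, cycle, end))
        if bin_ is not None and bin_[0] >= self.min_bin_count:
            return empirical_quality(bin_[0], bin_[1])
        n, mm = self.marginal(reported_q, end)
        if n >= self.min_bin_count:
            return empirical_quality(n, mm)
        return float(reported_q)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("reported_quality\tcycle\tmate_end\tobservations\tmismatches\tempirical_quality\n")
            for (r, c, e) in sorted(self.bins):
                n, mm = self.bins[(r, c, e)]
                fh.write(f"{r}\t{c}\t{e}\t{n}\t{mm}\t{empirical_quality(n, mm):.2f}\n")

    @classmethod
    def from_tsv(cls, path: str, min_bin_count: int = 100) -> "RecalTable":
        table = cls(min_bin_count=min_bin_count)
        with open(path) as fh:
            next(fh)
            for line in fh:
                r, c, e, n, mm = line.split("\t")[:5]
                table.bins[(int(r), int(c), int(e))] = [int(n), int(mm)]
        return table


def empirical_quality(observations: int, mismatches: int) -> float:
    """Laplace-smoothed phred quality of a count bin, capped at Q60."""
    if observations < 0 or mismatches < 0:
        raise ValueError("counts must be non-negative")
    rate = (mismatches + 1) / (observations + 2)
    return min(MAX_QUALITY, -10.0 * math.log10(rate))


def template_strand_of(read) -> str:
    """Strand of the original bisulfite-converted template of an aligned
    read (directional protocol).

    Mate 1 (or a single-end read) sequences the converted template itself,
    so its mapped strand is the template strand.  Mate 2 sequences the
    complementary strand of the same template and maps to the opposite
    strand, so its template is the reverse of its own mapped strand.
    """
    if read.is_paired and read.is_read2:
        return "forward" if read.is_reverse else "reverse"
    return "reverse" if read.is_reverse else "forward"


def normalize_read_orientation(read) -> list[tuple[int, ReadObservation]]:
    """Per-base observations of an aligned read in reference-forward space.

    Returns (reference_position, observation) pairs for aligned (non-clip,
    non-indel) bases.  SAM already stores reverse-strand alignments
    reverse-complemented, so mate-2 bases arrive pre-complemented and show
    the same substitution class as the template strand; this function adds
    the derived template strand and the original sequencing cycle (counted
    from the instrument's 5' end, so reverse-mapped reads count from the
    right).  N bases and malformed alignments yield no observations.
    """
    try:
        pairs = read.get_aligned_pairs(matches_only=True)
    except (ValueError, AttributeError):
        return []
    quals = read.query_qualities
    seq = read.query_sequence
    if seq is None or quals is None:
        return []
    qlen = len(seq)
    template = template_strand_of(read)
    end = 2 if (read.is_paired and read.is_read2) else 1
    out = []
    for qpos, rpos in pairs:
        base = seq[qpos].upper()
        if base not in "ACGT":
            continue
        q = quals[qpos]
        cycle = qlen - qpos if read.is_reverse else qpos + 1
        obs = ReadObservation(
            base=base,
            epsilon=max(phred_to_prob(q), 1e-10) if q > 0 else 1.0,
            template_strand=template,
            cycle=cycle,
            mapping_quality=read.mapping_quality,
            mate_end=end,
            duplicate_flag=read.is_duplicate,
            properly_paired=read.is_proper_pair if read.is_paired else True,
        )
        out.append((rpos, obs))
    return out


def is_x_base(ref_base: str, obs: ReadObservation) -> bool:
    """True for the bisulfite-ambiguous "5th base": T at a reference C on
    a forward-template read, or A at a reference G on a reverse-template
    read."""
    if ref_base == "C" and obs.template_strand == "forward" and obs.base == "T":
        return True
    if ref_base == "G" and obs.template_strand == "reverse" and obs.base == "A":
        return True
    return False


def build_recal_table(
    reads: Iterable,
    reference,
    known_sites=None,
    min_bin_count: int = 100,
    thresholds=None,
) -> RecalTable:
    """Tabulate empirical mismatches over an alignment stream.

    Sites in ``known_sites`` are skipped; X bases (see is_x_base) count
    as observations but never as mismatches.  Reads are prefiltered with
    the standard read prefilters.
    """
    from .filters import FilterThresholds, read_prefilters

    thresholds = thresholds or FilterThresholds()
    table = RecalTable(min_bin_count=min_bin_count)
    stats = table.stats
    for key in (
        "reads_used", "reads_dropped", "x_excluded",
        "ref_c_forward_increments", "ref_c_forward_non_t",
    ):
        stats.setdefault(key, 0)

    for read in reads:
        keep, _reason = read_prefilters(read, thresholds)
        if not keep:
            stats["reads_dropped"] += 1
            continue
        stats["reads_used"] += 1
        contig = read.reference_name
        span_start = read.reference_start
        span = _fetch(reference, contig, span_start, read.reference_end or span_start)
        if span is None:
            raise ValueError(f"reference contig {contig!r} not found or too short")
        for rpos, obs in normalize_read_orientation(read):
            ref_base = span[rpos - span_start]
            if ref_base not in "ACGT":
                continue
            if known_sites is not None and (contig, rpos) in known_sites:
                continue
            reported_q = int(round(prob_to_phred(obs.epsilon)))
            if is_x_base(ref_base, obs):
                # 5th base: an observation, never a mismatch
                stats["x_excluded"] += 1
                table.add(reported_q, obs.cycle, obs.mate_end, False)
                continue
            is_mismatch = obs.base != ref_base
            table.add(reported_q, obs.cycle, obs.mate_end, is_mismatch)
            if ref_base == "C" and obs.template_strand == "forward":
                stats["ref_c_forward_increments"] += 1
                stats["ref_c_forward_non_t"] += int(obs.base != "T")
                stats["ref_c_forward_mismatches"] = (
                    stats.get("ref_c_forward_mismatches", 0) + int(is_mismatch)
                )
    return table


def apply_recalibration(
    read,
    table: RecalTable,
    reference=None,
    known_sites=None,
):
    """Replace a read's base qualities with recalibrated values in place.

    Base identities are never changed.  When ``reference`` is supplied,
    X-base positions (bisulfite-ambiguous, never tabulated) keep their
    original reported quality; unaligned (clipped) bases always do.
    Returns the read.
    """
    quals = read.query_qualities
    if quals is None:
        return read
    new = list(quals)
    contig = read.reference_name
    qlen = len(read.query_sequence or "")
    end = 2 if (read.is_paired and read.is_read2) else 1
    for rpos, obs in normalize_read_orientation(read):
        if reference is not None:
            ref_base = _fetch(reference, contig, rpos, rpos + 1)
            if ref_base is not None and is_x_base(ref_base.upper(), obs):
                continue
        cycle = obs.cycle
        qpos = qlen - cycle if read.is_reverse else cycle - 1
        reported_q = quals[qpos]
        new[qpos] = int(round(table.recalibrated_quality(int(reported_q), cycle, end)))
    read.query_qualities = new
    return read
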