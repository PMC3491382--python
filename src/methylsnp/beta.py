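"""Estimation of the methylation prior beta used by the cytosine
observation model, and IUPAC cytosine-context matching.

Three estimation modes are supported:

naive    beta = 0.5 everywhere (used as round 1 of the context mode).
context  per-context means (e.g. beta_CG, beta_CH) learned from
         high-confidence non-SNP homozygous cytosines called in a first,
         naive round.
locus    beta = c/(c+t) from the same pileup being genotyped (the
         default): robust to the strongly bimodal CpG methylation
         distribution that genome-wide means cannot represent.

Cytosine contexts are written as IUPAC degeneracy strings whose scored C
sits at ``offset`` (CG, CH, CHH, CCGG, ...); reverse-strand cytosines are
matched against the reverse-complemented reference window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import GenotypeCall, PileupLocus

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContextPattern:
    """A cytosine sequence context, e.g. CG, CH, CHH or CCGG.

    ``offset`` is the position of the scored cytosine within the pattern
    (0 for the common mammalian contexts; 1 for the second C of CCGG when
    scoring MspI sites at that base).
    """

    pattern: str
    offset: int = 0

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat:
            raise ValueError("empty context pattern")
        for ch in pat:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in {pat!r}")
        if not (0 <= self.offset < len(pat)) or pat[self.offset] != "C":
            raise ValueError(f"position {self.offset} of {pat!r} is not C")
        object.__setattr__(self, "pattern", pat)

    def __str__(self) -> str:  # file naming / labels
        return self.pattern


def parse_contexts(spec: str) -> list[ContextPattern]:
    """Parse a comma-separated IUPAC context list, e.g. ``"CG,CH"``."""
    return [ContextPattern(tok.strip()) for tok in spec.split(",") if tok.strip()]


@dataclass
class BetaEstimate:
    """Container for the beta values a calling run works from."""

    mode: str
    per_context: dict[str, float] = field(default_factory=dict)
    per_locus: Optional[dict] = None
    alpha_source: Optional[float] = None  # e.g. chrM non-conversion rate


def _fetch(genome, contig: str, start: int, end: int) -> Optional[str]:
    """Window of reference sequence; None when out of bounds.

    Accepts pyfaidx.Fasta, pysam.FastaFile, or a plain mapping of contig
    name to sequence string.
    """
    if start < 0:
        return None
    try:
        if hasattr(genome, "fetch"):  # pysam.FastaFile
            seq = genome.fetch(contig, start, end)
        elif isinstance(genome, dict):
            seq = genome[contig][start:end]
        else:  # pyfaidx.Fasta
            seq = str(genome[contig][start:end])
    except (KeyError, IndexError, ValueError):
        return None
    if len(seq) != end - start:
        return None
    return seq.upper()


def match_context(
    genome,
    contig: str,
    position: int,
    strand: str,
    patterns: Iterable[ContextPattern],
    require_center_c: bool = True,
) -> Optional[ContextPattern]:
    """First pattern (in user order) matching the strand-appropriate
    sequence around ``position`` (0-based).

    For the reverse strand the window is reverse-complemented so patterns
    are always read 5'->3' along the strand carrying the C.  With
    ``require_center_c=False`` the scored position itself is not checked
    (used to pick a context beta for a candidate cytosine allele whose
    reference base differs).
    """
    for pat in patterns:
        n, off = len(pat.pattern), pat.offset
        if strand in ("+", "forward"):
            window = _fetch(genome, contig, position - off, position - off + n)
        else:
            window = _fetch(genome, contig, position - (n - 1 - off), position + off + 1)
            if window is not None:
                window = reverse_complement(window)
        if window is None:
            continue
        ok = True
        for i, code in enumerate(pat.pattern):
            if i == off and not require_center_c:
                continue
            if window[i] not in IUPAC[code]:
                ok = False
                break
        if ok:
            return pat
    return None


def beta_naive() -> float:
    """Uninformative methylation prior: every read equally likely
    methylated or not."""
    return 0.5


def beta_context(
    first_round_calls: Iterable[GenotypeCall],
    known_sites=None,
    patterns: Iterable[ContextPattern] = (),
    min_posterior: float = 0.9999,
) -> dict[str, float]:
    """Per-context mean methylation from high-confidence non-SNP
    homozygous cytosines of a naive first calling round.

    A locus qualifies when the posterior of its homozygous-cytosine
    genotype (C/C forward, G/G reverse) exceeds ``min_posterior``, it is
    absent from the known-variant set, and it has informative coverage.
    Contexts with no qualifying loci fall back to the naive 0.5 (with a
    warning).
    """
    patterns = list(patterns)
    sums: dict[str, float] = {str(p): 0.0 for p in patterns}
    counts: dict[str, int] = {str(p): 0 for p in patterns}
    for call in first_round_calls:
        if call.best not in (("C", "C"), ("G", "G")):
            continue
        if call.posterior.get(call.best, 0.0) <= min_posterior:
            continue
        if known_sites is not None and (call.locus.contig, call.locus.position) in known_sites:
            continue
        if call.methylation_fraction is None or call.context is None:
            continue
        if call.context not in sums:
            continue
        sums[call.context] += call.methylation_fraction
        counts[call.context] += 1

    out: dict[str, float] = {}
    for key in sums:
        if counts[key] == 0:
            warnings.warn(
                f"no qualifying loci for context {key}; falling back to beta=0.5",
                stacklevel=2,
            )
            out[key] = beta_naive()
        else:
            out[key] = sums[key] / counts[key]
    return out


def beta_locus(
    locus: PileupLocus,
    strand: str = "auto",
) -> float:
    """Locus-specific beta = c/(c+t) from the pileup being genotyped.

    ``strand`` selects which strand's cytosine is being evaluated:
    forward counts C vs T over forward-template reads, reverse counts the
    mirrored G vs A over reverse-template reads.  ``auto`` follows the
    reference base (G means a reverse-strand cytosine).  No informative
    reads -> 0.5, reducing to the naive prior.
    """
    if strand == "auto":
        strand = "reverse" if locus.ref_base.upper() == "G" else "forward"
    if strand in ("+", "forward"):
        c = sum(1 for o in locus.observations
                if o.template_strand == "forward" and o.base == "C")
        t = sum(1 for o in locus.observations
                if o.template_strand == "forward" and o.base == "T")
    else:
        c = sum(1 for o in locus.observations
                if o.template_strand == "reverse" and o.base == "G")
        t = sum(1 for o in locus.observations
                if o.template_strand == "reverse" and o.base == "A")
    if c + t == 0:
        return beta_naive()
    return c / (c + t)


def beta_pair_for_locus(locus: PileupLocus) -> tuple[float, float]:
    """(forward-strand, reverse-strand) locus-specific betas for Eq-5."""
    return beta_locus(locus, "forward"), beta_locus(locus, "reverse")
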