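"""Baseline callers and the sensitivity/FDR evaluation harness.

Baselines: the k-allele count-threshold heterozygote caller, the
reference-cytosine caller of the Berman-style methylation pipeline, and
the Shoemaker quality-weighted Fisher-exact caller.  The harness sweeps a
score threshold per truth stratum (homozygous cytosines; all
heterozygotes; C/T heterozygotes and their G/A mirror; the rest) and
reports sensitivity and FDR, including the operating point at the least
stringent threshold with FDR below a target.

All base bookkeeping is in reference-forward space: a "G-strand read
shows G" rule from read space becomes "reverse-template observation shows
C" once normalized (SAM stores reverse alignments reverse-complemented).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .model import (
    BASES,
    GENOTYPES,
    Genotype,
    GenotypeCall,
    PileupLocus,
    make_genotype,
)

#: heterozygotes whose detection is confounded by bisulfite conversion
CT_LIKE_HETS = {("C", "T"), ("A", "G")}

STRATA = ("hom_cytosine", "het_all", "het_CT", "het_nonCT")


@dataclass
class EvalPoint:
    threshold: float
    true_positives: int
    false_positives: int
    false_negatives: int
    stratum: str

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def fdr(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.false_positives / denom if denom else 0.0


# ---------------------------------------------------------------------------
# k-allele
# ---------------------------------------------------------------------------

def k_allele_call(locus: PileupLocus, K: int) -> str:
    """Count-threshold heterozygote call ('het' / 'hom' / 'no-call').

    At reference-cytosine positions only the genotype-informative strand
    is counted (reverse-template reads at a reference C, forward-template
    at a reference G); elsewhere both strands pool.  With n passing reads:
    n < 10 requires >= K reads of each of the top two alleles; n >= 10
    requires minor-allele reads >= ceil(n K / 10).  Base qualities are
    ignored by design.
    """
    if not (0 <= K <= 10):
        raise ValueError("K must lie in 0..10")
    ref = locus.ref_base.upper()
    if ref == "C":
        obs = [o for o in locus.observations if o.template_strand == "reverse"]
    elif ref == "G":
        obs = [o for o in locus.observations if o.template_strand == "forward"]
    else:
        obs = list(locus.observations)
    counts: dict[str, int] = {}
    for o in obs:
        counts[o.base] = counts.get(o.base, 0) + 1
    n = len(obs)
    if n == 0:
        return "no-call"
    ranked = sorted(counts.values(), reverse=True)
    minor = ranked[1] if len(ranked) > 1 else 0
    if n < 10:
        is_het = ranked[0] >= K and minor >= K
    else:
        is_het = minor >= math.ceil(n * K / 10)
    if is_het:
        return "het"
    return "hom" if minor == 0 else "no-call"


# ---------------------------------------------------------------------------
# Berman-style reference-cytosine caller
# ---------------------------------------------------------------------------

def berman2012_call(locus: PileupLocus, k: float = 10.0) -> str:
    """Homozygous-cytosine call at reference cytosines
    ('cytosine' / 'filtered').

    Requires at least 3 overlapping C-or-T reads on the C-strand, at
    least k% of C-strand reads being C or T, and at least k% of G-strand
    reads agreeing with the cytosine (read-space G, i.e. forward-space C
    for a forward cytosine).  k defaults to 10%, sweepable for ROC.
    """
    ref = locus.ref_base.upper()
    if ref == "C":
        c_strand = [o.base for o in locus.observations if o.template_strand == "forward"]
        g_strand = [o.base for o in locus.observations if o.template_strand == "reverse"]
        ct = {"C", "T"}
        g_ok = "C"
    elif ref == "G":
        c_strand = [o.base for o in locus.observations if o.template_strand == "reverse"]
        g_strand = [o.base for o in locus.observations if o.template_strand == "forward"]
        ct = {"G", "A"}
        g_ok = "G"
    else:
        return "filtered"
    n_ct = sum(1 for b in c_strand if b in ct)
    if n_ct < 3:
        return "filtered"
    frac = k / 100.0
    if c_strand and n_ct / len(c_strand) < frac:
        return "filtered"
    if g_strand and sum(1 for b in g_strand if b == g_ok) / len(g_strand) < frac:
        return "filtered"
    return "cytosine"


# ---------------------------------------------------------------------------
# Shoemaker-style quality-weighted Fisher caller
# ---------------------------------------------------------------------------

def _read_strand_class(seq: str) -> str:
    """Classify a read as bisulfite C-strand or G-strand by its base
    composition (the strand with depleted C reads as C-strand)."""
    nc, nt = seq.count("C"), seq.count("T")
    ng, na = seq.count("G"), seq.count("A")
    ct_ratio = nc / nt if nt else float("inf")
    ga_ratio = ng / na if na else float("inf")
    return "C" if ct_ratio <= ga_ratio else "G"


def shoemaker_call(
    contig: str,
    position: int,
    reads: Sequence,
    reference,
    known_sites,
    min_quality: int = 15,
    flank: int = 3,
    strand_fraction: float = 0.2,
    min_depth: int = 10,
    best_ratio: float = 10.0,
) -> Optional[Genotype]:
    """Genotype at one site per the quality-weighted Fisher-test scheme,
    or None for a no-call.

    Pipeline: classify each read's bisulfite strand from its C:T vs G:A
    composition and demethylate it in silico; keep base calls with
    quality >= 15 at the site and its three flanking read positions;
    require each base seen in > 20% of one strand's reads to be matched
    on >= 20% of the opposing strand; build the quality-weighted
    nucleotide frequency matrix, normalize, and scale to read counts;
    Fisher-test each allele against the error-implied expected counts;
    multiply the two allele p-values per genotype and normalize.  The
    call is reported only when the best genotype is >= 10x the next, the
    site is in the known-variant set, and depth >= 10.
    """
    from .beta import _fetch

    site_bases: list[tuple[str, float, str]] = []  # (base, weight, strand class)
    for read in reads:
        seq = read.query_sequence
        quals = read.query_qualities
        if seq is None or quals is None:
            continue
        pairs = dict((rpos, qpos) for qpos, rpos in read.get_aligned_pairs(matches_only=True))
        qpos = pairs.get(position)
        if qpos is None:
            continue
        lo, hi = max(0, qpos - flank), min(len(seq) - 1, qpos + flank)
        if any(quals[i] < min_quality for i in range(lo, hi + 1)):
            continue
        strand = _read_strand_class(seq)
        base = seq[qpos].upper()
        # in-silico demethylation: collapse the convertible base pair
        if strand == "C" and base == "C":
            base = "T"
        if strand == "G" and base == "G":
            base = "A"
        if base not in BASES:
            continue
        site_bases.append((base, float(quals[qpos]), strand))

    n = len(site_bases)
    if n < min_depth:
        return None
    if known_sites is None or (contig, position) not in known_sites:
        return None

    # reciprocal-strand rule
    for s, other in (("C", "G"), ("G", "C")):
        ours = [b for b, _, st in site_bases if st == s]
        theirs = [b for b, _, st in site_bases if st == other]
        if not ours or not theirs:
            continue
        for base in BASES:
            if ours.count(base) / len(ours) > strand_fraction:
                if theirs.count(base) / len(theirs) < strand_fraction:
                    return None

    # quality-weighted frequency matrix, normalized and scaled to counts
    weights = {b: 0.0 for b in BASES}
    for base, w, _ in site_bases:
        weights[base] += w
    total_w = sum(weights.values())
    if total_w == 0:
        return None
    scaled = {b: n * weights[b] / total_w for b in BASES}

    # each genotype's fit: Fisher test of the observed allele counts
    # against the genotype-implied expectation (each allele sequenced with
    # probability 1/2, residual counts from the error-implied background);
    # the two allele p-values are multiplied and the products normalized
    err = 0.01
    scores = np.empty(len(GENOTYPES))
    for k, (a, b) in enumerate(GENOTYPES):
        score = 1.0
        for allele in (a, b):
            share = 1.0 if a == b else 0.5
            e = n * (share * (1 - err) + err / 3)
            obs_n = int(round(scaled[allele]))
            table = [
                [obs_n, n - obs_n],
                [int(round(e)), n - int(round(e))],
            ]
            score *= fisher_exact(table)[1]
        scores[k] = score
    if scores.sum() == 0:
        return None
    scores = scores / scores.sum()
    order = np.argsort(-scores, kind="stable")
    if scores[order[1]] > 0 and scores[order[0]] / scores[order[1]] < best_ratio:
        return None
    return GENOTYPES[int(order[0])]


# ---------------------------------------------------------------------------
# evaluation harness
# ---------------------------------------------------------------------------

def _truth_in_stratum(g: Genotype, stratum: str) -> bool:
    het = g[0] != g[1]
    if stratum == "hom_cytosine":
        return g in (("C", "C"), ("G", "G"))
    if stratum == "het_all":
        return het
    if stratum == "het_CT":
        return het and g in CT_LIKE_HETS
    if stratum == "het_nonCT":
        return het and g not in CT_LIKE_HETS
    raise ValueError(f"unknown stratum {stratum!r}")


def _predicted_positive(call: GenotypeCall, stratum: str, threshold: float) -> bool:
    if call.filters or call.score < threshold:
        return False
    if stratum == "hom_cytosine":
        return call.best in (("C", "C"), ("G", "G"))
    return call.best[0] != call.best[1]


def evaluate_calls(
    calls: Sequence[GenotypeCall],
    truth_lookup: Callable[[int], Genotype],
    stratum: str,
    thresholds: Optional[Sequence[float]] = None,
    positions: Optional[set[int]] = None,
) -> list[EvalPoint]:
    """Sensitivity/FDR sweep for one truth stratum.

    ``truth_lookup`` maps a 0-based position to the true sample genotype.
    A true positive requires the predicted genotype to match the truth
    exactly; false positives are predicted positives where the truth is
    outside the positive class (counted over all evaluated loci, giving
    het_CT/het_nonCT the same false-positive pool as het_all, which is how
    the stratified sensitivity curves are read).  ``positions``, when
    given, restricts the evaluation universe (used to compare callers over
    an identical locus set, e.g. excluding site-filtered loci that a
    baseline without the filter stack would not see).
    """
    import warnings

    if positions is not None:
        calls = [c for c in calls if c.locus.position in positions]
    truth = [truth_lookup(c.locus.position) for c in calls]
    in_stratum = [(_truth_in_stratum(g, stratum)) for g in truth]
    n_truth = sum(in_stratum)
    if n_truth == 0:
        warnings.warn(f"no truth loci in stratum {stratum!r}", stacklevel=2)
        return []
    positive_class = "hom_cytosine" if stratum == "hom_cytosine" else "het_all"

    # cumulative sweep over the predicted-positive calls sorted by score
    scores, tp_flags, fp_flags = [], [], []
    for call, g, member in zip(calls, truth, in_stratum):
        if not _predicted_positive(call, stratum, 0.0):
            continue
        scores.append(call.score)
        tp_flags.append(member and call.best == g)
        fp_flags.append(not _truth_in_stratum(g, positive_class))
    scores = np.asarray(scores)
    tp_flags = np.asarray(tp_flags, dtype=np.int64)
    fp_flags = np.asarray(fp_flags, dtype=np.int64)
    order = np.argsort(-scores, kind="stable")
    scores, tp_flags, fp_flags = scores[order], tp_flags[order], fp_flags[order]
    cum_tp = np.cumsum(tp_flags)
    cum_fp = np.cumsum(fp_flags)

    if thresholds is None:
        thresholds = np.unique(np.concatenate([[0.0], np.round(scores, 6)]))
    points = []
    for thr in thresholds:
        k = int(np.searchsorted(-scores, -thr, side="right"))  # scores >= thr
        tp = int(cum_tp[k - 1]) if k > 0 else 0
        fp = int(cum_fp[k - 1]) if k > 0 else 0
        points.append(
            EvalPoint(
                threshold=float(thr),
                true_positives=tp,
                false_positives=fp,
                false_negatives=n_truth - tp,
                stratum=stratum,
            )
        )
    return points


def operating_point(
    points: Sequence[EvalPoint], max_fdr: float = 0.05
) -> Optional[EvalPoint]:
    """Least stringent threshold whose FDR is below ``max_fdr``."""
    for pt in sorted(points, key=lambda p: p.threshold):
        if pt.fdr < max_fdr:
            return pt
    return None


def k_allele_eval(
    pileups: Sequence[PileupLocus],
    truth_lookup: Callable[[int], Genotype],
    K_values: Sequence[int] = tuple(range(11)),
    positions: Optional[set[int]] = None,
) -> list[EvalPoint]:
    """Heterozygote sensitivity/FDR of the k-allele baseline per K."""
    if positions is not None:
        pileups = [p for p in pileups if p.position in positions]
    truth = [truth_lookup(p.position) for p in pileups]
    n_truth = sum(1 for g in truth if g[0] != g[1])
    points = []
    for K in K_values:
        tp = fp = 0
        for locus, g in zip(pileups, truth):
            if k_allele_call(locus, K) != "het":
                continue
            if g[0] != g[1]:
                tp += 1
            else:
                fp += 1
        points.append(
            EvalPoint(
                threshold=float(K),
                true_positives=tp,
                false_positives=fp,
                false_negatives=n_truth - tp,
                stratum="het_all",
            )
        )
    return points


def false_positive_rate(point: EvalPoint, n_negative: int) -> float:
    return point.false_positives / n_negative if n_negative else 0.0


def sensitivity_at_fpr(
    points: Sequence[EvalPoint], n_negative: int, fpr: float
) -> float:
    """Best sensitivity among operating points at or below the given
    false-positive rate (the ROC value matched at that FPR)."""
    best = 0.0
    for pt in points:
        if false_positive_rate(pt, n_negative) <= fpr:
            best = max(best, pt.sensitivity)
    return best


def evaluation_table(points: Iterable[EvalPoint]):
    """EvalPoints as a pandas DataFrame (for the compare subcommand)."""
    import pandas as pd

    rows = [
        {
            "stratum": p.stratum,
            "threshold": p.threshold,
            "tp": p.true_positives,
            "fp": p.false_positives,
            "fn": p.false_negatives,
            "sensitivity": p.sensitivity,
            "fdr": p.fdr,
        }
        for p in points
    ]
    return pd.DataFrame(rows)
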