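"""Bayesian diploid genotype and methylation model for directional
bisulfite sequencing.

At every reference position the sample carries one of 10 unordered diploid
genotypes G = {A,B}.  Given the pileup of base observations D = (D_1..D_r)
the posterior is

    Pr(G | D) = pi(G) Pr(D | G) / sum_G' pi(G') Pr(D | G')

with the read likelihood the product over reads of the per-allele mixture
Pr(D_j | AB) = 1/2 Pr(D_j | A) + 1/2 Pr(D_j | B).

For A and T alleles the per-read likelihood is the plain sequencing-error
model: 1 - eps for a matching base, eps/3 otherwise.  Cytosine (and, by
strand symmetry, guanine) alleles are bisulfite-affected on the strand that
carries the C: an unmethylated C is read as T unless under-conversion
(rate alpha) leaves it a C, and a methylated C is read as C unless
over-conversion (rate gamma) turns it into a T.  With beta the prior
probability that a read's template was methylated, the template base is

    C with probability p_C = beta (1 - gamma) + (1 - beta) alpha
    T with probability p_T = beta gamma + (1 - beta)(1 - alpha)

and sequencing error is applied on top of the template base.  Reads from
the opposite strand are unaffected by conversion and use the plain error
model.  All likelihoods are evaluated in reference-forward space, where
reverse-template reads express the bottom-strand C→T conversion as G→A.

The reported call quality is the phred-scaled odds ratio between the best
and second-best genotype, 10 log10(post_best / post_next).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: transition partner of each base (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

Genotype = tuple[str, str]


def make_genotype(a: str, b: str) -> Genotype:
    """Canonical (alphabetically ordered) unordered allele pair."""
    if a not in _BASE_INDEX or b not in _BASE_INDEX:
        raise ValueError(f"invalid alleles: {a}/{b}")
    return (a, b) if a <= b else (b, a)


#: the 10 diploid genotypes in canonical (lexicographic) order
GENOTYPES: tuple[Genotype, ...] = tuple(
    (BASES[i], BASES[j]) for i in range(4) for j in range(i, 4)
)
_GT_INDEX = {g: k for k, g in enumerate(GENOTYPES)}

Strand = Literal["forward", "reverse"]


@dataclass(frozen=True)
class ModelParams:
    """Tunable parameters of the observation model.

    alpha   under-conversion rate: P(unmethylated C stays C).
    gamma   over-conversion rate: P(methylated C reads as T).
    min_base_quality   exclusive phred cutoff for pileup inclusion.
    score_threshold    phred-scaled odds-ratio cutoff for reporting.
    beta_mode          how the methylation prior beta is obtained.
    """

    alpha: float = 0.0025
    gamma: float = 0.0
    min_base_quality: int = 5
    score_threshold: float = 20.0
    beta_mode: str = "locus"

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("alpha and gamma must lie in [0, 1]")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


@dataclass(frozen=True)
class PriorParams:
    """Genotype prior allocation.

    The reference homozygote receives 1 - theta (theta_known at sites
    present in the known-variant set, theta_novel elsewhere); the variant
    mass theta is spread over the nine remaining genotypes, weighting
    transition alleles by titv_ratio and reference-containing heterozygotes
    by het_vs_homalt_weight relative to non-reference homozygotes.
    Heterozygotes carrying two novel alleles require two mutation events
    and carry an extra factor of theta.
    """

    theta_novel: float = 1e-3
    theta_known: float = 0.1
    titv_ratio: float = 2.0
    het_vs_homalt_weight: float = 2.0

    def __post_init__(self) -> None:
        for name in ("theta_novel", "theta_known", "titv_ratio", "het_vs_homalt_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ReadObservation:
    """One aligned base call, orientation-normalized to the reference
    forward strand.

    ``template_strand`` is the strand of the original bisulfite-converted
    template molecule; it decides whether the read is bisulfite-affected at
    C (forward template) or G (reverse template) alleles.  ``epsilon`` is
    the base-call error probability implied by the (possibly recalibrated)
    phred quality.
    """

    base: str
    epsilon: float
    template_strand: Strand = "forward"
    cycle: int = 1
    mapping_quality: int = 60
    mate_end: int = 1
    duplicate_flag: bool = False
    properly_paired: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")


@dataclass
class PileupLocus:
    """All passing observations covering one reference position."""

    contig: str
    position: int  # 0-based
    ref_base: str
    observations: list[ReadObservation] = field(default_factory=list)
    # raw-depth metadata used by the MQ0-region filter (counted before
    # read prefilters drop low-MAPQ reads)
    total_reads: int = 0
    mq0_reads: int = 0

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class GenotypeCall:
    """Posterior summary at one locus."""

    locus: PileupLocus
    posterior: dict[Genotype, float]
    best: Genotype
    next_best: Genotype
    score: float
    methylation_fraction: Optional[float] = None
    c_reads: int = 0
    t_reads: int = 0
    filters: set[str] = field(default_factory=set)
    context: Optional[str] = None
    methylation_strand: Optional[str] = None  # '+' or '-'
    sb: Optional[float] = None  # strand-bias annotation (site filters)
    qd: Optional[float] = None  # quality-by-depth annotation

    @property
    def passes(self) -> bool:
        return not self.filters

    @property
    def is_variant(self) -> bool:
        ref = self.locus.ref_base
        return self.best != (ref, ref)


def phred_to_prob(q: float) -> float:
    """Error probability implied by a phred score."""
    return float(10.0 ** (-q / 10.0))


def prob_to_phred(p: float) -> float:
    return float(-10.0 * math.log10(p))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def genotype_priors(
    ref_base: str,
    known_site=None,
    p: PriorParams | None = None,
) -> dict[Genotype, float]:
    """Prior over the 10 diploid genotypes given the reference base.

    ``known_site``, when given, marks the site as present in the
    known-variant set; if it exposes ``alt_frequencies`` (mapping allele ->
    population frequency) the listed variant alleles absorb the variant
    mass proportionally (mixed 95:5 with the transition/transversion
    weights so unlisted alleles keep non-zero prior support).
    """
    p = p or PriorParams()
    ref_base = ref_base.upper()
    if ref_base not in _BASE_INDEX:
        # unresolvable reference: uninformative prior
        return {g: 1.0 / len(GENOTYPES) for g in GENOTYPES}

    theta = p.theta_novel if known_site is None else p.theta_known

    af: dict[str, float] = {}
    if known_site is not None:
        raw = getattr(known_site, "alt_frequencies", None) or {}
        af = {a: f for a, f in raw.items() if a in _BASE_INDEX and f > 0}

    def allele_weight(x: str) -> float:
        titv = p.titv_ratio if TRANSITION[ref_base] == x else 1.0
        if af:
            total = sum(af.values())
            freq = af.get(x, 0.0) / total if total > 0 else 0.0
            titv_norm = titv / (p.titv_ratio + 2.0)
            return 0.95 * freq + 0.05 * titv_norm
        return titv

    weights: dict[Genotype, float] = {}
    for g in GENOTYPES:
        a, b = g
        if g == (ref_base, ref_base):
            continue
        if ref_base in g:  # reference-containing heterozygote
            x = b if a == ref_base else a
            weights[g] = p.het_vs_homalt_weight * allele_weight(x)
        elif a == b:  # non-reference homozygote
            weights[g] = allele_weight(a)
        else:  # heterozygote of two non-reference alleles: two events
            weights[g] = theta * allele_weight(a) * allele_weight(b)

    wsum = sum(weights.values())
    priors = {g: theta * w / wsum for g, w in weights.items()}
    priors[(ref_base, ref_base)] = 1.0 - theta
    return priors


# ---------------------------------------------------------------------------
# observation likelihood
# ---------------------------------------------------------------------------

def _beta_pair(beta) -> tuple[float, float]:
    """Split a beta argument into (forward-strand C, reverse-strand C)."""
    if isinstance(beta, (tuple, list)):
        bc, bg = float(beta[0]), float(beta[1])
    else:
        bc = bg = float(beta)
    for b in (bc, bg):
        if not (0.0 <= b <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
    return bc, bg


def allele_observation_likelihood(
    obs: ReadObservation,
    allele: str,
    beta,
    params: ModelParams | None = None,
) -> float:
    """P(observed base | underlying allele) for one read.

    ``beta`` is the methylation prior for the cytosine being evaluated: a
    single probability, or a pair (forward-strand C, reverse-strand C)
    when the two strands carry different priors.
    """
    params = params or ModelParams()
    allele = allele.upper()
    if allele not in _BASE_INDEX:
        raise ValueError(f"invalid allele {allele!r}")
    base = obs.base.upper()
    if base not in _BASE_INDEX:
        raise ValueError("observations with base N must be excluded by the caller")
    eps = obs.epsilon
    beta_c, beta_g = _beta_pair(beta)

    if allele in ("A", "T"):
        return 1.0 - eps if base == allele else eps / 3.0

    alpha, gamma = params.alpha, params.gamma

    if allele == "C":
        if obs.template_strand == "forward":
            p_c = beta_c * (1.0 - gamma) + (1.0 - beta_c) * alpha
            p_t = 1.0 - p_c
            if base == "C":
                return p_c * (1.0 - eps) + p_t * eps / 3.0
            if base == "T":
                return p_t * (1.0 - eps) + p_c * eps / 3.0
            return eps / 3.0
        return 1.0 - eps if base == "C" else eps / 3.0

    # allele == "G": mirror image — reverse-template reads are bisulfite
    # affected, conversion appearing as G->A in forward-normalized space.
    if obs.template_strand == "reverse":
        p_g = beta_g * (1.0 - gamma) + (1.0 - beta_g) * alpha
        p_a = 1.0 - p_g
        if base == "G":
            return p_g * (1.0 - eps) + p_a * eps / 3.0
        if base == "A":
            return p_a * (1.0 - eps) + p_g * eps / 3.0
        return eps / 3.0
    return 1.0 - eps if base == "G" else eps / 3.0


def _allele_likelihood_matrix(
    bases: np.ndarray,
    eps: np.ndarray,
    fwd_template: np.ndarray,
    beta,
    params: ModelParams,
) -> np.ndarray:
    """Vectorized P(obs | allele): shape (4 alleles, r observations).

    Must agree bit-for-bit with allele_observation_likelihood; this is the
    shared-work fast path (each allele column is computed once and reused
    by every genotype containing it).
    """
    beta_c, beta_g = _beta_pair(beta)
    alpha, gamma = params.alpha, params.gamma
    r = len(bases)
    out = np.empty((4, r), dtype=np.float64)
    err = eps / 3.0
    hit = 1.0 - eps

    for ai, allele in enumerate(BASES):
        if allele in ("A", "T"):
            out[ai] = np.where(bases == ai, hit, err)
        elif allele == "C":
            p_c = beta_c * (1.0 - gamma) + (1.0 - beta_c) * alpha
            p_t = 1.0 - p_c
            bis = np.where(
                bases == _BASE_INDEX["C"],
                p_c * hit + p_t * err,
                np.where(bases == _BASE_INDEX["T"], p_t * hit + p_c * err, err),
            )
            plain = np.where(bases == _BASE_INDEX["C"], hit, err)
            out[ai] = np.where(fwd_template, bis, plain)
        else:  # G
            p_g = beta_g * (1.0 - gamma) + (1.0 - beta_g) * alpha
            p_a = 1.0 - p_g
            bis = np.where(
                bases == _BASE_INDEX["G"],
                p_g * hit + p_a * err,
                np.where(bases == _BASE_INDEX["A"], p_a * hit + p_g * err, err),
            )
            plain = np.where(bases == _BASE_INDEX["G"], hit, err)
            out[ai] = np.where(~fwd_template, bis, plain)
    return out


def _observation_arrays(
    observations: Sequence[ReadObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bases = np.array([_BASE_INDEX[o.base] for o in observations], dtype=np.int8)
    eps = np.array([o.epsilon for o in observations], dtype=np.float64)
    fwd = np.array(
        [o.template_strand == "forward" for o in observations], dtype=bool
    )
    return bases, eps, fwd


def genotype_likelihood(
    locus: PileupLocus,
    g: Genotype,
    beta,
    params: ModelParams | None = None,
    log: bool = True,
) -> float:
    """log Pr(D | G) = sum_j log [ 1/2 P(D_j|A) + 1/2 P(D_j|B) ].

    An empty pileup yields the empty product (log-likelihood 0).
    """
    params = params or ModelParams()
    if not locus.observations:
        return 0.0 if log else 1.0
    bases, eps, fwd = _observation_arrays(locus.observations)
    mat = _allele_likelihood_matrix(bases, eps, fwd, beta, params)
    a, b = make_genotype(*g)
    per_read = 0.5 * mat[_BASE_INDEX[a]] + 0.5 * mat[_BASE_INDEX[b]]
    ll = float(np.sum(np.log(per_read)))
    return ll if log else math.exp(ll)


def _log_likelihoods_all(
    locus: PileupLocus, beta, params: ModelParams
) -> np.ndarray:
    """Log-likelihood of every genotype, sharing per-allele columns."""
    if not locus.observations:
        return np.zeros(len(GENOTYPES))
    bases, eps, fwd = _observation_arrays(locus.observations)
    mat = _allele_likelihood_matrix(bases, eps, fwd, beta, params)
    out = np.empty(len(GENOTYPES))
    for k, (a, b) in enumerate(GENOTYPES):
        per_read = 0.5 * mat[_BASE_INDEX[a]] + 0.5 * mat[_BASE_INDEX[b]]
        out[k] = np.sum(np.log(per_read))
    return out


def locus_posterior(
    locus: PileupLocus,
    priors: Mapping[Genotype, float],
    beta,
    params: ModelParams | None = None,
) -> GenotypeCall:
    """Posterior over the 10 genotypes, best/next-best, and the call score.

    Computed in log space; score = 10 log10(post_best / post_next), 0 on a
    tie, with ties broken by canonical genotype order.
    """
    params = params or ModelParams()
    log_lik = _log_likelihoods_all(locus, beta, params)
    log_prior = np.array(
        [math.log(priors[g]) if priors[g] > 0 else -math.inf for g in GENOTYPES]
    )
    log_post = log_prior + log_lik
    m = np.max(log_post)
    norm = np.exp(log_post - m)
    norm /= norm.sum()
    posterior = {g: float(norm[k]) for k, g in enumerate(GENOTYPES)}

    # stable sort: descending posterior, ties by canonical genotype order
    order = sorted(range(len(GENOTYPES)), key=lambda k: (-log_post[k], k))
    best, nxt = GENOTYPES[order[0]], GENOTYPES[order[1]]
    d = log_post[order[0]] - log_post[order[1]]
    score = 0.0 if d <= 0 else float(10.0 * d / math.log(10.0))

    call = GenotypeCall(
        locus=locus, posterior=posterior, best=best, next_best=nxt, score=score
    )
    frac, c, t, strand = methylation_from_call(call, locus)
    call.methylation_fraction = frac
    call.c_reads = c
    call.t_reads = t
    call.methylation_strand = strand
    return call


#: genotypes whose methylation cannot be measured: the non-cytosine allele's
#: reads are indistinguishable from converted cytosine reads on the
#: informative strand (C/T on the forward strand, its mirror A/G on the
#: reverse strand).
UNMEASURABLE_GENOTYPES = {("C", "T"), ("A", "G")}


def methylation_from_call(
    call: GenotypeCall, locus: PileupLocus
) -> tuple[Optional[float], int, int, Optional[str]]:
    """Methylation summary for the called genotype.

    Returns (fraction, c_reads, t_reads, strand).  The fraction is
    c/(c+t) over C-strand observations (forward-template reads for a C
    allele; the G/A mirror over reverse-template reads for a G allele);
    None when the genotype carries no measurable cytosine or no informative
    reads cover the site.
    """
    best = call.best
    if "C" in best and best not in UNMEASURABLE_GENOTYPES:
        c = sum(
            1
            for o in locus.observations
            if o.template_strand == "forward" and o.base == "C"
        )
        t = sum(
            1
            for o in locus.observations
            if o.template_strand == "forward" and o.base == "T"
        )
        strand = "+"
    elif "G" in best and best not in UNMEASURABLE_GENOTYPES:
        c = sum(
            1
            for o in locus.observations
            if o.template_strand == "reverse" and o.base == "G"
        )
        t = sum(
            1
            for o in locus.observations
            if o.template_strand == "reverse" and o.base == "A"
        )
        strand = "-"
    else:
        return None, 0, 0, None
    if c + t == 0:
        return None, 0, 0, strand
    return c / (c + t), c, t, strand
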