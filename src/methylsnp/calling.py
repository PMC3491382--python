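"""Per-locus calling pipeline: priors, beta selection, posterior,
methylation summary, context annotation, and site filters.

The context beta mode runs the two-round procedure: a first round with
the naive beta (0.5) selects high-confidence non-SNP homozygous
cytosines, per-context means are estimated from them, and the second
round calls with those means.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from . import beta as beta_mod
from .beta import ContextPattern, beta_naive, beta_pair_for_locus, match_context
from .filters import FilterThresholds, site_filters
from .model import (
    GenotypeCall,
    ModelParams,
    PileupLocus,
    PriorParams,
    genotype_priors,
    locus_posterior,
)

DEFAULT_CONTEXTS = (ContextPattern("CG"), ContextPattern("CH"))


def _context_for(
    reference, locus: PileupLocus, patterns: Sequence[ContextPattern]
) -> Optional[str]:
    """Context label of the locus's cytosine strand (reference-based)."""
    ref = locus.ref_base.upper()
    if ref == "C":
        strand = "forward"
    elif ref == "G":
        strand = "reverse"
    else:
        return None
    pat = match_context(reference, locus.contig, locus.position, strand, patterns)
    return str(pat) if pat is not None else None


def _beta_for_locus(
    locus: PileupLocus,
    mode: str,
    reference,
    patterns: Sequence[ContextPattern],
    context_betas: Optional[dict[str, float]],
):
    """(forward, reverse) methylation prior for Eq-5 at this locus."""
    if mode == "naive":
        b = beta_naive()
        return (b, b)
    if mode == "locus":
        return beta_pair_for_locus(locus)
    if mode == "context":
        out = []
        for strand in ("forward", "reverse"):
            pat = match_context(
                reference, locus.contig, locus.position, strand, patterns,
                require_center_c=False,
            )
            betas = context_betas or {}
            out.append(betas.get(str(pat), beta_naive()) if pat else beta_naive())
        return tuple(out)
    raise ValueError(f"unknown beta mode {mode!r}")


def call_pileups(
    pileups: Iterable[PileupLocus],
    reference,
    known_sites=None,
    params: ModelParams | None = None,
    prior_params: PriorParams | None = None,
    thresholds: FilterThresholds | None = None,
    contexts: Sequence[ContextPattern] = DEFAULT_CONTEXTS,
    beta_mode: Optional[str] = None,
    context_betas: Optional[dict[str, float]] = None,
    apply_site_filters: bool = True,
) -> list[GenotypeCall]:
    """Genotype every pileup locus and annotate it.

    ``beta_mode`` defaults to params.beta_mode; 'context' mode expects
    ``context_betas`` (see two_round_call for the full procedure).
    """
    params = params or ModelParams()
    prior_params = prior_params or PriorParams()
    thresholds = thresholds or FilterThresholds()
    mode = beta_mode or params.beta_mode
    contexts = list(contexts)

    calls: list[GenotypeCall] = []
    for locus in pileups:
        known = (
            known_sites.get(locus.contig, locus.position)
            if known_sites is not None
            else None
        )
        priors = genotype_priors(locus.ref_base, known, prior_params)
        beta = _beta_for_locus(locus, mode, reference, contexts, context_betas)
        call = locus_posterior(locus, priors, beta, params)
        call.context = _context_for(reference, locus, contexts)
        calls.append(call)

    if apply_site_filters:
        site_filters(calls, t=thresholds)
    return calls


def two_round_call(
    pileups: Sequence[PileupLocus],
    reference,
    known_sites=None,
    params: ModelParams | None = None,
    prior_params: PriorParams | None = None,
    thresholds: FilterThresholds | None = None,
    contexts: Sequence[ContextPattern] = DEFAULT_CONTEXTS,
) -> tuple[list[GenotypeCall], dict[str, float]]:
    """Context beta mode: naive round 1, per-context estimation, round 2.

    Returns (second-round calls, per-context beta estimates).
    """
    pileups = list(pileups)
    round1 = call_pileups(
        pileups, reference, known_sites, params, prior_params, thresholds,
        contexts, beta_mode="naive", apply_site_filters=False,
    )
    context_betas = beta_mod.beta_context(round1, known_sites, contexts)
    round2 = call_pileups(
        pileups, reference, known_sites, params, prior_params, thresholds,
        contexts, beta_mode="context", context_betas=context_betas,
    )
    return round2, context_betas
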