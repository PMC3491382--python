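"""Shared fixtures: tiny hand-built pileups and a medium simulated
dataset reused across test modules (session-scoped so the simulation and
calling cost is paid once)."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from methylsnp import (
    ModelParams,
    PileupLocus,
    ReadObservation,
    SimParams,
    call_pileups,
    pileup_iterator,
    simulate_truth_set,
)


def make_obs(base, eps=0.001, strand="forward", **kw):
    return ReadObservation(base=base, epsilon=eps, template_strand=strand, **kw)


def make_locus(ref, bases_fwd=(), bases_rev=(), eps=0.001, contig="chr1", pos=100):
    obs = [make_obs(b, eps, "forward") for b in bases_fwd]
    obs += [make_obs(b, eps, "reverse") for b in bases_rev]
    return PileupLocus(contig=contig, position=pos, ref_base=ref, observations=obs)


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def locus_factory():
    return make_locus


@pytest.fixture(scope="session")
def sim_truth():
    """30x / 75 bp / Q30 directional simulation over 40 kb (seeded)."""
    p = SimParams(genome_length=40_000, coverage=30.0, seed=101)
    return simulate_truth_set(p)


@pytest.fixture(scope="session")
def sim_files(sim_truth, tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    fa = str(d / "reference.fa")
    sam = str(d / "reads.sam")
    vcf = str(d / "truth.vcf")
    tsv = str(d / "truth_methylation.tsv")
    sim_truth.write_fasta(fa)
    sim_truth.write_sam(sam)
    sim_truth.write_truth_vcf(vcf)
    sim_truth.write_methylation_tsv(tsv)
    return {"fasta": fa, "sam": sam, "vcf": vcf, "methylation": tsv}


@pytest.fixture(scope="session")
def sim_genome(sim_files):
    import pyfaidx

    return pyfaidx.Fasta(sim_files["fasta"])


@pytest.fixture(scope="session")
def sim_pileups(sim_files, sim_genome):
    with pysam.AlignmentFile(sim_files["sam"]) as af:
        return list(pileup_iterator(af, sim_genome))


@pytest.fixture(scope="session")
def sim_calls(sim_pileups, sim_genome):
    return call_pileups(sim_pileups, sim_genome)
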