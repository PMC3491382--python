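"""Tests of the synthetic-data generator: determinism, statistical
calibration of the generated data, provenance replay, and Eq-7-style
per-locus downsampling."""

from __future__ import annotations

import math

import numpy as np
import pysam
import pytest

from methylsnp import (
    PileupLocus,
    ReadObservation,
    SimParams,
    assign_methylation,
    downsample_pileup,
    simulate_genome,
    simulate_reads,
    simulate_truth_set,
)
from methylsnp.simulator import rebuild_read

from conftest import make_locus


class TestSimulateGenome:
    def test_zero_snp_rate_identity(self):
        p = SimParams(genome_length=5000, snp_rate=0.0, seed=3)
        ref, haps, variants = simulate_genome(p)
        assert haps == (ref, ref)
        assert variants == []

    def test_expected_snp_count_binomial(self):
        p = SimParams(genome_length=50_000, snp_rate=1e-3, seed=4)
        _, _, variants = simulate_genome(p)
        n = p.genome_length * p.snp_rate
        assert abs(len(variants) - n) <= 3 * math.sqrt(n) + 1

    def test_same_seed_identical(self):
        p = SimParams(genome_length=3000, seed=5)
        a = simulate_genome(p)
        b = simulate_genome(p)
        assert a[0] == b[0] and a[1] == b[1]
        assert [(v.position, v.hap_alleles) for v in a[2]] == [
            (v.position, v.hap_alleles) for v in b[2]
        ]

    def test_gc_content_near_target(self):
        p = SimParams(genome_length=50_000, seed=6)
        ref, _, _ = simulate_genome(p)
        gc = (ref.count("G") + ref.count("C")) / len(ref)
        assert gc == pytest.approx(0.41, abs=0.02)

    def test_het_fraction(self):
        p = SimParams(genome_length=200_000, snp_rate=2e-3, seed=7)
        _, _, variants = simulate_genome(p)
        het = sum(1 for v in variants if v.hap_alleles[0] != v.hap_alleles[1])
        frac = het / len(variants)
        se = math.sqrt(0.67 * 0.33 / len(variants))
        assert abs(frac - 0.67) < 4 * se


class TestAssignMethylation:
    def test_ch_mean_near_target(self):
        p = SimParams(genome_length=50_000, cpg_enrichment=0.0, seed=8)
        ref, haps, _ = simulate_genome(p)
        table = assign_methylation(haps, p)
        ch = [b for (pos, s), (b, ctx) in table.items() if ctx == "CH"]
        assert np.mean(ch) == pytest.approx(0.01, abs=0.005)

    def test_degenerate_cg_mixture(self):
        p = SimParams(
            genome_length=20_000, cg_high_weight=1.0, cg_high=(1e6, 1e-3), seed=9
        )
        _, haps, _ = simulate_genome(p)
        table = assign_methylation(haps, p)
        cg = [b for (pos, s), (b, ctx) in table.items() if ctx == "CG"]
        assert min(cg) > 0.999

    def test_cpg_dyad_shares_beta(self):
        p = SimParams(genome_length=20_000, seed=10)
        _, haps, _ = simulate_genome(p)
        table = assign_methylation(haps, p)
        hap = haps[0]
        shared = 0
        for i in range(len(hap) - 1):
            if hap[i] == "C" and hap[i + 1] == "G":
                b1 = table.get((i, "+"))
                b2 = table.get((i + 1, "-"))
                if b1 and b2:
                    assert b1[0] == b2[0]
                    shared += 1
        assert shared > 50

    def test_same_seed_identical(self):
        p = SimParams(genome_length=5000, seed=11)
        _, haps, _ = simulate_genome(p)
        assert assign_methylation(haps, p) == assign_methylation(haps, p)


class TestSimulateReads:
    def test_all_converted_when_unmethylated(self):
        p = SimParams(
            genome_length=4000, coverage=10, alpha=0.0, gamma=0.0,
            cg_high_weight=1.0, cg_high=(1e-3, 1e6), beta_ch=0.0,
            true_quality=93.0, seed=12,
        )
        ref, haps, _ = simulate_genome(p)
        meth = assign_methylation(haps, p)
        reads = simulate_reads(haps, meth, p)
        for rec in reads[:200]:
            hap = haps[rec.haplotype]
            window = hap[rec.start : rec.start + rec.length]
            if rec.template == "+":
                assert "C" not in rec.seq or all(
                    window[i] != "C" for i, b in enumerate(rec.seq) if b == "C"
                )
            else:
                assert all(
                    window[i] != "G" for i, b in enumerate(rec.seq) if b == "G"
                )

    def test_fully_methylated_protected(self):
        p = SimParams(
            genome_length=4000, coverage=10, gamma=0.0,
            cg_high_weight=1.0, cg_high=(1e6, 1e-3), beta_ch=1.0,
            true_quality=93.0, seed=13,
        )
        _, haps, _ = simulate_genome(p)
        meth = assign_methylation(haps, p)
        reads = simulate_reads(haps, meth, p)
        for rec in reads[:200]:
            hap = haps[rec.haplotype]
            window = hap[rec.start : rec.start + rec.length]
            assert rec.seq == window  # nothing converted, no errors

    def test_conversion_accounting_alpha(self):
        """With beta = 0 everywhere, the fraction of template-strand Cs
        still read as C equals the under-conversion rate alpha."""
        p = SimParams(
            genome_length=20_000, coverage=10, alpha=0.02, gamma=0.0,
            cg_high_weight=1.0, cg_high=(1e-3, 1e6), beta_ch=0.0,
            true_quality=93.0, seed=14,
        )
        _, haps, _ = simulate_genome(p)
        meth = assign_methylation(haps, p)
        reads = simulate_reads(haps, meth, p)
        n_c = n_tot = 0
        for rec in reads:
            hap = haps[rec.haplotype]
            window = hap[rec.start : rec.start + rec.length]
            target = "C" if rec.template == "+" else "G"
            for i, b in enumerate(window):
                if b == target:
                    n_tot += 1
                    n_c += rec.seq[i] == target
        se = math.sqrt(0.02 * 0.98 / n_tot)
        assert abs(n_c / n_tot - 0.02) < 3 * se

    def test_mean_depth_near_target(self, sim_truth, sim_pileups):
        depths = [l.depth for l in sim_pileups]
        target = sim_truth.params.coverage
        assert abs(np.mean(depths) - target) < 3 * math.sqrt(target)

    def test_provenance_replay_reconstructs_reads(self, sim_truth):
        for rec in sim_truth.reads[::97]:
            assert rebuild_read(sim_truth, rec) == rec.seq

    def test_same_seed_byte_identical_sam(self, sim_truth, tmp_path):
        p = sim_truth.params
        t2 = simulate_truth_set(p)
        a, b = str(tmp_path / "a.sam"), str(tmp_path / "b.sam")
        sim_truth.write_sam(a)
        t2.write_sam(b)
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_zero_coverage_rejected(self):
        p = SimParams(genome_length=1000, coverage=0.0, seed=1)
        ref, haps, _ = simulate_genome(p)
        meth = assign_methylation(haps, p)
        with pytest.raises(ValueError):
            simulate_reads(haps, meth, p)


class TestPairedEnd:
    def test_mates_share_template_and_flags(self):
        p = SimParams(genome_length=6000, coverage=6, paired=True, seed=15)
        truth = simulate_truth_set(p)
        by_name = {}
        for r in truth.reads:
            by_name.setdefault(r.name, []).append(r)
        assert all(len(v) == 2 for v in by_name.values())
        for m1, m2 in by_name.values():
            assert m1.template == m2.template
            assert m1.is_reverse != m2.is_reverse
            assert {m1.mate_end, m2.mate_end} == {1, 2}

    def test_sam_parses_with_pysam(self, tmp_path):
        p = SimParams(genome_length=6000, coverage=6, paired=True, seed=16)
        truth = simulate_truth_set(p)
        sam = str(tmp_path / "pe.sam")
        truth.write_sam(sam)
        with pysam.AlignmentFile(sam) as af:
            reads = list(af)
        assert all(r.is_paired and r.is_proper_pair for r in reads)
        r2 = [r for r in reads if r.is_read2]
        assert r2 and all(r.mate_is_reverse != r.is_reverse for r in r2)


class TestDownsamplePileup:
    def _locus(self, m):
        return make_locus("A", bases_fwd="A" * m)

    def test_eq7_arithmetic(self):
        locus = self._locus(40)
        out = downsample_pileup(locus, n=8, N=32, seed=1)
        assert out.depth == 10  # z = round(40 * 8 / 32)

    def test_target_equals_dataset_unchanged(self):
        locus = self._locus(25)
        out = downsample_pileup(locus, n=32, N=32, seed=1)
        assert out is locus

    def test_cannot_exceed_available(self):
        locus = self._locus(3)
        out = downsample_pileup(locus, n=30, N=32, seed=1)
        assert out.depth == 3

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            downsample_pileup(self._locus(5), n=40, N=32)

    def test_subset_of_original_observations(self):
        locus = make_locus("A", bases_fwd="ACGTACGTAC")
        out = downsample_pileup(locus, n=16, N=32, seed=2)
        assert out.depth == 5
        ids = {id(o) for o in locus.observations}
        assert all(id(o) in ids for o in out.observations)
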