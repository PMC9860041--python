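import math

import numpy as np
import pytest

from podovirome.errors import ParameterError
from podovirome.recruit import (
    KPKGRecord,
    RecruitedRead,
    assign_reads,
    clade_abundance,
    clade_kpkg,
    compute_kpkg,
    depth_contrast,
    filter_hits,
    genome_breadth,
    layer_proportions,
    sample_gate,
)
from podovirome.seqio import GenomeRecord, HitRecord, PipelineConfig, SampleMeta


def _hit(read="r1", genome="gA", identity=99.0, evalue=1e-20, q_start=1, q_end=200,
         bitscore=300.0, s_start=1001, s_end=1200):
    aln = q_end - q_start + 1
    return HitRecord(read, genome, identity, aln, 2, 0, q_start, q_end,
                     s_start, s_end, evalue, bitscore)


CFG = PipelineConfig()


class TestFilterHits:
    LENGTHS = {"r1": 200}

    def test_identity_boundary_inclusive(self):
        kept = filter_hits([_hit(identity=95.0, q_end=190)], self.LENGTHS, CFG)
        assert len(kept) == 1

    def test_coverage_boundary_strict(self):
        # exactly 90% of the read aligned -> dropped
        kept = filter_hits([_hit(q_end=180)], self.LENGTHS, CFG)
        assert kept == []

    def test_identity_below_threshold_dropped(self):
        kept = filter_hits([_hit(identity=94.9, q_end=200)], self.LENGTHS, CFG)
        assert kept == []

    def test_evalue_boundary_strict(self):
        kept = filter_hits([_hit(evalue=1e-5)], self.LENGTHS, CFG)
        assert kept == []

    def test_unknown_read_raises(self):
        with pytest.raises(ParameterError):
            filter_hits([_hit(read="r9")], self.LENGTHS, CFG)


class TestAssignReads:
    def test_highest_bitscore_wins(self):
        hits = [_hit(genome="g1", bitscore=180.0), _hit(genome="g2", bitscore=150.0)]
        (rec,) = assign_reads(hits)
        assert rec.genome_id == "g1"

    def test_exact_tie_broken_lexicographically(self):
        hits = [_hit(genome="gB", bitscore=160.0), _hit(genome="gA", bitscore=160.0)]
        (rec,) = assign_reads(hits)
        assert rec.genome_id == "gA"

    def test_partition_no_double_counting(self):
        hits = [
            _hit(read="r1", genome="g1", bitscore=100.0),
            _hit(read="r1", genome="g2", bitscore=90.0),
            _hit(read="r2", genome="g2", bitscore=80.0),
        ]
        recs = assign_reads(hits)
        assert sorted(r.read_id for r in recs) == ["r1", "r2"]


class TestGenomeBreadth:
    def test_half_tiled_genome(self):
        assert genome_breadth([(0, 20_000)], 40_000) == 0.5

    def test_union_is_idempotent(self):
        once = genome_breadth([(100, 300)], 1000)
        twice = genome_breadth([(100, 300), (100, 300)], 1000)
        assert once == twice == 0.2

    def test_overlapping_intervals_merged(self):
        assert genome_breadth([(0, 150), (100, 250)], 1000) == 0.25

    def test_no_reads_gives_zero(self):
        assert genome_breadth([], 1000) == 0.0

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ParameterError):
            genome_breadth([(900, 1100)], 1000)


class TestComputeKPKG:
    GENOME = GenomeRecord("gA", "A" * 40_000, "MPP-C")
    META = SampleMeta("s1", "SRF", 5.0, 0.5)

    def _assigned(self, n=100, aligned=200):
        return [
            RecruitedRead(f"r{i}", "gA", aligned, 99.0, 300.0, (i * 200, i * 200 + 200))
            for i in range(n)
        ]

    def test_direct_arithmetic(self):
        rec = compute_kpkg(self._assigned(), self.GENOME, self.META, breadth=0.8, cfg=CFG)
        assert rec.kpkg == pytest.approx(1.0)  # 20 kb / (40 kb * 0.5 Gb)
        assert rec.present

    def test_low_breadth_forces_zero(self):
        rec = compute_kpkg(self._assigned(), self.GENOME, self.META, breadth=0.35, cfg=CFG)
        assert rec.kpkg == 0.0
        assert not rec.present

    def test_no_reads_gives_zero(self):
        rec = compute_kpkg([], self.GENOME, self.META, breadth=0.0, cfg=CFG)
        assert rec.recruited_kb == 0.0 and rec.kpkg == 0.0

    def test_doubling_dataset_size_halves_kpkg_exactly(self):
        meta2 = SampleMeta("s1", "SRF", 5.0, 1.0)
        r1 = compute_kpkg(self._assigned(), self.GENOME, self.META, breadth=0.8, cfg=CFG)
        r2 = compute_kpkg(self._assigned(), self.GENOME, meta2, breadth=0.8, cfg=CFG)
        assert r2.kpkg == r1.kpkg / 2


def _kpkg_record(sample, genome, kpkg, breadth=0.9):
    return KPKGRecord(sample, genome, kpkg * 40 * 1.0, 40.0, 1.0, breadth, kpkg > 0, kpkg)


CLADE_MAP = {"gA": "MPP-A", "gB": "MPP-B", "gC": "MPP-C", "gR": "P-RSP2"}


class TestSampleGate:
    def test_all_clades_below_floor_excluded(self):
        recs = [
            _kpkg_record("s1", "gA", 0.0005),
            _kpkg_record("s1", "gB", 0.0002),
            _kpkg_record("s1", "gC", 0.0),
            _kpkg_record("s1", "gR", 0.0),
        ]
        assert sample_gate(recs, CLADE_MAP, CFG) is False

    def test_floor_boundary_inclusive(self):
        recs = [_kpkg_record("s1", "gA", 0.001)]
        assert sample_gate(recs, CLADE_MAP, CFG) is True

    def test_all_zero_excluded_and_gate_idempotent(self):
        recs = [_kpkg_record("s1", "gA", 0.0)]
        assert sample_gate(recs, CLADE_MAP, CFG) is False
        assert sample_gate(recs, CLADE_MAP, CFG) is False


class TestCladeAbundance:
    def test_simple_proportions(self):
        recs = [_kpkg_record("s1", "gA", 3.0), _kpkg_record("s1", "gB", 1.0)]
        out = clade_abundance(recs, CLADE_MAP)
        by_clade = {a.clade: a.proportion for a in out if not math.isnan(a.proportion)}
        assert by_clade["MPP-A"] == 0.75 and by_clade["MPP-B"] == 0.25

    def test_zero_total_sample_yields_nan_proportions(self):
        recs = [_kpkg_record("s1", "gA", 0.0)]
        out = clade_abundance(recs, CLADE_MAP)
        assert all(math.isnan(a.proportion) for a in out)

    def test_excluded_sample_not_reported(self):
        recs = [_kpkg_record("s1", "gA", 3.0), _kpkg_record("s2", "gA", 1.0)]
        out = clade_abundance(recs, CLADE_MAP, included_samples={"s1"})
        assert {a.sample_id for a in out} == {"s1"}

    def test_layer_pooling_sums_before_normalizing(self):
        recs = [
            _kpkg_record("s1", "gA", 3.0),
            _kpkg_record("s1", "gB", 1.0),
            _kpkg_record("s2", "gA", 1.0),
            _kpkg_record("s2", "gB", 3.0),
        ]
        metas = {
            "s1": SampleMeta("s1", "SRF", 5, 1.0),
            "s2": SampleMeta("s2", "SRF", 5, 1.0),
        }
        out = layer_proportions(clade_abundance(recs, CLADE_MAP), metas, method="pooled")
        srf = out[out.layer == "SRF"].set_index("clade")["proportion"]
        assert srf["MPP-A"] == 0.5 and srf["MPP-B"] == 0.5


class TestDepthContrast:
    def _metas(self):
        return {
            "x_srf": SampleMeta("x_srf", "SRF", 5, 1.0, site="x"),
            "x_dcm": SampleMeta("x_dcm", "DCM", 80, 1.0, site="x"),
            "y_srf": SampleMeta("y_srf", "SRF", 5, 1.0, site="y"),
            "y_mix": SampleMeta("y_mix", "MIX", 60, 1.0, site="y"),
            "z_srf": SampleMeta("z_srf", "SRF", 5, 1.0, site="z"),
        }

    def test_log_transform_values(self):
        recs = [
            _kpkg_record("x_srf", "gA", 9.0),
            _kpkg_record("x_dcm", "gA", 0.0),
        ]
        out = depth_contrast(recs, self._metas(), CLADE_MAP)
        assert out.loc[0, "srf_log10_kpkg"] == pytest.approx(1.0)  # log10(9+1)
        assert out.loc[0, "deep_log10_kpkg"] == 0.0  # log10(0+1)

    def test_sites_missing_one_layer_excluded(self):
        recs = [
            _kpkg_record(s, "gA", 1.0)
            for s in ("x_srf", "x_dcm", "y_srf", "y_mix", "z_srf")
        ]
        out = depth_contrast(recs, self._metas(), CLADE_MAP)
        assert sorted(out["site"]) == ["x", "y"]  # z has no deep sample

    def test_empty_input_gives_empty_frame(self):
        out = depth_contrast([], self._metas(), CLADE_MAP)
        assert out.empty


class TestCladeKPKG:
    def test_sums_member_genomes(self):
        recs = [
            _kpkg_record("s1", "gA", 1.0),
            _kpkg_record("s1", "gB", 2.0),
            _kpkg_record("s1", "gC", 0.5),
        ]
        sums = clade_kpkg(recs, CLADE_MAP)
        assert sums == {"MPP-A": 1.0, "MPP-B": 2.0, "MPP-C": 0.5}
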