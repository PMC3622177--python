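import numpy as np
import pytest

from moderseq.io_formats import AlignmentRecord, CandidateRegion, GeneModel
from moderseq.quantify import (GeneReadTally, MultireadGroup,
                               apportion_multireads, expand_gene_regions,
                               first_pass_rpkm, quantify_sample, tally_reads)


def rec(read_id, start, end, cls="unique", hits=("gA",), chrom="chr1"):
    return AlignmentRecord(read_id, chrom, start, end, cls, tuple(hits))


class TestTallyReads:
    def test_read_inside_gene_counts_once(self, two_gene_models):
        tallies, regions, groups = tally_reads([rec("r1", 10, 60)], two_gene_models)
        assert tallies["gA"].unique_reads == 1
        assert tallies["gB"].unique_reads == 0
        assert regions == [] and groups == []

    def test_splice_reads_counted_separately(self, two_gene_models):
        tallies, _, _ = tally_reads([rec("r1", 10, 60, "splice")], two_gene_models)
        assert tallies["gA"].splice_reads == 1 and tallies["gA"].unique_reads == 0

    def test_orphan_reads_cluster_into_regions(self, two_gene_models):
        reads = [rec("r1", 50_000, 50_050, hits=("gA",)),
                 rec("r2", 50_300, 50_350, hits=("gA",)),   # within 500 bp: same cluster
                 rec("r3", 60_000, 60_050, hits=("gA",))]   # far: new cluster
        _, regions, _ = tally_reads(reads, two_gene_models)
        assert regions == [CandidateRegion("chr1", 50_000, 50_350, 2),
                           CandidateRegion("chr1", 60_000, 60_050, 1)]

    def test_multi_record_becomes_group(self, two_gene_models):
        _, _, groups = tally_reads([rec("r1", 10, 60, "multi", ("gA", "gB"))],
                                   two_gene_models)
        assert groups == [MultireadGroup("r1", ("gA", "gB"))]

    def test_ambiguous_unique_read_goes_to_larger_overlap(self):
        models = [GeneModel("gA", "chr1", "+", ((0, 100),)),
                  GeneModel("gB", "chr1", "+", ((80, 200),))]
        tallies, _, _ = tally_reads([rec("r1", 60, 120)], models)  # 40 bp on A, 40...
        # overlap A = 100-60 = 40, overlap B = 120-80 = 40 -> tie -> smaller id
        assert tallies["gA"].unique_reads == 1 and tallies["gB"].unique_reads == 0


class TestRpkmFormulae:
    def test_first_pass_formula(self):
        tallies = {"g": GeneReadTally("g", unique_reads=600, exonic_length=1000,
                                      effective_length=1000)}
        assert first_pass_rpkm(tallies, 1e6)["g"] == pytest.approx(600.0)

    def test_zero_reads_zero_rpkm(self, two_gene_models):
        tallies, _, _ = tally_reads([], two_gene_models)
        assert first_pass_rpkm(tallies, 1e6) == {"gA": 0.0, "gB": 0.0}

    def test_doubling_total_halves_rpkm(self, toy_multiread_setup):
        models, records = toy_multiread_setup
        r1 = quantify_sample(records, models, total_mapped_reads=1e6)["final_rpkm"]
        r2 = quantify_sample(records, models, total_mapped_reads=2e6)["final_rpkm"]
        assert np.allclose(r1.to_numpy(), 2 * r2.to_numpy())


class TestApportionment:
    def test_weights_proportional_to_first_pass(self):
        groups = [MultireadGroup(f"m{i}", ("gA", "gB")) for i in range(200)]
        fp = {"gA": 600.0, "gB": 200.0}
        weighted = apportion_multireads(groups, fp)
        assert weighted[0].weights == pytest.approx((0.75, 0.25))
        total_a = sum(g.weights[0] for g in weighted)
        assert total_a == pytest.approx(150.0)

    def test_single_candidate_gets_full_weight(self):
        (g,) = apportion_multireads([MultireadGroup("m", ("gA",))], {"gA": 0.0})
        assert g.weights == (1.0,)

    def test_all_zero_first_pass_splits_evenly(self):
        (g,) = apportion_multireads([MultireadGroup("m", ("gA", "gB"))],
                                    {"gA": 0.0, "gB": 0.0})
        assert g.weights == (0.5, 0.5)

    def test_weights_sum_to_one_exactly(self):
        fp = {"gA": 0.1, "gB": 0.3, "gC": 0.7}
        (g,) = apportion_multireads([MultireadGroup("m", ("gA", "gB", "gC"))], fp)
        assert sum(g.weights) == 1.0


class TestRegionExpansion:
    def make(self):
        models = [GeneModel("gA", "chr1", "+", ((0, 1000),)),
                  GeneModel("gB", "chr1", "+", ((20_000, 21_000),))]
        tallies, _, _ = tally_reads([], models)
        return models, tallies

    def test_nearby_region_absorbed(self):
        models, tallies = self.make()
        region = CandidateRegion("chr1", 6_000, 6_100, 7)  # 5 kb from gA
        expanded, leftovers = expand_gene_regions(models, [region], tallies)
        assert leftovers == []
        assert tallies["gA"].region_reads == 7
        assert tallies["gA"].effective_length == 1100
        assert expanded[0].exons == ((0, 1000), (6_000, 6_100))

    def test_region_outside_radius_unassigned(self):
        models, tallies = self.make()
        region = CandidateRegion("chr1", 60_000, 60_100, 3)  # > 20 kb from both
        _, leftovers = expand_gene_regions(models, [region], tallies)
        assert leftovers == [region]
        assert tallies["gA"].region_reads == tallies["gB"].region_reads == 0

    def test_region_assigned_to_nearer_gene(self):
        models, tallies = self.make()
        # 8 kb from gA (end 1000), 3 kb from gB (start 20000)
        region = CandidateRegion("chr1", 9_000, 17_000, 5)
        # distances: to gA = 9000-1000 = 8000; to gB = 20000-17000 = 3000
        expand_gene_regions(models, [region], tallies)
        assert tallies["gB"].region_reads == 5 and tallies["gA"].region_reads == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        models, tallies = self.make()
        region = CandidateRegion("chr1", 6_000, 15_000, 2)  # 5 kb from both
        expand_gene_regions(models, [region], tallies)
        assert tallies["gA"].region_reads == 2


class TestTwoPassPipeline:
    def test_toy_final_rpkm_exact(self, toy_multiread_setup):
        models, records = toy_multiread_setup
        df = quantify_sample(records, models, total_mapped_reads=1e6)
        assert df.loc["gA", "final_rpkm"] == pytest.approx(750.0)
        assert df.loc["gB", "final_rpkm"] == pytest.approx(250.0)

    def test_read_mass_conserved(self, toy_multiread_setup):
        models, records = toy_multiread_setup
        df = quantify_sample(records, models, total_mapped_reads=1e6)
        total = (df["unique_reads"] + df["splice_reads"] + df["multiread_weight"]
                 + df["region_reads"]).sum()
        assert total == pytest.approx(len(records), rel=1e-9)

    def test_no_multireads_two_pass_equals_one_pass(self, two_gene_models):
        records = [rec(f"r{i}", 10 + i, 80 + i) for i in range(50)]
        df = quantify_sample(records, two_gene_models, total_mapped_reads=1e6)
        assert (df["final_rpkm"] == df["first_pass_rpkm"]).all()

    def test_adding_reads_never_decreases_final_rpkm(self, two_gene_models):
        base = [rec(f"r{i}", 10 + i, 80 + i) for i in range(20)]
        extra = base + [rec("x1", 200, 260), rec("x2", 300, 360)]
        r_base = quantify_sample(base, two_gene_models, total_mapped_reads=1e6)
        r_more = quantify_sample(extra, two_gene_models, total_mapped_reads=1e6)
        assert (r_more["final_rpkm"] >= r_base["final_rpkm"]).all()

    def test_extra_iterations_preserve_mass(self, toy_multiread_setup):
        models, records = toy_multiread_setup
        df = quantify_sample(records, models, total_mapped_reads=1e6, iterations=5)
        total = (df["unique_reads"] + df["multiread_weight"]).sum()
        assert total == pytest.approx(1000, rel=1e-9)
        # reweighting sharpens toward the better-supported gene
        assert df.loc["gA", "final_rpkm"] > 749.0
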