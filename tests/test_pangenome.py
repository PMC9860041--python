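import numpy as np
import pytest

from podovirome.pangenome import (
    OrthologGroup,
    ProteinRecord,
    accumulation_curves,
    all_vs_all_protein_hits,
    build_groups,
    build_pangenome,
    pan_core_counts,
    pssm_rescue,
    rbh_pairs,
)
from podovirome.errors import ParameterError
from podovirome.seqio import HitRecord
from podovirome.synthetic import (
    CladeSpec,
    GenePoolSpec,
    simulate_clade_genomes,
    simulate_gene_complements,
    true_pan_core,
)


def _hit(q, s, bitscore, evalue=1e-30, aln_length=100):
    return HitRecord(q, s, 90.0, aln_length, 5, 0, 1, aln_length, 1, aln_length,
                     evalue, bitscore)


class TestRBH:
    LENGTHS = {"A1": 100, "A2": 100, "B1": 100}
    GENOMES = {"A1": "A", "A2": "A", "B1": "B"}

    def test_mutual_best_full_length_accepted(self):
        hits = [_hit("A1", "B1", 200.0), _hit("B1", "A1", 200.0)]
        pairs, scores = rbh_pairs(hits, self.LENGTHS, self.GENOMES)
        assert pairs == {("A1", "B1")}
        assert scores[frozenset(("A1", "B1"))] == 200.0

    def test_asymmetric_best_rejected(self):
        # A2's best is B1 but B1's best is A1
        hits = [
            _hit("A2", "B1", 150.0),
            _hit("A1", "B1", 200.0),
            _hit("B1", "A1", 200.0),
            _hit("B1", "A2", 150.0),
        ]
        pairs, _ = rbh_pairs(hits, self.LENGTHS, self.GENOMES)
        assert ("A2", "B1") not in pairs
        assert ("A1", "B1") in pairs

    def test_short_coverage_rejected(self):
        hits = [_hit("A1", "B1", 200.0, aln_length=60), _hit("B1", "A1", 200.0, aln_length=60)]
        pairs, _ = rbh_pairs(hits, self.LENGTHS, self.GENOMES)
        assert pairs == set()

    def test_weak_evalue_rejected(self):
        hits = [_hit("A1", "B1", 20.0, evalue=1e-3), _hit("B1", "A1", 20.0, evalue=1e-3)]
        pairs, _ = rbh_pairs(hits, self.LENGTHS, self.GENOMES)
        assert pairs == set()

    def test_output_symmetric_by_construction(self):
        hits = [_hit("A1", "B1", 200.0), _hit("B1", "A1", 200.0)]
        pairs, _ = rbh_pairs(hits, self.LENGTHS, self.GENOMES)
        assert all(x < y for x, y in pairs)  # stored as sorted tuples


class TestBuildGroups:
    def test_chain_forms_single_group(self):
        genes = [("A", "A1"), ("B", "B1"), ("C", "C1")]
        groups = build_groups({("A1", "B1"), ("B1", "C1")}, genes)
        assert len(groups) == 1
        assert groups[0].gene_ids == {"A1", "B1", "C1"}

    def test_duplicate_genome_member_demoted_by_summed_score(self):
        genes = [("A", "A1"), ("A", "A2"), ("B", "B1")]
        pairs = {("A1", "B1"), ("A2", "B1")}
        scores = {frozenset(("A1", "B1")): 300.0, frozenset(("A2", "B1")): 100.0}
        groups = build_groups(pairs, genes, scores)
        by_size = sorted(groups, key=lambda g: -len(g.members))
        assert by_size[0].gene_ids == {"A1", "B1"}
        assert by_size[1].gene_ids == {"A2"}

    def test_no_pairs_gives_all_singletons(self):
        genes = [("A", "A1"), ("A", "A2"), ("B", "B1")]
        groups = build_groups(set(), genes)
        assert sorted(len(g.members) for g in groups) == [1, 1, 1]
        pan, _ = pan_core_counts(groups, {"A", "B"})
        assert pan == 3

    def test_grouping_is_a_partition(self):
        genes = [("A", "A1"), ("A", "A2"), ("B", "B1"), ("C", "C1")]
        groups = build_groups({("A1", "B1"), ("B1", "C1")}, genes)
        seen = [gene for g in groups for _, gene in g.members]
        assert sorted(seen) == ["A1", "A2", "B1", "C1"]


class TestPSSMRescue:
    def _family_groups(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        members = {("gA", "gA_x"), ("gB", "gB_x"), ("gC", "gC_x")}
        proteins = {"gA_x": base, "gB_x": base, "gC_x": base}
        return [OrthologGroup("OG0001", set(members))], proteins, base

    def test_identical_orphan_joins(self):
        rng = np.random.default_rng(40)
        groups, proteins, base = self._family_groups(rng)
        orphan = ProteinRecord("gD", "gD_x", base)
        proteins["gD_x"] = base
        out = pssm_rescue(groups, [orphan], proteins)
        assert ("gD", "gD_x") in out[0].members

    def test_orphan_with_genome_already_present_not_joined(self):
        rng = np.random.default_rng(41)
        groups, proteins, base = self._family_groups(rng)
        orphan = ProteinRecord("gA", "gA_y", base)
        proteins["gA_y"] = base
        out = pssm_rescue(groups, [orphan], proteins)
        assert ("gA", "gA_y") not in out[0].members

    def test_random_orphans_nearly_always_rejected(self):
        rng = np.random.default_rng(42)
        groups, proteins, _ = self._family_groups(rng)
        joined = 0
        for i in range(100):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
            out = pssm_rescue(
                [OrthologGroup("OG0001", set(groups[0].members))],
                [ProteinRecord("gZ", f"gZ_{i}", seq)],
                {**proteins, f"gZ_{i}": seq},
            )
            if any(("gZ", f"gZ_{i}") in g.members for g in out):
                joined += 1
        assert joined <= 1  # >= 99% rejected


class TestPanCoreCounts:
    def test_single_genome_counts_its_genes(self):
        groups = build_groups(set(), [("A", f"A{i}") for i in range(8)])
        assert pan_core_counts(groups, {"A"}) == (8, 8)

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ParameterError):
            pan_core_counts([], set())

    def test_two_genome_truth_fixture(self):
        genomes = simulate_clade_genomes(
            [CladeSpec("A", 1, 0.0, 0.05), CladeSpec("B", 1, 0.0, 0.1)], 1500, seed=43
        )
        pool = GenePoolSpec(n_core=5, n_clade_specific_per_clade=0, n_strain_specific_mean=3.0)
        proteomes, truth = simulate_gene_complements(genomes, pool, seed=44)
        proteins = [
            ProteinRecord(gid, gene, seq)
            for gid, genes in proteomes.items()
            for gene, seq in genes
        ]
        groups = build_pangenome(proteins)
        ids = {g.genome_id for g in genomes}
        assert pan_core_counts(groups, ids) == true_pan_core(truth)

    def test_core_recovery_on_clade_structured_proteomes(self):
        genomes = simulate_clade_genomes(
            [CladeSpec(c, 3, 0.02, 0.15) for c in ("A", "B", "C")], 2000, seed=45
        )
        pool = GenePoolSpec(n_core=9, n_clade_specific_per_clade=2,
                            n_strain_specific_mean=1.5)
        proteomes, truth = simulate_gene_complements(genomes, pool, seed=46)
        proteins = [
            ProteinRecord(gid, gene, seq)
            for gid, genes in proteomes.items()
            for gene, seq in genes
        ]
        groups = build_pangenome(proteins)
        ids = {g.genome_id for g in genomes}
        pan, core = pan_core_counts(groups, ids)
        true_pan, true_core = true_pan_core(truth)
        assert core == true_core == 9
        assert pan == true_pan
        # partition: every gene in exactly one group
        seen = sorted(gene for g in groups for _, gene in g.members)
        assert seen == sorted(p.gene_id for p in proteins)


class TestAccumulationCurves:
    def test_identical_gene_content_gives_flat_curves(self):
        genes = [(g, f"{g}_f{i}") for g in "ABCD" for i in range(6)]
        pairs = {
            (f"{a}_f{i}", f"{b}_f{i}")
            for i in range(6)
            for a in "ABCD"
            for b in "ABCD"
            if a < b
        }
        groups = build_groups(pairs, genes)
        curve = accumulation_curves(groups, list("ABCD"), n_permutations=20, seed=47)
        assert np.allclose(curve.mean_pan, 6)
        assert np.allclose(curve.mean_core, 6)

    def test_endpoint_equals_full_set_counts_for_every_permutation(self):
        genomes = simulate_clade_genomes(
            [CladeSpec("A", 2, 0.01, 0.1), CladeSpec("B", 2, 0.01, 0.1)], 1500, seed=48
        )
        pool = GenePoolSpec(n_core=4, n_clade_specific_per_clade=1, n_strain_specific_mean=1.0)
        proteomes, _ = simulate_gene_complements(genomes, pool, seed=49)
        proteins = [
            ProteinRecord(gid, gene, seq)
            for gid, genes in proteomes.items()
            for gene, seq in genes
        ]
        groups = build_pangenome(proteins)
        ids = sorted({g.genome_id for g in genomes})
        pan, core = pan_core_counts(groups, set(ids))
        curve = accumulation_curves(groups, ids, n_permutations=50, seed=50)
        assert curve.mean_pan[-1] == pan and curve.sd_pan[-1] == 0.0
        assert curve.mean_core[-1] == core and curve.sd_core[-1] == 0.0

    def test_monotone_means(self, four_clade_genomes):
        pool = GenePoolSpec(n_core=6, n_clade_specific_per_clade=2, n_strain_specific_mean=2.0)
        genomes = four_clade_genomes[:6]
        proteomes, _ = simulate_gene_complements(genomes, pool, seed=51)
        proteins = [
            ProteinRecord(gid, gene, seq)
            for gid, genes in proteomes.items()
            for gene, seq in genes
        ]
        groups = build_pangenome(proteins)
        ids = sorted({g.genome_id for g in genomes})
        curve = accumulation_curves(groups, ids, n_permutations=30, seed=52)
        assert (np.diff(curve.mean_pan) >= -1e-12).all()
        assert (np.diff(curve.mean_core) <= 1e-12).all()

    def test_requires_two_genomes(self):
        with pytest.raises(ParameterError):
            accumulation_curves([], ["A"], 10, 0)


class TestAllVsAll:
    def test_identical_single_gene_genomes_hit_both_directions(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        proteins = [ProteinRecord("A", "A1", seq), ProteinRecord("B", "B1", seq)]
        hits = all_vs_all_protein_hits(proteins)
        assert {(h.query_id, h.subject_id) for h in hits} == {("A1", "B1"), ("B1", "A1")}
        assert all(h.pct_identity == 100.0 for h in hits)

    def test_single_genome_gives_no_hits(self):
        proteins = [ProteinRecord("A", "A1", "MKTAYIAK"), ProteinRecord("A", "A2", "MKTAYIAK")]
        assert all_vs_all_protein_hits(proteins) == []

    def test_empty_proteome_for_one_genome_tolerated(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        proteins = [
            ProteinRecord("A", "A1", seq),
            ProteinRecord("B", "B1", seq),
            ProteinRecord("C", "C1", "W"),  # near-empty proteome
        ]
        hits = all_vs_all_protein_hits(proteins)
        assert {("A1", "B1"), ("B1", "A1")} <= {(h.query_id, h.subject_id) for h in hits}
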