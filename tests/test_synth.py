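"""Synthetic-data generator: determinism and statistical truth recovery."""

import numpy as np
import pytest

from streamline_scan import synth
from streamline_scan.genome_stats import gc_content, intergenic_spacers


class TestGenerateGenome:
    def test_gc_target_hit(self):
        g = synth.generate_genome(100_000, gc=0.63, seed=7)
        assert abs(gc_content(g) - 0.63) < 0.01

    def test_spacer_target_hit(self):
        g = synth.generate_genome(200_000, mean_spacer=15, seed=8)
        med = intergenic_spacers(g).median
        assert 10 <= med <= 20  # geometric(mean 15) has median ~10

    def test_deterministic_under_seed(self):
        a = synth.generate_genome(20_000, seed=5)
        b = synth.generate_genome(20_000, seed=5)
        assert a.sequence == b.sequence
        assert [(f.start, f.end, f.strand) for f in a.features] == \
               [(f.start, f.end, f.strand) for f in b.features]

    def test_genes_carry_proteins_and_layout_is_disjoint(self):
        g = synth.generate_genome(30_000, seed=9)
        assert all(f.protein for f in g.cds)
        ends = [f.end for f in g.cds]
        starts = [f.start for f in g.cds]
        assert all(e <= s for e, s in zip(ends, starts[1:]))

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_genome(500, mean_gene_len=900, seed=1)
        with pytest.raises(ValueError):
            synth.generate_genome(1000, gc=1.5, seed=1)


@pytest.fixture(scope="module")
def lineage_ref():
    return synth.generate_genome(100_000, seed=21)


@pytest.fixture(scope="module")
def member_genomes():
    return (synth.generate_genome(40_000, seed=1, genome_id="m1"),
            synth.generate_genome(40_000, seed=2, genome_id="m2"))


class TestMutateLineage:
    def test_rate_zero_is_identity(self, lineage_ref):
        genome = lineage_ref
        mut, log = synth.mutate_lineage(genome, 0.0, seed=1)
        assert mut.sequence == genome.sequence
        assert len(log) == 0

    def test_hamming_distance_matches_rate_and_log(self, lineage_ref):
        genome = lineage_ref
        mut, log = synth.mutate_lineage(genome, 0.05, seed=2)
        ham = sum(a != b for a, b in zip(genome.sequence, mut.sequence))
        assert ham == len(log)  # every logged substitution changes the base
        assert abs(ham / len(genome) - 0.05) < 0.003

    def test_log_records_actual_changes(self, lineage_ref):
        genome = lineage_ref
        mut, log = synth.mutate_lineage(genome, 0.01, seed=3)
        codes = "ACGT"
        for p, o, n in zip(log.positions[:50], log.old[:50], log.new[:50]):
            assert genome.sequence[p] == codes[o]
            assert mut.sequence[p] == codes[n]


class TestSimulateReads:
    def test_single_member_all_labelled(self, member_genomes):
        g, _ = member_genomes
        spec = synth.CommunitySpec(
            members=[synth.CommunityMember(g, 1.0, divergence=0.0)],
            read_count=1_000, seed=4)
        rs = synth.simulate_reads(spec)
        assert len(rs) == 1_000
        assert all(rs.truth[rid][0] == "m1" for rid, _ in rs.reads)

    def test_abundance_fractions_recovered(self, member_genomes):
        g1, g2 = member_genomes
        spec = synth.CommunitySpec(
            members=[synth.CommunityMember(g1, 0.8, divergence=0.0),
                     synth.CommunityMember(g2, 0.2, divergence=0.0)],
            read_count=100_000, error_rate=0.0, seed=5)
        rs = synth.simulate_reads(spec)
        frac = sum(1 for rid, _ in rs.reads if rs.truth[rid][0] == "m1") / len(rs)
        assert abs(frac - 0.8) < 0.01

    def test_zero_frequency_island_emits_no_reads(self, member_genomes):
        g, _ = member_genomes
        isl = synth.IslandPlan(10_000, 30_000, 0.0)
        spec = synth.CommunitySpec(
            members=[synth.CommunityMember(g, 1.0, divergence=0.0, islands=[isl])],
            read_count=5_000, seed=6)
        rs = synth.simulate_reads(spec)
        for rid, _ in rs.reads:
            _, (s, e), from_island = rs.truth[rid]
            assert not from_island
            assert e <= 10_000 or s >= 30_000

    def test_error_rate_realized(self, member_genomes):
        g, _ = member_genomes
        spec = synth.CommunitySpec(
            members=[synth.CommunityMember(g, 1.0, divergence=0.0)],
            read_count=2_000, error_rate=0.01, n_lineages=0, seed=7)
        rs = synth.simulate_reads(spec)
        from conftest import revcomp
        mismatches = bases = 0
        for rid, seq in rs.reads:
            _, (s, e), _ = rs.truth[rid]
            ref = g.sequence[s:e]
            fwd = sum(a != b for a, b in zip(seq, ref))
            rev = sum(a != b for a, b in zip(revcomp(seq), ref))
            mismatches += min(fwd, rev)
            bases += len(seq)
        assert abs(mismatches / bases - 0.01) < 0.002

    def test_deterministic_under_seed(self, member_genomes):
        g, _ = member_genomes
        spec = lambda: synth.CommunitySpec(
            members=[synth.CommunityMember(g, 1.0)], read_count=200, seed=8)
        assert synth.simulate_reads(spec()).reads == synth.simulate_reads(spec()).reads

    def test_read_longer_than_genome_rejected(self):
        tiny = synth.generate_genome(1_000, mean_gene_len=90, seed=9)
        spec = synth.CommunitySpec(
            members=[synth.CommunityMember(tiny, 1.0)],
            read_length=2_000, read_count=10, seed=1)
        with pytest.raises(ValueError):
            synth.simulate_reads(spec)


class TestGenerateProteome:
    def test_halophile_de_enrichment(self):
        sample = synth.generate_proteome("halophile", 200, seed=1)
        total = sum(len(p) for p in sample.proteins)
        de = sum(p.count("D") + p.count("E") for p in sample.proteins)
        assert de / total >= 0.15

    def test_deterministic_under_seed(self):
        a = synth.generate_proteome("freshwater", 50, seed=2).proteins
        b = synth.generate_proteome("freshwater", 50, seed=2).proteins
        assert a == b

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_proteome("martian", 10, seed=0)
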