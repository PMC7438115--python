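"""Coalescent engine: structural invariants, distributions, conversions."""

import numpy as np
import pytest

import demesim as d
from demesim.engine import NonTerminationError, marginal_tree_count
from demesim.tables import validate_tables
from demesim.validation import two_island_model


def descendants_by_brute_force(tables, node, position):
    """Oracle: samples below `node` at `position`, by downward edge traversal."""
    out = set()
    stack = [node]
    while stack:
        cur = stack.pop()
        if tables.node_is_sample[cur]:
            out.add(cur)
        for k in range(tables.num_edges):
            if (
                tables.edge_parent[k] == cur
                and tables.edge_left[k] <= position < tables.edge_right[k]
            ):
                stack.append(tables.edge_child[k])
    return out


class TestAncestry:
    def test_two_sample_no_recombination_topology(self, constant_model):
        tables = d.simulate_ancestry(
            constant_model, d.SampleSpec.simple([2]), d.Contig(length=100.0), seed=1
        )
        assert tables.num_nodes == 3
        assert tables.node_is_sample == [True, True, False]
        assert tables.num_edges == 2
        validate_tables(tables)

    def test_root_time_is_exponential_with_mean_2N(self, constant_model):
        roots = [
            d.simulate_ancestry(
                constant_model, d.SampleSpec.simple([2]), d.Contig(length=100.0), seed=s
            ).node_time[2]
            for s in range(400)
        ]
        mean = np.mean(roots)
        se = np.std(roots) / np.sqrt(len(roots))
        assert abs(mean - 2000.0) < 3 * se + 1e-9

    def test_determinism_is_byte_identical(self, constant_model, small_contig):
        a = d.simulate_ancestry(constant_model, d.SampleSpec.simple([5]), small_contig, seed=42)
        b = d.simulate_ancestry(constant_model, d.SampleSpec.simple([5]), small_contig, seed=42)
        assert a.node_time == b.node_time
        assert a.edge_left == b.edge_left and a.edge_parent == b.edge_parent

    def test_zero_recombination_yields_single_marginal_tree(self, constant_model):
        tables = d.simulate_ancestry(
            constant_model, d.SampleSpec.simple([6]), d.Contig(length=1e6), seed=2
        )
        assert marginal_tree_count(tables) == 1

    def test_recombination_yields_multiple_trees(self, constant_model):
        contig = d.Contig(length=1e6, recombination_map=d.flat_map(1e6, 1e-8))
        counts = [
            marginal_tree_count(
                d.simulate_ancestry(constant_model, d.SampleSpec.simple([4]), contig, seed=s)
            )
            for s in range(5)
        ]
        assert all(c > 1 for c in counts)

    def test_nonuniform_map_concentrates_breakpoints_in_hot_region(self, constant_model):
        # left half has 100x the rate of the right half
        gmap = d.RecombinationMap(
            np.array([0.0, 1e5, 2e5]), np.array([1e-7, 1e-9]), 2e5
        )
        contig = d.Contig(length=2e5, recombination_map=gmap)
        hot = cold = 0
        for s in range(10):
            t = d.simulate_ancestry(constant_model, d.SampleSpec.simple([4]), contig, seed=s)
            bps = {l for l in t.edge_left if 0 < l < 2e5}
            hot += sum(1 for b in bps if b < 1e5)
            cold += sum(1 for b in bps if b >= 1e5)
        assert hot > 5 * max(cold, 1)

    def test_edge_invariants_hold_across_seeds(self, two_epoch_model):
        contig = d.Contig(length=5e4, recombination_map=d.flat_map(5e4, 1e-8))
        for s in range(20):
            tables = d.simulate_ancestry(two_epoch_model, d.SampleSpec.simple([5]), contig, seed=s)
            validate_tables(tables)

    def test_disconnected_demes_raise_guard_error(self):
        m = two_island_model(1000.0, 0.0)  # no migration, no merge event
        with pytest.raises(NonTerminationError):
            d.simulate_ancestry(m, d.SampleSpec.simple([1, 1]), d.Contig(length=100.0), seed=1)

    def test_ancient_sampling_time_shifts_node_times(self, constant_model):
        samples = d.SampleSpec([(0, 1, 0.0), (0, 1, 500.0)])
        tables = d.simulate_ancestry(constant_model, samples, d.Contig(length=100.0), seed=3)
        assert tables.node_time[1] == 500.0
        assert tables.node_time[2] > 500.0


class TestMutations:
    def test_zero_rate_gives_zero_sites(self, constant_model, small_contig):
        tables = d.simulate_ancestry(constant_model, d.SampleSpec.simple([4]), small_contig, seed=5)
        d.drop_mutations(tables, 0.0, seed=6)
        assert tables.num_sites == 0

    def test_pairwise_diversity_matches_4Nmu(self):
        # E[pi] = 4 N mu per bp for a pair; average over replicate loci
        N, mu, L = 1000.0, 1e-8, 1e4
        model = d.generic_piecewise_constant([N])
        vals = []
        for s in range(300):
            t = d.simulate_ancestry(model, d.SampleSpec.simple([2]), d.Contig(length=L), seed=s)
            d.drop_mutations(t, mu, seed=s + 10_000)
            vals.append(t.num_sites / L)
        mean, se = np.mean(vals), np.std(vals) / np.sqrt(len(vals))
        assert abs(mean - 4 * N * mu) < 3 * se + 1e-9

    def test_deterministic_given_seed(self, simulated_tables, constant_model, small_contig):
        t2 = d.simulate_ancestry(constant_model, d.SampleSpec.simple([6]), small_contig, seed=11)
        d.drop_mutations(t2, 1e-8, seed=12)
        assert t2.site_position == simulated_tables.site_position
        assert t2.mutation_node == simulated_tables.mutation_node


class TestGenotypes:
    def test_matrix_matches_brute_force_descent(self, simulated_tables):
        G, positions = d.genotype_matrix(simulated_tables)
        samples = simulated_tables.samples()
        for s in range(simulated_tables.num_sites):
            expected = descendants_by_brute_force(
                simulated_tables, simulated_tables.mutation_node[s], positions[s]
            )
            carriers = {samples[j] for j in np.flatnonzero(G[s])}
            assert carriers == expected

    def test_leaf_edge_mutation_is_singleton(self, simulated_tables):
        G, _ = d.genotype_matrix(simulated_tables)
        samples = set(simulated_tables.samples())
        for s in range(simulated_tables.num_sites):
            if simulated_tables.mutation_node[s] in samples:
                assert G[s].sum() == 1

    def test_rows_are_polymorphic(self, simulated_tables):
        G, _ = d.genotype_matrix(simulated_tables)
        counts = G.sum(axis=1)
        assert np.all(counts >= 1) and np.all(counts < G.shape[1])


class TestVCF:
    def test_allele_counts_match_genotype_column_sums(self, simulated_tables):
        G, positions = d.genotype_matrix(simulated_tables)
        vcf = d.export_vcf(simulated_tables)
        records = [ln for ln in vcf.splitlines() if not ln.startswith("#")]
        assert len(records) == simulated_tables.num_sites
        for s, rec in enumerate(records):
            fields = rec.split("\t")
            assert int(fields[1]) == positions[s] + 1
            gt_alleles = "".join(fields[9:]).replace("|", "").replace("\t", "")
            assert sum(int(a) for a in gt_alleles) == G[s].sum()
            assert fields[7] == f"AC={G[s].sum()}"

    def test_four_haploids_make_two_diploid_columns(self, constant_model, small_contig):
        t = d.simulate_ancestry(constant_model, d.SampleSpec.simple([4]), small_contig, seed=9)
        d.drop_mutations(t, 1e-8, seed=10)
        header = [ln for ln in d.export_vcf(t).splitlines() if ln.startswith("#CHROM")][0]
        assert header.split("\t")[9:] == ["ind0", "ind1"]

    def test_zero_sites_gives_header_only(self, constant_model):
        t = d.simulate_ancestry(constant_model, d.SampleSpec.simple([4]), d.Contig(length=100.0), seed=1)
        d.drop_mutations(t, 0.0, seed=1)
        assert all(ln.startswith("#") for ln in d.export_vcf(t).splitlines())

    def test_odd_haploid_count_rejected_for_diploids(self, constant_model):
        t = d.simulate_ancestry(constant_model, d.SampleSpec.simple([3]), d.Contig(length=100.0), seed=1)
        with pytest.raises(ValueError, match="ploidy"):
            d.export_vcf(t)


class TestPairwiseTmrca:
    def test_constant_N_mean_within_3_se(self):
        N = 5000.0
        tm = d.pairwise_tmrca_replicates(d.generic_piecewise_constant([N]), 0, 0, 20000, seed=8)
        se = tm.std() / np.sqrt(len(tm))
        assert abs(tm.mean() - 2 * N) < 3 * se

    def test_clean_split_pair_never_coalesces_before_divergence(self):
        m = d.generic_im(7300, 10000, 10000, 4000, 0.0, 0.0)
        tm = d.pairwise_tmrca_replicates(m, 0, 1, 2000, seed=9)
        assert tm.min() >= 4000.0

    def test_mean_tmrca_invariant_to_recombination(self, constant_model):
        """Each locus marginally follows the same coalescent, so the root time
        at a fixed position has the same mean with and without recombination."""
        contig_r = d.Contig(length=2e4, recombination_map=d.flat_map(2e4, 1e-8))
        contig_0 = d.Contig(length=2e4)

        def root_time_at_zero(tables):
            samples = set(tables.samples())
            t = 0.0
            for k in range(tables.num_edges):
                if tables.edge_left[k] == 0.0:
                    t = max(t, tables.node_time[tables.edge_parent[k]])
            return t

        a = [
            root_time_at_zero(
                d.simulate_ancestry(constant_model, d.SampleSpec.simple([2]), contig_r, seed=s)
            )
            for s in range(600)
        ]
        b = [
            root_time_at_zero(
                d.simulate_ancestry(constant_model, d.SampleSpec.simple([2]), contig_0, seed=10_000 + s)
            )
            for s in range(600)
        ]
        se = np.sqrt(np.var(a) / len(a) + np.var(b) / len(b))
        assert abs(np.mean(a) - np.mean(b)) < 3 * se
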