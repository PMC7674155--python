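"""Synthetic community generator: determinism, planted structure, depth."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from pmocphage.align import percent_identity
from pmocphage.profiles import scaffold_coverage
from pmocphage.references import CATALYTIC_SITES
from pmocphage.synthetic import (
    PMOC_PRODUCT,
    CommunityConfig,
    _diverge,
    simulate_community,
    simulate_depth,
    simulate_snp_table,
    simulate_transcriptome,
)


class TestConfigValidation:
    def test_bad_probability_names_field(self):
        with pytest.raises(ValueError, match="fragmentation_prob"):
            CommunityConfig(fragmentation_prob=1.5).validate()

    def test_bad_length_range(self):
        with pytest.raises(ValueError, match="genome_length_range"):
            CommunityConfig(genome_length_range=(0, 10)).validate()

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="read_identity_mix"):
            CommunityConfig(read_identity_mix=((0.99, 0.5),)).validate()

    def test_coupling_range(self):
        with pytest.raises(ValueError, match="coupling"):
            CommunityConfig(coupling=1.5).validate()


class TestCommunity:
    def test_identical_seed_identical_output(self, fast_config):
        config = replace(fast_config, seed=5)
        genomes_a, truth_a = simulate_community(config)
        genomes_b, truth_b = simulate_community(replace(fast_config, seed=5))
        assert [g.sequences for g in genomes_a] == [g.sequences for g in genomes_b]
        assert truth_a.true_host_of == truth_b.true_host_of
        assert truth_a.true_abundances.equals(truth_b.true_abundances)

    def test_zero_divergence_copies_host_pmoc_exactly(self, fast_config):
        config = replace(
            fast_config, pmoc_terminal_divergence=0.0, pmoc_core_divergence=0.0
        )
        genomes, truth = simulate_community(config)
        by_id = {g.genome_id: g for g in genomes}
        for phage_id, host_id in truth.true_host_of.items():
            phage_pmoc = "".join(
                g.protein
                for g in by_id[phage_id].genes
                if g.gene_id in truth.pmoc_genes[phage_id]
            )
            assert phage_pmoc == truth.host_pmoc[host_id]
            assert percent_identity(phage_pmoc, truth.host_pmoc[host_id]) == 100.0

    def test_divergence_counts_within_binomial_bounds(self):
        rng = np.random.default_rng(8)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=260))
        mutated = _diverge(rng, protein, 0.2, 0.02)
        n = len(protein)
        third = n // 3
        term_subs = sum(
            a != b
            for i, (a, b) in enumerate(zip(protein, mutated))
            if i < third or i >= n - third
        )
        core_subs = sum(
            a != b
            for i, (a, b) in enumerate(zip(protein, mutated))
            if third <= i < n - third
        )
        lo_t, hi_t = stats.binom.ppf([0.005, 0.995], 2 * third, 0.2)
        lo_c, hi_c = stats.binom.ppf([0.005, 0.995], n - 2 * third, 0.02)
        assert lo_t <= term_subs <= hi_t
        assert lo_c <= core_subs <= hi_c

    def test_every_phage_has_one_host_and_abundances_conserve(self, community):
        _, genomes, truth = community
        phage_ids = {
            g.genome_id
            for g in genomes
            if g.kind == "phage" and truth.pmoc_genes.get(g.genome_id)
        }
        assert set(truth.true_host_of) == phage_ids
        host_ids = {g.genome_id for g in genomes if g.kind == "host"}
        assert set(truth.true_host_of.values()) <= host_ids
        sums = truth.true_abundances.sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert (truth.true_abundances.to_numpy() >= 0).all()

    def test_fragmentation_produces_two_genes(self):
        config = CommunityConfig(
            genome_length_range=(15_000, 25_000), fragmentation_prob=1.0, seed=6
        )
        genomes, truth = simulate_community(config)
        for phage_id in truth.true_host_of:
            assert len(truth.pmoc_genes[phage_id]) == 2

    def test_host_operon_and_catalytic_sites(self, community):
        _, genomes, truth = community
        for genome in genomes:
            if genome.kind != "host":
                continue
            products = [g.product for g in genome.genes]
            assert PMOC_PRODUCT in products
            pmoc = truth.host_pmoc[genome.genome_id]
            for site, residue in zip(CATALYTIC_SITES, ("D", "H", "H")):
                assert pmoc[site - 1] == residue


class TestDepth:
    def test_zero_abundance_all_zero(self, community):
        config, genomes, _ = community
        sim = simulate_depth(genomes[0], 0.0, 1.0, config, rng=1)
        assert sim.depth_by_bin.sum() == 0

    def test_flat_profile_at_unit_gradient(self, community):
        config, genomes, _ = community
        sim = simulate_depth(genomes[0], 20.0, 1.0, config, rng=2)
        depth = sim.filtered(0.0).depth
        n = depth.size // 10
        first, last = depth[:n].mean(), depth[-n:].mean()
        assert first == pytest.approx(last, rel=0.05)

    def test_gradient_decile_ratio(self, community):
        config, genomes, _ = community
        sim = simulate_depth(genomes[0], 20.0, 2.0, config, rng=3)
        depth = sim.filtered(0.0).depth
        n = depth.size // 10
        ratio = depth[:n].mean() / depth[-n:].mean()
        # window means: origin decile ~2x terminus decile (modulo decile
        # averaging, which pulls the ratio slightly inside 2.0)
        assert 1.7 <= ratio <= 2.2

    def test_identity_mix_mass_allocation(self, community):
        config, genomes, _ = community
        sim = simulate_depth(genomes[0], 20.0, 1.0, config, rng=4)
        total = sim.depth_by_bin.sum()
        weights = np.array([w for _, w in config.read_identity_mix])
        observed = sim.depth_by_bin.sum(axis=1) / total
        assert np.allclose(observed, weights, atol=0.01)

    def test_negative_abundance_rejected(self, community):
        config, genomes, _ = community
        with pytest.raises(ValueError):
            simulate_depth(genomes[0], -1.0, 1.0, config)


class TestTranscriptome:
    def test_zero_reads_all_zero(self, community):
        _, genomes, _ = community
        phage = next(g for g in genomes if g.genome_id == "phage_1")
        counts = simulate_transcriptome(phage, "late", 0, seed=1)
        assert counts["reads"].sum() == 0

    def test_unknown_stage_rejected(self, community):
        _, genomes, _ = community
        phage = next(g for g in genomes if g.genome_id == "phage_1")
        with pytest.raises(ValueError, match="stage"):
            simulate_transcriptome(phage, "lysogenic", 100, seed=1)

    def test_inactive_stage_caps_reads(self, community):
        _, genomes, _ = community
        phage = next(g for g in genomes if g.genome_id == "phage_1")
        counts = simulate_transcriptome(phage, "inactive", 50_000, seed=1)
        assert counts["reads"].sum() <= 10


class TestSnpTable:
    def test_empty_when_no_sites(self):
        table, shifted = simulate_snp_table(0, seed=1)
        assert len(table) == 0 and shifted.size == 0

    def test_shifted_fraction_zero_plants_nothing(self):
        _, shifted = simulate_snp_table(200, (100, 100), 0.0, 0.5, seed=2)
        assert not shifted.any()

    def test_zero_group_depth_rejected(self):
        with pytest.raises(ValueError):
            simulate_snp_table(10, (0, 100), 0.1, 0.2, seed=1)


def test_depth_profile_matches_per_base_oracle_small(community):
    # cross-check SimulatedDepth.filtered against manual bin summation
    config, genomes, _ = community
    sim = simulate_depth(genomes[0], 5.0, 1.0, config, rng=9)
    manual = np.zeros(sim.depth_by_bin.shape[1], dtype=np.int64)
    for ident, row in zip(sim.identities, sim.depth_by_bin):
        if ident >= 0.95:
            manual += row
    assert np.array_equal(sim.filtered(0.95).depth, manual)
    stat = scaffold_coverage(sim.filtered(0.95))
    assert stat.coverage == pytest.approx(manual.sum() / manual.size)
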