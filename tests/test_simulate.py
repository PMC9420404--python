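"""The synthetic-data generator: drift model, planting, sampling, round-trip."""

import numpy as np
import pytest

from poolscan.io import (
    read_counts_tsv,
    read_genes,
    read_scaffold_lengths,
    read_truth_bed,
    read_vcf,
)
from poolscan.simulate import (
    SimConfig,
    TruthRegions,
    plant_selection_regions,
    sample_individual_genotypes,
    sample_pool_counts,
    simulate_dataset,
    simulate_species_frequencies,
    write_dataset,
)


class TestConfig:
    def test_region_bounds_validated(self):
        with pytest.raises(ValueError, match="outside scaffold bounds"):
            SimConfig(n_scaffolds=1, scaffold_length=1000, sweep_regions=[("scaf1", 500, 2000)])
        with pytest.raises(ValueError, match="unknown scaffold"):
            SimConfig(n_scaffolds=1, scaffold_length=1000, sweep_regions=[("scaf9", 0, 100)])

    def test_parameter_ranges(self):
        with pytest.raises(ValueError):
            SimConfig(sweep_maf_ceiling=0.5)
        with pytest.raises(ValueError):
            SimConfig(species_divergence=0.3)
        with pytest.raises(ValueError):
            SimConfig(n_scaffolds=0)

    def test_truth_regions_must_not_overlap_within_type(self):
        with pytest.raises(ValueError, match="overlapping"):
            TruthRegions([("s", 0, 100, "sweep"), ("s", 50, 150, "sweep")])


class TestSpeciesFrequencies:
    def test_zero_divergence_identity(self):
        cfg = SimConfig(n_scaffolds=2, scaffold_length=100_000, species_divergence=0.0, seed=1)
        f = simulate_species_frequencies(cfg)
        assert np.all(f.species_freqs == f.species_freqs[:, [0]])
        np.testing.assert_array_equal(f.pool_freq, f.species_freqs[:, 0])

    def test_frequencies_bounded(self):
        cfg = SimConfig(n_scaffolds=2, scaffold_length=200_000, species_divergence=0.25, seed=2)
        f = simulate_species_frequencies(cfg)
        assert np.all((f.species_freqs >= 0) & (f.species_freqs <= 1))

    def test_tree_distance_orders_mean_frequency_difference(self):
        """A and C are two extra branches apart vs A and B, so their mean
        frequency difference is larger (Monte-Carlo at 10^4 sites)."""
        cfg = SimConfig(
            n_scaffolds=2, scaffold_length=1_000_000, species_divergence=0.25, seed=3
        )
        f = simulate_species_frequencies(cfg)
        assert f.n_sites >= 9_000
        d_ab = np.mean(np.abs(f.species_freqs[:, 0] - f.species_freqs[:, 1]))
        d_ac = np.mean(np.abs(f.species_freqs[:, 0] - f.species_freqs[:, 2]))
        assert d_ac > d_ab

    def test_positions_sorted_unique_within_scaffold(self):
        cfg = SimConfig(n_scaffolds=3, scaffold_length=50_000, seed=4)
        f = simulate_species_frequencies(cfg)
        for scaf in np.unique(f.scaffolds):
            pos = f.positions[f.scaffolds == scaf]
            assert np.all(np.diff(pos) > 0)
            assert pos.min() >= 1 and pos.max() <= 50_000


class TestPlanting:
    def cfg(self, **kw):
        return SimConfig(n_scaffolds=2, scaffold_length=500_000, seed=5, **kw)

    def test_zero_ceiling_makes_pool_monomorphic_in_sweeps(self):
        cfg = self.cfg(sweep_regions=[("scaf1", 100_000, 200_000)], sweep_maf_ceiling=0.0)
        f = plant_selection_regions(simulate_species_frequencies(cfg), cfg)
        m = (f.scaffolds == "scaf1") & (f.positions - 1 >= 100_000) & (f.positions - 1 < 200_000)
        folded = np.minimum(f.pool_freq[m], 1 - f.pool_freq[m])
        assert np.all(folded == 0.0)

    def test_sweep_separates_focal_from_other_species(self):
        cfg = self.cfg(sweep_regions=[("scaf1", 100_000, 200_000)])
        f = plant_selection_regions(simulate_species_frequencies(cfg), cfg)
        m = (f.scaffolds == "scaf1") & (f.positions - 1 >= 100_000) & (f.positions - 1 < 200_000)
        sep = np.abs(f.species_freqs[m][:, 1:] - f.species_freqs[m][:, :1])
        # jitter is clipped at the frequency boundary, so allow its scale
        assert np.all(sep.min(axis=1) >= cfg.sweep_fst_floor - 0.1)
        folded = np.minimum(f.pool_freq[m], 1 - f.pool_freq[m])
        assert np.all(folded <= cfg.sweep_maf_ceiling)

    def test_balancing_raises_region_maf_above_background(self):
        cfg = self.cfg(balancing_regions=[("scaf2", 100_000, 300_000)])
        f = plant_selection_regions(simulate_species_frequencies(cfg), cfg)
        m = (f.scaffolds == "scaf2") & (f.positions - 1 >= 100_000) & (f.positions - 1 < 300_000)
        folded = np.minimum(f.pool_freq, 1 - f.pool_freq)
        assert folded[m].mean() > folded.mean()

    def test_empty_region_lists_are_noop(self):
        cfg = self.cfg()
        f0 = simulate_species_frequencies(cfg)
        f1 = plant_selection_regions(f0, cfg)
        np.testing.assert_array_equal(f0.species_freqs, f1.species_freqs)
        np.testing.assert_array_equal(f0.pool_freq, f1.pool_freq)

    def test_sites_outside_regions_untouched(self):
        cfg = self.cfg(sweep_regions=[("scaf1", 100_000, 200_000)])
        f0 = simulate_species_frequencies(cfg)
        f1 = plant_selection_regions(f0, cfg)
        outside = ~(
            (f0.scaffolds == "scaf1")
            & (f0.positions - 1 >= 100_000)
            & (f0.positions - 1 < 200_000)
        )
        np.testing.assert_array_equal(f0.species_freqs[outside], f1.species_freqs[outside])


class TestSampling:
    def test_zero_frequency_yields_zero_variant_reads(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=10_000, seed=6)
        depth, alt = sample_pool_counts(np.zeros(5_000), cfg)
        assert np.all(alt == 0)

    def test_binomial_sampling_calibration(self, rng):
        """Mean variant fraction tracks the realised pool frequency."""
        cfg = SimConfig(n_scaffolds=1, scaffold_length=10_000, mean_depth=40.0, seed=7)
        f = np.full(10_000, 0.5)
        depth, alt = sample_pool_counts(f, cfg, rng)
        ok = depth > 0
        frac = alt[ok] / depth[ok]
        se = frac.std(ddof=1) / np.sqrt(ok.sum())
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_poisson_limit_of_depth_model(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=10_000, depth_dispersion=0.0, seed=8)
        depth, _ = sample_pool_counts(np.full(50_000, 0.5), cfg)
        assert depth.var() == pytest.approx(depth.mean(), rel=0.05)

    def test_overdispersed_depth_variance(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=10_000, depth_dispersion=0.25, seed=8)
        depth, _ = sample_pool_counts(np.full(50_000, 0.5), cfg)
        expected = cfg.mean_depth + cfg.depth_dispersion * cfg.mean_depth**2
        assert depth.var() == pytest.approx(expected, rel=0.1)

    def test_genotypes_fixed_frequencies(self):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=50_000, species_divergence=0.0, seed=9)
        f = simulate_species_frequencies(cfg)
        f.species_freqs[:] = 1.0
        g = sample_individual_genotypes(f, cfg)
        assert np.all(g == 2)
        f.species_freqs[:] = 0.0
        assert np.all(sample_individual_genotypes(f, cfg) == 0)

    def test_hardy_weinberg_heterozygosity(self, rng):
        cfg = SimConfig(n_scaffolds=1, scaffold_length=50_000, species_divergence=0.0, seed=10)
        f = simulate_species_frequencies(cfg)
        f.species_freqs[:] = 0.5
        g = sample_individual_genotypes(f, cfg, rng)
        het = np.mean(g == 1)
        n = g.size
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * se


class TestDeterminismAndRoundTrip:
    def test_fixed_seed_bitwise_identical(self):
        cfg = SimConfig(n_scaffolds=2, scaffold_length=100_000, seed=11)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.freqs.species_freqs, d2.freqs.species_freqs)
        np.testing.assert_array_equal(d1.pool_alt, d2.pool_alt)
        np.testing.assert_array_equal(d1.genotypes, d2.genotypes)

    def test_write_then_read_round_trip(self, tmp_path):
        cfg = SimConfig(
            n_scaffolds=2,
            scaffold_length=100_000,
            seed=12,
            sweep_regions=[("scaf1", 10_000, 30_000)],
            balancing_regions=[("scaf2", 40_000, 60_000)],
        )
        ds = simulate_dataset(cfg)
        paths = write_dataset(ds, tmp_path)

        vt = read_vcf(paths["vcf"], pool_samples=["pool"])
        assert vt.samples == ds.sample_names  # header declares every sample
        np.testing.assert_array_equal(vt.positions, ds.freqs.positions)
        np.testing.assert_array_equal(vt.scaffolds.astype(str), ds.freqs.scaffolds.astype(str))
        ind_cols = [vt.samples.index(s) for s in cfg.individual_names]
        np.testing.assert_array_equal(vt.genotypes[:, ind_cols], ds.genotypes)
        ref, alt = vt.pool_ad["pool"]
        np.testing.assert_array_equal(ref, ds.pool_ref)
        np.testing.assert_array_equal(alt, ds.pool_alt)
        assert np.all(vt.quals == 999.0)

        counts = read_counts_tsv(paths["counts"])
        np.testing.assert_array_equal(counts["altCount"].to_numpy(), ds.pool_alt)

        lengths = read_scaffold_lengths(paths["scaffolds"])
        assert lengths == cfg.scaffold_lengths

        truth = read_truth_bed(paths["truth"])
        assert len(truth) == len(cfg.sweep_regions) + len(cfg.balancing_regions)

        genes = read_genes(paths["genes"])
        assert len(genes) == len(ds.genes)
        # at least one toy gene inside each truth region, and some outside
        for scaf, start, end, _ in truth:
            assert any(s == scaf and a < end and b > start for s, a, b, _ in genes)
        assert any(
            not any(s == scaf and a < end and b > start for scaf, start, end, _ in truth)
            for s, a, b, _ in genes
        )

    def test_gff3_gene_reader(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "scaf1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene1;Name=x\n"
            "scaf1\tsrc\texon\t101\t150\t.\t+\t.\tParent=gene1\n"
            "scaf2\tsrc\tgene\t501\t900\t.\t-\t.\tID=gene2\n"
        )
        genes = read_genes(gff)
        assert genes == [("scaf1", 100, 200, "gene1"), ("scaf2", 500, 900, "gene2")]
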