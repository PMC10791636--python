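"""Generator correctness: haplotype construction, read models, truth files."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scntomics.reads import seq_to_array
from scntomics.synthdata import (
    CONTROL,
    LAMBDA_CONTIG,
    TEST,
    DmrSpec,
    GeneExpressionSpec,
    SimulationConfig,
    SlideSpec,
    gen_hybrid_genomes,
    make_gene_models,
    simulate_bisulfite_reads,
    simulate_gestation,
    simulate_placenta_slide,
    simulate_rnaseq,
)


class TestHybridGenomes:
    def test_zero_snp_rate_yields_identical_haplotypes(self):
        cfg = SimulationConfig(genome_length=20_000, snp_rate=0.0, rng_seed=3)
        mat, pat, truth = gen_hybrid_genomes(cfg)
        assert mat == pat
        assert truth.snps.empty

    def test_snp_count_within_binomial_interval(self):
        # central 99.9% binomial interval for n=100k, p=1e-3, minus the CpG
        # and adjacency exclusions which drop only a small fraction of sites
        cfg = SimulationConfig(genome_length=100_000, snp_rate=1e-3, rng_seed=5)
        _, _, truth = gen_hybrid_genomes(cfg)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 100_000, 1e-3)
        # exclusions can only remove candidates, never add
        assert truth.snps.shape[0] <= hi
        assert truth.snps.shape[0] >= 0.5 * lo

    def test_haplotypes_differ_exactly_at_truth_snps(self, genomes):
        mat, pat, truth = genomes
        for chrom in truth.chrom_names:
            a = seq_to_array(mat[chrom])
            b = seq_to_array(pat[chrom])
            diff = np.flatnonzero(a != b)
            expected = truth.snps.loc[truth.snps["chrom"] == chrom, "pos"].to_numpy() - 1
            np.testing.assert_array_equal(diff, np.sort(expected))

    def test_snps_never_inside_cpg_on_either_haplotype(self, genomes):
        mat, pat, truth = genomes
        for hap in (mat, pat):
            for chrom in truth.chrom_names:
                arr = seq_to_array(hap[chrom])
                cpg = set(np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))))
                cpg |= {i + 1 for i in cpg}
                pos0 = truth.snps.loc[truth.snps["chrom"] == chrom, "pos"] - 1
                assert not (set(pos0) & cpg)

    def test_determinism_same_seed_same_output(self, small_cfg):
        a = gen_hybrid_genomes(small_cfg)
        b = gen_hybrid_genomes(small_cfg)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2].snps, b[2].snps)

    def test_planted_dmrs_lie_within_chromosomes(self, genomes):
        _, _, truth = genomes
        for d in truth.dmrs.itertuples():
            assert 0 <= d.start < d.end <= truth.chrom_lengths[d.chrom]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=0)
        with pytest.raises(ValueError):
            SimulationConfig(snp_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=50, read_length=100)
        with pytest.raises(ValueError):
            DmrSpec("bogus_kind", 100)


class TestBisulfiteReads:
    def test_read_count_conservation(self, small_cfg, bis_reads):
        expected = small_cfg.depth * small_cfg.genome_length / small_cfg.read_length
        assert len(bis_reads[CONTROL]) == round(expected)

    def test_full_conversion_unmethylated_genome(self):
        cfg = SimulationConfig(
            genome_length=10_000, snp_rate=0, background_meth=0.0, depth=5,
            conversion_efficiency=1.0, lambda_fraction=0.0, rng_seed=7,
        )
        mat, pat, truth = gen_hybrid_genomes(cfg)
        reads = simulate_bisulfite_reads(mat, pat, truth, cfg)
        ref = seq_to_array(mat["chr1"])
        top = reads.subset(reads.strand == 0)
        pos = top.start[:, None] + np.arange(cfg.read_length)[None, :]
        assert not np.any(top.seq[(ref[pos] == ord("C"))] == ord("C"))

    def test_full_methylation_keeps_cpg_cytosines(self):
        cfg = SimulationConfig(
            genome_length=10_000, snp_rate=0, background_meth=1.0, depth=5,
            conversion_efficiency=1.0, lambda_fraction=0.0, rng_seed=7,
        )
        mat, pat, truth = gen_hybrid_genomes(cfg)
        reads = simulate_bisulfite_reads(mat, pat, truth, cfg)
        ref = seq_to_array(mat["chr1"])
        cpg_c = np.zeros(len(ref), dtype=bool)
        cpg_c[:-1] = (ref[:-1] == ord("C")) & (ref[1:] == ord("G"))
        top = reads.subset(reads.strand == 0)
        pos = top.start[:, None] + np.arange(cfg.read_length)[None, :]
        at_cpg = cpg_c[pos]
        assert np.all(top.seq[at_cpg] == ord("C"))

    def test_deep_coverage_recovers_methylation_level(self):
        # a 200 bp genome at depth 1000: every CpG's observed fraction of
        # methylated calls must sit within 3 binomial SE of the planted 0.7
        cfg = SimulationConfig(
            genome_length=200, snp_rate=0, background_meth=0.7, depth=1000,
            read_length=50, conversion_efficiency=1.0, lambda_fraction=0.0, rng_seed=9,
        )
        mat, pat, truth = gen_hybrid_genomes(cfg)
        reads = simulate_bisulfite_reads(mat, pat, truth, cfg)
        from scntomics.methylome import add_level, call_cpg_methylation

        table = add_level(call_cpg_methylation(reads, {k: mat[k] for k in mat}))
        table = table[table["coverage"] >= 100]
        assert len(table) > 0
        se = np.sqrt(0.7 * 0.3 / table["coverage"])
        assert (np.abs(table["level"] - 0.7) <= 3 * se + 1e-12).all()

    def test_lambda_reads_fully_converted_at_perfect_efficiency(self):
        cfg = SimulationConfig(
            genome_length=10_000, snp_rate=0, background_meth=1.0, depth=10,
            conversion_efficiency=1.0, lambda_fraction=0.2, rng_seed=3,
        )
        mat, pat, truth = gen_hybrid_genomes(cfg)
        reads = simulate_bisulfite_reads(mat, pat, truth, cfg)
        lam_idx = reads.ref_names.index(LAMBDA_CONTIG)
        lam = reads.subset(reads.chrom_idx == lam_idx)
        assert len(lam) == round(0.2 * len(reads))
        ref = seq_to_array(mat[LAMBDA_CONTIG])
        pos = lam.start[:, None] + np.arange(cfg.read_length)[None, :]
        top = lam.strand[:, None] == 0
        # spike-in is always unmethylated: no C survives on top, no G on bottom
        assert not np.any((ref[pos] == ord("C")) & top & (lam.seq == ord("C")))
        assert not np.any((ref[pos] == ord("G")) & ~top & (lam.seq == ord("G")))

    def test_determinism(self, small_cfg, genomes):
        mat, pat, truth = genomes
        r1 = simulate_bisulfite_reads(mat, pat, truth, small_cfg, CONTROL)
        r2 = simulate_bisulfite_reads(mat, pat, truth, small_cfg, CONTROL)
        np.testing.assert_array_equal(r1.seq, r2.seq)
        np.testing.assert_array_equal(r1.start, r2.start)

    def test_condition_substreams_independent(self, small_cfg, genomes):
        mat, pat, truth = genomes
        r_icsi = simulate_bisulfite_reads(mat, pat, truth, small_cfg, CONTROL)
        r_scnt = simulate_bisulfite_reads(mat, pat, truth, small_cfg, TEST)
        assert not np.array_equal(r_icsi.start, r_scnt.start)


class TestRnaSeq:
    @pytest.fixture()
    def cfg(self):
        return SimulationConfig(genome_length=50_000, snp_rate=5e-3, rng_seed=21)

    def test_equal_means_plant_zero_log2fc(self, cfg):
        models = make_gene_models(cfg, 4)
        specs = [GeneExpressionSpec(g, 200, 200) for g in models["gene_id"]]
        counts, _ = simulate_rnaseq(models, specs, cfg, n_replicates=30)
        # planted log2FC is zero: group means agree within sampling noise
        ratio = counts[TEST].mean(axis=1) / counts[CONTROL].mean(axis=1)
        assert np.abs(np.log2(ratio)).max() < 0.5

    def test_poisson_limit_mean_recovery(self, cfg):
        models = make_gene_models(cfg, 1)
        specs = [GeneExpressionSpec("gene1", 500, 500, dispersion=0.0)]
        counts, _ = simulate_rnaseq(models, specs, cfg, n_replicates=200)
        m = counts[CONTROL].to_numpy().mean()
        se = np.sqrt(500 / 200)
        assert abs(m - 500) < 3 * se

    def test_maternal_fraction_one_gives_all_maternal_reads(self, cfg):
        mat, pat, truth = gen_hybrid_genomes(cfg)
        models = make_gene_models(cfg, 2)
        specs = [
            GeneExpressionSpec(g, 100, 100, maternal_fraction_control=1.0, n_allelic_reads=50)
            for g in models["gene_id"]
        ]
        _, allelic = simulate_rnaseq(models, specs, cfg, truth, mat, pat)
        assert (allelic[CONTROL].allele_truth == 0).all()

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            GeneExpressionSpec("g", 10, 10, dispersion=-0.1)

    def test_overlapping_gene_models_rejected(self, cfg):
        models = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": ["chr1", "chr1"],
                "start": [100, 500],
                "end": [1000, 1500],
                "strand": ["+", "+"],
                "exon_starts": ["100", "500"],
                "exon_ends": ["1000", "1500"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_rnaseq(models, [GeneExpressionSpec("a", 10, 10)], cfg)


class TestSlides:
    def test_zero_particles_zero_truth_area(self, rng):
        _, truth = simulate_placenta_slide(SlideSpec(particles=[]), rng)
        assert truth["calcified_area_mm2"] == 0.0
        assert truth["n_particles"] == 0

    def test_truth_area_equals_rasterized_pixels_times_pixel_area(self, rng):
        spec = SlideSpec(particles=[(256, 256, 10)])
        img, truth = simulate_placenta_slide(spec, rng)
        # a rasterized disk of radius 10 holds ~pi*r^2 pixels
        n_px = truth["calcified_area_mm2"] / spec.pixel_size_mm**2
        assert abs(n_px - np.pi * 100) / (np.pi * 100) < 0.05

    def test_known_geometry_truth_cci(self, rng):
        # one particle of ~1% of the tissue area -> truth CCI ~1%
        spec = SlideSpec(particles=[(256, 256, 30)])
        _, truth = simulate_placenta_slide(spec, rng)
        cci = 100 * truth["calcified_area_mm2"] / truth["tissue_area_mm2"]
        expected = 100 * (np.pi * 30**2) / (np.pi * 200 * 150)
        assert abs(cci - expected) < 0.1

    def test_particle_outside_tissue_rejected(self, rng):
        with pytest.raises(ValueError, match="outside"):
            simulate_placenta_slide(SlideSpec(particles=[(5, 5, 4)]), rng)


class TestGestation:
    def test_point_mass_all_events_on_that_day(self):
        t = simulate_gestation({"A": 10}, {"A": ("point", 40)}, seed=1)
        assert (t["day"] == 40).all() and t["event"].all()

    def test_exponential_median_within_order_statistic_interval(self):
        scale = 60 / np.log(2)  # exponential with median 60
        t = simulate_gestation({"A": 500}, {"A": ("exponential", scale)}, seed=2)
        med = t["day"].median()
        # 99.7% CI of the sample median: ~ median * 1.25/sqrt(n) spread
        assert abs(med - 60) < 3 * 1.2533 * 60 / np.sqrt(500)

    def test_same_seed_reproducible(self):
        a = simulate_gestation({"A": 20, "B": 20}, {"A": ("exponential", 50), "B": ("exponential", 50)}, seed=3)
        b = simulate_gestation({"A": 20, "B": 20}, {"A": ("exponential", 50), "B": ("exponential", 50)}, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_censoring_at_term(self):
        t = simulate_gestation({"A": 200}, {"A": ("exponential", 100)}, seed=4, censor_at=165)
        censored = t[~t["event"]]
        assert (censored["day"] == 165).all()
        assert (t.loc[t["event"], "day"] < 165).all()

    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError):
            simulate_gestation({"A": 5}, {"A": ("exponential", 0)}, seed=1)
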