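import math

import numpy as np
import pandas as pd
import pytest

from oracles import compound_binomial_read_var
from polyfoot.io_formats import read_gene_annotation, read_sync
from polyfoot.simulate import (
    ScenarioConfig,
    emit_dataset,
    neutral_wf_evolve,
    pool_sequence,
    simulate_populations,
)


class TestNeutralDrift:
    def test_final_frequency_variance_matches_closed_form(self):
        """Var(p_t) = p0 q0 (1 - (1 - 1/2N)^t) for pure drift."""
        n, t, reps = 500, 100, 500
        rng = np.random.default_rng(0)
        p = neutral_wf_evolve(np.full(reps, 0.5), n, 0.0, t, rng)
        expected = 0.25 * (1 - (1 - 1 / (2 * n)) ** t)
        assert np.var(p) == pytest.approx(expected, rel=0.15)

    def test_heterozygosity_decays_geometrically(self):
        """E[2pq] after t generations = H_0 (1 - 1/2N)^t."""
        n, reps = 200, 2000
        rng = np.random.default_rng(1)
        p0 = np.full(reps, 0.5)
        for t in (50, 200):
            p = neutral_wf_evolve(p0, n, 0.0, t, rng)
            h = np.mean(2 * p * (1 - p))
            assert h == pytest.approx(0.5 * (1 - 1 / (2 * n)) ** t, rel=0.05)


class TestScenarios:
    def test_same_seed_is_bit_reproducible(self):
        cfg = ScenarioConfig(scenario="DISCORDANT_ENGINEERED", n_genes=30, seed=9)
        a = simulate_populations(cfg)
        b = simulate_populations(cfg)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="BOGUS")

    def test_stabilizing_keeps_trait_mean_near_the_optimum(self):
        cfg = ScenarioConfig(
            scenario="STABILIZING_SHARED", n_genes=15, n_diploid=200,
            n_ns_loci=10, n_syn_loci=5, omega=0.5, effect_scale=0.3,
            burn_in=100, g_split=100, optima=(0.0, 0.0, 0.0), seed=3,
        )
        res = simulate_populations(cfg)
        alpha = res.truth.effect_sizes
        for pop in range(cfg.n_pops):
            p = res.freqs[pop, :, : cfg.n_ns_loci]
            z_mean = (alpha * 2 * p).sum(axis=1)
            z_sd = np.sqrt((alpha**2 * 2 * p * (1 - p)).sum(axis=1))
            # trait mean within 2 phenotypic SD of the optimum (SD floored by
            # omega for genes whose variation has been exhausted)
            scale = np.maximum(z_sd, cfg.omega)
            assert (np.abs(z_mean) <= 2 * scale + 1e-9).mean() > 0.8

    def test_shifted_optima_diverge_more_than_shared(self):
        common = dict(
            n_diploid=200, n_genes=15, n_ns_loci=10, n_syn_loci=5,
            burn_in=80, g_split=120, omega=1.0, effect_scale=0.3, seed=5,
        )
        shared = simulate_populations(
            ScenarioConfig(scenario="STABILIZING_SHARED", optima=(0.0, 0.0, 0.0), **common)
        )
        shifted = simulate_populations(
            ScenarioConfig(scenario="STABILIZING_SHIFTED", optima=(0.0, 1.5, -1.5), **common)
        )

        def ns_divergence(res):
            f = res.freqs[:, :, :10]
            return np.mean(
                (f[0] - f[1]) ** 2 + (f[0] - f[2]) ** 2 + (f[1] - f[2]) ** 2
            )

        assert ns_divergence(shifted) > ns_divergence(shared)

    def test_discordant_genes_show_opposite_d_signs(self, discordant_run):
        """Sweep population: rare-variant excess (D < 0); balancing: D > 0."""
        truth = discordant_run.truth
        stats = discordant_run.gene_stats
        merged = stats.merge(
            truth[["gene_id", "scenario_class", "sweep_pop"]], on="gene_id"
        )
        disc = merged[merged["scenario_class"] == "DISCORDANT"]
        sweep = disc[disc["pop"] == disc["sweep_pop"]]
        balance = disc[(disc["pop"] == 1 - disc["sweep_pop"])]
        neutral = merged[merged["scenario_class"] == "NEUTRAL"]
        assert sweep["D_ns"].mean() < neutral["D_ns"].mean()
        assert balance["D_ns"].mean() > 0
        assert sweep["D_ns"].mean() < 0 or (
            sweep["D_ns"].mean() < balance["D_ns"].mean() - 1.0
        )


class TestPoolSequence:
    def test_monomorphic_frequency_gives_all_reference_reads(self):
        cfg = ScenarioConfig(seed=0)
        rng = np.random.default_rng(0)
        alt, depth = pool_sequence(np.zeros((1, 5, 4)), cfg, rng)
        assert alt.sum() == 0
        assert depth.shape == (1, 5, 4)

    def test_read_frequency_variance_matches_compound_binomial(self):
        cfg = ScenarioConfig(seed=0)
        rng = np.random.default_rng(2)
        p = 0.5
        alt, depth = pool_sequence(np.full((1, 100, 100), p), cfg, rng)
        ok = depth > 0
        freqs = alt[ok] / depth[ok]
        expected = compound_binomial_read_var(p, cfg.n_pool_haploid, depth[ok])
        assert np.var(freqs) == pytest.approx(expected, rel=0.10)

    def test_seeded_determinism(self):
        cfg = ScenarioConfig(seed=0)
        f = np.random.default_rng(5).uniform(0, 1, (2, 10, 10))
        a1, d1 = pool_sequence(f, cfg, np.random.default_rng(7))
        a2, d2 = pool_sequence(f, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(d1, d2)


class TestEmitDataset:
    def test_files_are_consistent(self, neutral_run):
        ds = neutral_run.dataset
        genes, site_classes = read_gene_annotation(
            ds.paths["bed"], ds.paths["site_classes"]
        )
        sync_sites = {
            (r.contig, r.pos)
            for r in read_sync(ds.paths["sync"], [400, 400, 400])
        }
        # every sync site is classified, and vice versa
        classified = set(zip(site_classes["contig"], site_classes["pos"]))
        assert sync_sites == classified
        # every gene in the BED has sites in the sync file
        assert set(site_classes["gene_id"]) == set(genes["gene_id"])

    def test_default_calibration_hits_diversity_and_density_anchors(self, neutral_run):
        """pi_S within a factor 2 of 0.022; SNP density within a factor 2 of 6/kb."""
        stats = neutral_run.gene_stats
        pi_s = stats["pi_s"].mean()
        assert 0.011 <= pi_s <= 0.044
        snps = (
            neutral_run.sites.groupby(["pool", "gene_id"])["is_snp"]
            .sum()
            .reset_index()
            .merge(neutral_run.genes[["gene_id", "length"]], on="gene_id")
        )
        density = (snps["is_snp"] / (snps["length"] / 1000)).mean()
        assert 3.0 <= density <= 12.0

    def test_pi_s_recovers_the_scaled_mutation_rate(self, neutral_run):
        """Mean synonymous diversity matches theta = 4 N mu within 10%."""
        theta = neutral_run.dataset.config.theta_site
        pi_s = neutral_run.gene_stats["pi_s"].mean()
        assert pi_s == pytest.approx(theta, rel=0.10)

    def test_neutral_tajimas_d_is_calibrated_at_full_spectrum_depth(self, tmp_path):
        """Mean raw D_NS near 0 (within +-0.3) and standardized D exactly 0.

        Run at 1000x so the folded spectrum is fully observable; at the
        default 125x the minor-count threshold hides variants below ~1.6%
        frequency, which truncates the rare tail and shifts raw D upward.
        """
        from polyfoot.pipeline import run_scenario
        from polyfoot.sfs import FilterParams

        cfg = ScenarioConfig(
            scenario="NEUTRAL_INDEPENDENT", n_genes=300, seed=21, depth_mean=1000
        )
        run = run_scenario(
            cfg, tmp_path, params=FilterParams(min_depth=10, max_depth=10_000)
        )
        stats = run.gene_stats
        assert abs(stats["D_ns"].mean()) < 0.3
        assert np.nanmean(stats["D_ns_std"]) == pytest.approx(0.0, abs=1e-9)

    def test_estimated_fst_tracks_truth_across_genes(self, discordant_run):
        merged = discordant_run.pair_tables["0-1"].merge(
            discordant_run.truth[["gene_id", "fst_true_0-1"]], on="gene_id"
        )
        ok = merged[["fst", "fst_true_0-1"]].dropna()
        r = np.corrcoef(ok["fst"], ok["fst_true_0-1"])[0, 1]
        assert r > 0.7
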