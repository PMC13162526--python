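"""Gene-dropping genotypes, oligogenic trait and augmented-trial phenotypes."""

import numpy as np
import pandas as pd
import pytest

import hcngp
from hcngp.io_config import ConfigError, DesignError
from hcngp.synthetic_data import (SimConfig, simulate_genotypes,
                                  simulate_trait, simulate_trials)


def _cross_cfg(**kw):
    base = dict(n_founders=2, n_families=1, family_size=50, n_markers=30,
                missing_rate=0.0, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestGenotypes:
    def test_homozygous_opposite_founders_force_heterozygotes(self):
        cfg = _cross_cfg()
        founders = np.vstack([np.zeros(30), np.full(30, 2.0)])
        geno, ped = simulate_genotypes(cfg, founder_dosage=founders)
        off = [c for c in geno.clone_ids if ped[c][0] is not None]
        sub = geno.subset(clones=off)
        assert np.all(sub.dosage == 1.0)

    def test_het_by_het_segregates_1_2_1(self):
        cfg = _cross_cfg(family_size=2000)
        founders = np.ones((2, 30))
        geno, ped = simulate_genotypes(cfg, founder_dosage=founders)
        off = [c for c in geno.clone_ids if ped[c][0] is not None]
        d = geno.subset(clones=off).dosage[:, 0]
        props = [np.mean(d == k) for k in (0, 1, 2)]
        # binomial error at n=2000 is ~0.01; allow 4 sigma
        assert props[0] == pytest.approx(0.25, abs=0.04)
        assert props[1] == pytest.approx(0.50, abs=0.045)
        assert props[2] == pytest.approx(0.25, abs=0.04)

    def test_zero_missing_rate_leaves_no_gaps(self, small_sim):
        cfg = SimConfig(n_founders=10, n_families=4, family_size=5,
                        n_markers=100, missing_rate=0.0, seed=2)
        geno, _ = simulate_genotypes(cfg)
        assert not np.isnan(geno.dosage).any()

    def test_missing_rate_applied(self, small_sim):
        frac = np.isnan(small_sim["geno"].dosage).mean()
        assert frac == pytest.approx(small_sim["cfg"].missing_rate, abs=0.01)

    def test_full_sibs_share_both_parents(self, small_sim):
        cfg, geno = small_sim["cfg"], small_sim["geno"]
        _, ped = simulate_genotypes(cfg)
        off = [c for c in geno.clone_ids if ped[c][0] is not None]
        fam = off[:cfg.family_size]
        parents = {ped[c] for c in fam}
        assert len(parents) == 1

    def test_too_few_founders_rejected(self):
        with pytest.raises(ConfigError, match="n_founders"):
            SimConfig(n_founders=1).validate()

    def test_determinism(self):
        cfg = SimConfig(n_founders=10, n_families=4, family_size=5,
                        n_markers=100, seed=11)
        g1, _ = simulate_genotypes(cfg)
        g2, _ = simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)


class TestTrait:
    def test_qtl_variance_fractions_recovered_by_regression(self):
        # variance-component oracle: R2 of the latent phenotype on each QTL
        # dosage should match the target fraction at large n
        cfg = SimConfig(n_founders=40, n_families=50, family_size=20,
                        n_markers=360, missing_rate=0.0, polygenic_h2=0.0,
                        dominance_fraction=0.0, seed=3)
        geno, ped = simulate_genotypes(cfg)
        truth = simulate_trait(geno, cfg, pedigree=ped)
        rng = np.random.default_rng(99)
        noise_sd = np.sqrt(cfg.var_clone_location + cfg.var_residual)
        y = (truth.true_breeding_values.to_numpy()
             + rng.normal(0, noise_sd, geno.n_clones))
        var_p = cfg.phenotypic_variance
        mi = {m: j for j, m in enumerate(geno.marker_ids)}
        X = geno.dosage
        for (chrom, frac), mk in zip(cfg.qtl_spec, truth.qtl_marker_ids):
            x = X[:, mi[mk]]
            r2 = np.corrcoef(x, y)[0, 1] ** 2 * np.var(y) / var_p
            assert r2 == pytest.approx(frac, abs=0.05)

    def test_null_trait_has_zero_breeding_values(self):
        cfg = SimConfig(n_founders=10, n_families=4, family_size=5,
                        n_markers=100, qtl_spec=(), polygenic_h2=0.0,
                        dominance_fraction=0.0, seed=4)
        geno, ped = simulate_genotypes(cfg)
        truth = simulate_trait(geno, cfg, pedigree=ped)
        assert np.allclose(truth.true_breeding_values, 0.0)

    def test_additive_variance_matches_target(self, small_sim):
        cfg, truth = small_sim["cfg"], small_sim["truth"]
        target = cfg.additive_fraction * cfg.phenotypic_variance
        assert truth.realized_variances["additive"] == pytest.approx(
            target, rel=0.15)

    def test_doubling_effects_quadruples_additive_variance(self, small_sim):
        tbv = small_sim["truth"].true_breeding_values.to_numpy()
        assert np.var(2 * tbv) == pytest.approx(4 * np.var(tbv))

    def test_monomorphic_qtl_chromosome_is_error(self):
        cfg = SimConfig(n_founders=2, n_families=1, family_size=10,
                        n_markers=36, missing_rate=0.0, seed=5)
        founders = np.zeros((2, 36))     # everything monomorphic
        geno, ped = simulate_genotypes(cfg, founder_dosage=founders)
        # drop the random check clones so the table is truly monomorphic
        mono = [c for c in geno.clone_ids if not c.startswith("CK")]
        with pytest.raises(hcngp.SimulationError, match="monomorphic"):
            simulate_trait(geno.subset(clones=mono), cfg, pedigree=ped)


class TestTrials:
    def test_degenerate_design_scores_exactly_mu(self):
        cfg = SimConfig(n_founders=10, n_families=4, family_size=5,
                        n_markers=100, qtl_spec=(("chr1", 0.0),),
                        polygenic_h2=0.0, dominance_fraction=0.0,
                        var_clone_location=0.0, var_block=0.0,
                        var_residual=0.0, var_subsample=0.0, mu=5.0,
                        location_effects=(0.0, 0.0, 0.0), seed=6)
        geno, ped = simulate_genotypes(cfg)
        truth = simulate_trait(geno, cfg, pedigree=ped)
        pheno = simulate_trials(truth, cfg)
        scores = pheno.data[[f"score_{i}" for i in range(1, 7)]].to_numpy()
        assert np.all(scores == 5.0)

    def test_location_means_follow_location_effects(self, small_sim):
        # qualitative check: the low location (-0.8) sits clearly below the
        # two high ones (+0.3, +0.5), whose 0.2 gap is within design noise
        cfg = small_sim["cfg"]
        df = small_sim["pheno"].data
        means = df.groupby("location")["plot_mean"].mean()
        assert means["L1"] < means["L2"] and means["L1"] < means["L3"]
        grand = df["plot_mean"].mean()
        # genetic values are centered over all clones, so the phenotyped
        # subset carries a (real) nonzero mean genetic value
        g_pheno = small_sim["truth"].total_genetic_values.loc[
            df["clone_id"]].mean()     # plot-weighted (checks repeat)
        assert grand == pytest.approx(
            cfg.mu + np.mean(cfg.location_effects) + g_pheno, abs=0.3)

    def test_checks_once_per_block(self, small_sim):
        df = small_sim["pheno"].data
        checks = df[df["is_check"]]
        per_block = checks.groupby(["block_id", "clone_id"]).size()
        assert (per_block == 1).all()
        n_blocks = df["block_id"].nunique()
        assert len(per_block) == 2 * n_blocks

    def test_every_test_clone_once_per_location(self, small_sim):
        df = small_sim["pheno"].data
        entries = df[~df["is_check"]]
        counts = entries.groupby(["location", "clone_id"]).size()
        assert (counts == 1).all()

    def test_capacity_error_when_too_many_clones(self):
        cfg = SimConfig(n_founders=10, n_families=10, family_size=10,
                        n_markers=50, blocks_per_trial=2, plots_per_block=15,
                        seed=8)
        geno, ped = simulate_genotypes(cfg)
        truth = simulate_trait(geno, cfg, pedigree=ped)
        with pytest.raises(DesignError, match="capacity"):
            simulate_trials(truth, cfg)

    def test_scores_within_ordinal_range(self, small_sim):
        scores = small_sim["pheno"].data[
            [f"score_{i}" for i in range(1, 7)]].to_numpy()
        assert scores.min() >= 1 and scores.max() <= 9

    def test_determinism(self, small_sim):
        cfg = small_sim["cfg"]
        p1 = simulate_trials(small_sim["truth"], cfg)
        p2 = simulate_trials(small_sim["truth"], cfg)
        pd.testing.assert_frame_equal(p1.data, p2.data)
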