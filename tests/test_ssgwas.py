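"""SNP-effect back-solving, p-values and panel pre-selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from sibstep import GenotypeMatrix, VarianceComponents, make_kinship_inverse
from sibstep.genomic import allele_frequencies, blend_G, build_G, centred_scores
from sibstep.ssgwas import (
    backsolve_snp_effects,
    gwas_scan,
    preselect_snps,
    snp_effect_variances,
    snp_pvalues,
)

from conftest import small_config


def random_panel(seed, n=20, m=5):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(
        np.array([f"a{i}" for i in range(n)], object),
        np.array([f"S{j}" for j in range(m)], object),
        vals,
    )


class TestBacksolve:
    def test_reconstruction_identity_with_unblended_G(self):
        panel = random_panel(1, n=20, m=5)
        Z, keep, denom = centred_scores(panel)
        G = Z @ Z.T / denom + 1e-9 * np.eye(20)  # ridge only for invertibility
        # GEBVs computed with this G live in the SNP span, as in a real fit
        u = Z @ np.random.default_rng(2).standard_normal(Z.shape[1])
        a = backsolve_snp_effects(u, G, Z, denom)
        # G built from the same Z: Z a reproduces u up to the tiny ridge
        np.testing.assert_allclose(Z @ a, u, atol=1e-5)

    def test_matches_ridge_regression_closed_form(self):
        # a = Z'(ZZ' + lam I)^-1 u equals ridge (Z'Z + lam I)^-1 Z'u
        panel = random_panel(3, n=15, m=40)
        Z, keep, denom = centred_scores(panel)
        u = np.random.default_rng(4).standard_normal(15)
        lam = 0.7
        G = (Z @ Z.T + lam * np.eye(15)) / denom
        a = backsolve_snp_effects(u, G, Z, denom)
        ridge = linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ u)
        np.testing.assert_allclose(a, ridge, atol=1e-8)

    def test_monomorphic_snp_gets_zero_effect(self):
        panel = random_panel(5, n=12, m=6)
        panel.values[:, 2] = 2  # fixed allele
        from sibstep.pedigree import validate_and_renumber

        G = build_G(panel) + 0.05 * np.eye(12)
        u = np.random.default_rng(6).standard_normal(12)
        res = gwas_scan(panel, u, G, np.zeros((12, 12)), 1.0)
        row = res.table.set_index("snp_id").loc["S2"]
        assert row["effect"] == 0.0
        assert row["p"] == 1.0 and row["flagged"]

    def test_dimension_mismatch(self):
        panel = random_panel(7)
        Z, _, denom = centred_scores(panel)
        with pytest.raises(ValueError, match="dimension"):
            backsolve_snp_effects(np.ones(3), np.eye(3), Z, denom)


class TestPvalues:
    def test_zero_effect_gives_p_one(self):
        t = snp_pvalues(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert t.loc[0, "p"] == 1.0

    def test_nonpositive_variance_flagged(self):
        t = snp_pvalues(np.array([0.5]), np.array([0.0]))
        assert t.loc[0, "p"] == 1.0 and bool(t.loc[0, "flagged"])

    def test_null_panel_p_values_are_calibrated(self):
        # no QTL at all: the p distribution should be near uniform
        from sibstep import drop_genes, simulate_phenotypes, simulate_pedigree
        from sibstep.mixed_model import MMESystem, ModelSpec, build_design
        from sibstep.pedigree import extract_A22
        from sibstep.simulate import mask_genotypes

        cfg = small_config(
            seed=61, families_per_generation=(14, 12, 8), offspring_mean=14.0,
            n_snp=2000, n_qtl=2, sigma_g=1e-8, genotyped_families=12,
            genotyped_individuals=120, missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        geno, truth = drop_genes(ped, cfg)
        pheno = simulate_phenotypes(ped, truth, cfg)
        panel = mask_genotypes(geno, cfg, ped=ped)
        A22 = extract_A22(ped, panel.sample_ids)
        G_star = blend_G(build_G(panel), A22, 0.95, 0.05)
        from sibstep.genomic import build_H_inverse
        from sibstep.pedigree import build_A_inverse

        geno_idx = ped.code_of(panel.sample_ids) - 1
        parts = build_H_inverse(build_A_inverse(ped), G_star, A22, geno_idx)
        design = build_design(pheno, ModelSpec(), ped)
        vc = VarianceComponents(5.0, cfg.sigma_e, cfg.sigma_c)
        sys_ = MMESystem(pheno["tag_weight_g"].to_numpy(), design, parts.to_sparse(), parts.logdet_H)
        sys_.set_components(vc)
        theta = sys_.solution()
        u_geno = theta[sys_.sl_u][geno_idx]
        pev = sys_.pev_block(geno_idx)
        res = gwas_scan(panel, u_geno, G_star, pev, vc.sigma_g)
        frac = float((res.table["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.035)

    def test_large_qtl_is_top_hit(self):
        # a QTL explaining a large share of the genetic variance should be
        # the panel's strongest signal in most replicates
        from sibstep import drop_genes, simulate_phenotypes, simulate_pedigree
        from sibstep.mixed_model import MMESystem, ModelSpec, build_design
        from sibstep.pedigree import build_A_inverse, extract_A22
        from sibstep.genomic import build_H_inverse
        from sibstep.simulate import mask_genotypes

        hits = 0
        reps = 5
        for seed in range(71, 71 + reps):
            cfg = small_config(
                seed=seed, families_per_generation=(12, 18, 8), offspring_mean=18.0,
                n_snp=300, n_qtl=1, sigma_g=30.0, sigma_c=5.0, sigma_e=20.0,
                genotyped_families=16, genotyped_individuals=200, missing_rate=0.0,
            )
            ped = simulate_pedigree(cfg)
            geno, truth = drop_genes(ped, cfg)
            pheno = simulate_phenotypes(ped, truth, cfg)
            panel = mask_genotypes(geno, cfg, ped=ped)
            A22 = extract_A22(ped, panel.sample_ids)
            G_star = blend_G(build_G(panel), A22, 0.95, 0.05)
            geno_idx = ped.code_of(panel.sample_ids) - 1
            parts = build_H_inverse(build_A_inverse(ped), G_star, A22, geno_idx)
            design = build_design(pheno, ModelSpec(), ped)
            vc = VarianceComponents(cfg.sigma_g, cfg.sigma_e, cfg.sigma_c)
            sys_ = MMESystem(
                pheno["tag_weight_g"].to_numpy(), design, parts.to_sparse(), parts.logdet_H
            )
            sys_.set_components(vc)
            theta = sys_.solution()
            u_geno = theta[sys_.sl_u][geno_idx]
            pev = sys_.pev_block(geno_idx)
            res = gwas_scan(panel, u_geno, G_star, pev, vc.sigma_g)
            top = res.table.sort_values("p").iloc[0]["snp_id"]
            hits += top in set(truth.qtl_ids)
        assert hits >= int(0.8 * reps)


class TestPreselect:
    def test_threshold_on_single_run(self):
        run = pd.Series({"S1": 1e-6, "S2": 1e-4})
        sel = preselect_snps([run], threshold=1e-5)
        assert sel.tolist() == ["S1"]

    def test_empty_runs_empty_selection(self):
        assert preselect_snps([pd.Series(dtype=float)]).tolist() == []

    def test_intersection_vs_union(self):
        runs = [
            pd.Series({"S1": 1e-6, "S2": 1e-6, "S3": 0.5}),
            pd.Series({"S1": 1e-6, "S2": 0.5, "S3": 0.5}),
            pd.Series({"S1": 1e-6, "S2": 1e-6, "S3": 0.5}),
        ]
        assert preselect_snps(runs).tolist() == ["S1"]
        assert preselect_snps(runs, rule="union").tolist() == ["S1", "S2"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            preselect_snps([pd.Series({"S1": 0.5})], threshold=2.0)


class TestRefitWithPanel:
    @pytest.fixture(scope="class")
    def setting(self):
        from sibstep import drop_genes, simulate_phenotypes, simulate_pedigree
        from sibstep.evaluation import make_folds
        from sibstep.simulate import mask_genotypes

        cfg = small_config(
            seed=81, families_per_generation=(8, 7, 4), offspring_mean=12.0,
            n_snp=200, n_qtl=40, genotyped_families=6, genotyped_individuals=60,
            missing_rate=0.0,
        )
        ped = simulate_pedigree(cfg)
        geno, truth = drop_genes(ped, cfg)
        pheno = simulate_phenotypes(ped, truth, cfg)
        panel = mask_genotypes(geno, cfg, ped=ped)
        vc = VarianceComponents(cfg.sigma_g, cfg.sigma_e, cfg.sigma_c)
        plan = make_folds(len(pheno), 4, 1, seed=82)
        return cfg, ped, pheno, panel, truth, vc, plan

    def test_full_panel_selection_reproduces_ssgblup(self, setting):
        from sibstep.evaluation import cross_validate
        from sibstep.mixed_model import ModelSpec
        from sibstep.ssgwas import refit_with_panel

        cfg, ped, pheno, panel, truth, vc, plan = setting
        spec = ModelSpec(relationship="H")
        K_inv, logdet_K, _ = make_kinship_inverse(ped, panel, "H")
        direct = cross_validate(pheno, ped, K_inv, logdet_K, spec, vc, plan)
        refit = refit_with_panel(panel.snp_ids, panel, pheno, ped, spec, vc, plan)
        np.testing.assert_allclose(
            refit.runs["accuracy"].to_numpy(), direct.runs["accuracy"].to_numpy(), atol=1e-10
        )
        assert refit.label.get("method") == "ssGWAS"

    def test_single_snp_panel_runs_via_blending(self, setting):
        from sibstep.mixed_model import ModelSpec
        from sibstep.ssgwas import refit_with_panel

        cfg, ped, pheno, panel, truth, vc, plan = setting
        res = refit_with_panel(panel.snp_ids[:1], panel, pheno, ped, ModelSpec(relationship="H"), vc, plan)
        assert np.isfinite(res.mean_accuracy)

    def test_empty_selection_falls_back_to_full_panel(self, setting):
        from sibstep.mixed_model import ModelSpec
        from sibstep.ssgwas import refit_with_panel

        cfg, ped, pheno, panel, truth, vc, plan = setting
        with pytest.warns(UserWarning, match="full panel"):
            res = refit_with_panel([], panel, pheno, ped, ModelSpec(relationship="H"), vc, plan)
        assert np.isfinite(res.mean_accuracy)

    def test_causal_panel_keeps_accuracy(self, setting):
        # restricting G to the causal loci keeps essentially all the
        # predictive information of the full panel
        from sibstep.mixed_model import ModelSpec
        from sibstep.evaluation import cross_validate
        from sibstep.ssgwas import refit_with_panel

        cfg, ped, pheno, panel, truth, vc, plan = setting
        spec = ModelSpec(relationship="H")
        K_inv, logdet_K, _ = make_kinship_inverse(ped, panel, "H")
        full = cross_validate(pheno, ped, K_inv, logdet_K, spec, vc, plan)
        qtl = refit_with_panel(truth.qtl_ids, panel, pheno, ped, spec, vc, plan)
        assert qtl.mean_accuracy >= full.mean_accuracy - 0.02
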