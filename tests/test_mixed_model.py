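"""Mixed-model equations, REML/Gibbs variance components and the LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sibstep import (
    AnimalModel,
    ModelSpec,
    VarianceComponents,
    aireml,
    fit_bivariate,
    gibbs_sampler,
    lrt_c2,
    make_kinship_inverse,
    reml_loglik,
    simulate_pedigree,
    solve_mme,
)
from sibstep.mixed_model import build_design
from sibstep.pedigree import build_A, validate_and_renumber

from conftest import small_config


def dense_restricted_loglik(y, X, ZA, W, sg, sc, se):
    """Independent dense-V oracle for the restricted likelihood."""
    n, p = X.shape
    V = sg * ZA + se * np.eye(n)
    if W is not None:
        V = V + sc * (W @ W.T)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XVX)[1]
        + r @ Vi @ r
        + (n - p) * np.log(2 * np.pi)
    )


@pytest.fixture(scope="module")
def tiny():
    """~170 animals, 3 cohorts: small enough for dense oracles."""
    from sibstep import drop_genes, simulate_phenotypes

    cfg = small_config(seed=21, families_per_generation=(6, 5, 3), offspring_mean=11.0)
    ped = simulate_pedigree(cfg)
    _, truth = drop_genes(ped, cfg)
    pheno = simulate_phenotypes(ped, truth, cfg)
    design = build_design(pheno, ModelSpec(), ped)
    K_inv, logdet_K, _ = make_kinship_inverse(ped)
    y = pheno["tag_weight_g"].to_numpy(float)
    A = build_A(ped)
    Z = design.Z.toarray()
    return ped, pheno, design, K_inv, logdet_K, y, A, Z


class TestBuildDesign:
    def test_column_count_two_gens_three_batches_one_covariate(self):
        ped = validate_and_renumber(
            pd.DataFrame(
                {"animal_id": [f"a{i}" for i in range(6)], "sire_id": "0", "dam_id": "0"}
            )
        )
        data = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(6)],
                "tag_weight_g": np.arange(6.0),
                "generation": ["G0", "G0", "G0", "G1", "G1", "G1"],
                "batch": ["B1", "B2", "B3", "B1", "B2", "B3"],  # crossed, not nested
                "age_d": [150, 161, 170, 155, 166, 149.0],
                "family_id": ["f1", "f1", "f2", "f2", "f3", "f3"],
            }
        )
        d = build_design(data, ModelSpec(), ped)
        assert d.X.shape[1] == 1 + 1 + 2 + 1  # intercept + gen + batch + age

    def test_no_c2_drops_W(self, tiny):
        ped, pheno, *_ = tiny
        d = build_design(pheno, ModelSpec(include_c2=False), ped)
        assert d.W is None

    def test_every_record_maps_to_one_family(self, tiny):
        ped, pheno, design, *_ = tiny
        np.testing.assert_array_equal(np.asarray(design.W.sum(axis=1)).ravel(), 1.0)

    def test_nested_batches_are_aliased_not_fatal(self, tiny):
        # spawning batches are nested within generation in the breeding
        # design, so some batch dummies are exactly collinear
        ped, pheno, design, *_ = tiny
        assert len(design.dropped_aliased) >= 1
        r = np.linalg.matrix_rank(design.X)
        assert r == design.X.shape[1]

    def test_nonfinite_covariate_rejected(self, tiny):
        ped, pheno, *_ = tiny
        bad = pheno.copy()
        bad.loc[bad.index[0], "age_d"] = np.nan
        with pytest.raises(ValueError, match="age_d"):
            build_design(bad, ModelSpec(), ped)


class TestSolveMME:
    def test_matches_dense_gls_oracle(self, tiny):
        ped, pheno, design, K_inv, logdet_K, y, A, Z = tiny
        vc = VarianceComponents(20.0, 25.0, 90.0)
        sol = solve_mme(y, design, K_inv, vc, animal_ids=ped.ids, logdet_K=logdet_K)
        X = design.X
        W = design.W.toarray()
        V = vc.sigma_g * (Z @ A @ Z.T) + vc.sigma_c * (W @ W.T) + vc.sigma_e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = vc.sigma_g * (A @ Z.T) @ (Vi @ (y - X @ beta))
        np.testing.assert_allclose(sol.b.to_numpy(), beta, atol=1e-6)
        np.testing.assert_allclose(sol.u.to_numpy(), u, atol=1e-6)

    def test_shrinkage_limit_small_sigma_g(self, tiny):
        ped, pheno, design, K_inv, logdet_K, y, A, Z = tiny
        vc = VarianceComponents(1e-9, 25.0, 1e-9)
        d2 = build_design(pheno, ModelSpec(include_c2=False), ped)
        sol = solve_mme(y, d2, K_inv, vc, logdet_K=logdet_K)
        assert np.abs(sol.u.to_numpy()).max() < 1e-6
        X = design.X
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(sol.b.to_numpy(), ols, atol=1e-4)


class TestRemlLoglik:
    def test_matches_dense_oracle_and_is_deterministic(self, tiny):
        ped, pheno, design, K_inv, logdet_K, y, A, Z = tiny
        vc = VarianceComponents(18.0, 30.0, 95.0)
        ll = reml_loglik(vc, y, design, K_inv, logdet_K)
        ll2 = reml_loglik(vc, y, design, K_inv, logdet_K)
        assert ll == ll2
        W = design.W.toarray()
        oracle = dense_restricted_loglik(y, design.X, Z @ A @ Z.T, W, 18.0, 95.0, 30.0)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_gradient_matches_numerical_differentiation(self, tiny):
        # the AI-REML score equations against finite differences of the
        # dense-V restricted likelihood
        from scipy import sparse as sp

        from sibstep.mixed_model import MMESystem, _sparse_weighted_trace

        ped, pheno, design, K_inv, logdet_K, y, A, Z = tiny
        sg, sc, se = 20.0, 90.0, 25.0
        sys_ = MMESystem(y, design, K_inv, logdet_K)
        sys_.set_components(VarianceComponents(sg, se, sc))
        sol = sys_.solution()
        Cinv = sys_.inverse_dense()
        Kcsr = sp.csr_matrix(K_inv)
        u = sol[sys_.sl_u]
        c = sol[sys_.sl_c]
        e = y - sys_.M @ sol
        trK = _sparse_weighted_trace(Kcsr, Cinv[sys_.sl_u, sys_.sl_u])
        trC = np.trace(Cinv[sys_.sl_c, sys_.sl_c])
        n, p = sys_.n, sys_.p
        g_g = -0.5 * (sys_.q_u / sg - trK / sg**2 - u @ (Kcsr @ u) / sg**2)
        g_c = -0.5 * (sys_.q_c / sc - trC / sc**2 - c @ c / sc**2)
        trP = (n - p - sys_.q_u - sys_.q_c + trK / sg + trC / sc) / se
        g_e = -0.5 * (trP - e @ e / se**2)

        W = design.W.toarray()
        ZA = Z @ A @ Z.T

        def ll(a, b, r):
            return dense_restricted_loglik(y, design.X, ZA, W, a, b, r)

        h = 1e-4
        assert g_g == pytest.approx((ll(sg + h, sc, se) - ll(sg - h, sc, se)) / (2 * h), rel=1e-4)
        assert g_c == pytest.approx((ll(sg, sc + h, se) - ll(sg, sc - h, se)) / (2 * h), rel=1e-4)
        assert g_e == pytest.approx((ll(sg, sc, se + h) - ll(sg, sc, se - h)) / (2 * h), rel=1e-4)


class TestAiremlSmall:
    def test_balanced_one_way_matches_anova_reml(self):
        # repeated records on unrelated animals: classic one-way layout with
        # closed-form REML sigma_e = MSW, sigma_u = (MSB - MSW) / n
        rng = np.random.default_rng(8)
        s, n = 30, 6
        ped = validate_and_renumber(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(s)], "sire_id": "0", "dam_id": "0"})
        )
        u = rng.normal(0, 3.0, s)
        y = (10 + np.repeat(u, n) + rng.normal(0, 2.0, s * n))
        data = pd.DataFrame(
            {"animal_id": np.repeat([f"a{i}" for i in range(s)], n), "y": y}
        )
        spec = ModelSpec(response="y", fixed_factors=(), covariates=(), include_c2=False)
        design = build_design(data, spec, ped)
        K_inv, logdet_K, _ = make_kinship_inverse(ped)
        vc, _ = aireml(y, design, K_inv, logdet_K, tol=1e-8, gtol=1e-8)
        grp = y.reshape(s, n)
        msw = float(np.sum((grp - grp.mean(axis=1, keepdims=True)) ** 2) / (s * (n - 1)))
        msb = float(n * np.sum((grp.mean(axis=1) - y.mean()) ** 2) / (s - 1))
        assert vc.sigma_e == pytest.approx(msw, rel=1e-5)
        assert vc.sigma_g == pytest.approx((msb - msw) / n, rel=1e-5)

    def test_zero_genetic_variance_hits_boundary_flag(self):
        rng = np.random.default_rng(9)
        s, n = 20, 5
        ped = validate_and_renumber(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(s)], "sire_id": "0", "dam_id": "0"})
        )
        y = 5 + rng.normal(0, 2.0, s * n)  # no animal effect at all
        data = pd.DataFrame({"animal_id": np.repeat([f"a{i}" for i in range(s)], n), "y": y})
        spec = ModelSpec(response="y", fixed_factors=(), covariates=(), include_c2=False)
        design = build_design(data, spec, ped)
        K_inv, logdet_K, _ = make_kinship_inverse(ped)
        vc, _ = aireml(y, design, K_inv, logdet_K)
        assert vc.h2 < 0.02
        assert vc.boundary.get("sigma_g", False) or vc.sigma_g < 0.05


class TestLRT:
    def test_equal_likelihoods(self):
        chi2, p = lrt_c2(-10.0, -10.0)
        assert chi2 == 0.0 and p == 1.0

    def test_known_quantile(self):
        chi2, p = lrt_c2(-8.08, -10.0)  # difference 1.92
        assert chi2 == pytest.approx(3.84)
        assert p == pytest.approx(0.05, abs=0.002)

    def test_reversed_likelihoods_clip_to_zero(self):
        with pytest.warns(UserWarning, match="clipped"):
            chi2, p = lrt_c2(-10.0, -9.0)
        assert chi2 == 0.0 and p == 1.0

    def test_boundary_mixture_halves_p(self):
        _, p_plain = lrt_c2(-8.08, -10.0)
        _, p_mix = lrt_c2(-8.08, -10.0, boundary_mixture=True)
        assert p_mix == pytest.approx(p_plain / 2)

    def test_type_one_error_not_inflated_under_null(self):
        # simulate sigma_c = 0, test the c2 term; df=1 chi-square at the
        # boundary is conservative, so rejections stay below nominal 5%
        rejections = 0
        reps = 60
        for seed in range(reps):
            cfg = small_config(
                seed=seed + 1000, families_per_generation=(5, 4, 3),
                offspring_min=5, offspring_mean=8.0, sigma_c=0.0,
            )
            from sibstep import drop_genes, simulate_phenotypes

            ped = simulate_pedigree(cfg)
            _, truth = drop_genes(ped, cfg)
            pheno = simulate_phenotypes(ped, truth, cfg)
            K_inv, logdet_K, _ = make_kinship_inverse(ped)
            y = pheno["tag_weight_g"].to_numpy(float)
            vc_f, sol_f = aireml(
                y, build_design(pheno, ModelSpec(), ped), K_inv, logdet_K,
                tol=1e-5, gtol=1e-2,
            )
            vc_r, sol_r = aireml(
                y, build_design(pheno, ModelSpec(include_c2=False), ped), K_inv, logdet_K,
                tol=1e-5, gtol=1e-2,
            )
            _, p = lrt_c2(sol_f.loglik, sol_r.loglik)
            rejections += p < 0.05
        assert rejections / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestGibbs:
    def test_fixed_mean_posterior_matches_sample_mean(self):
        rng = np.random.default_rng(5)
        s = 40
        ped = validate_and_renumber(
            pd.DataFrame({"animal_id": [f"a{i}" for i in range(s)], "sire_id": "0", "dam_id": "0"})
        )
        y = 7.0 + rng.normal(0, 1.0, s)
        data = pd.DataFrame({"animal_id": [f"a{i}" for i in range(s)], "y": y})
        spec = ModelSpec(response="y", fixed_factors=(), covariates=(), include_c2=False)
        design = build_design(data, spec, ped)
        K_inv, logdet_K, _ = make_kinship_inverse(ped)
        res = gibbs_sampler(y, design, K_inv, logdet_K, total_cycles=3000, burn_in=500, seed=1)
        mu_post = res.solution.b["intercept"]
        assert mu_post == pytest.approx(y.mean(), abs=0.15)

    def test_same_seed_reproduces_draws(self, tiny):
        ped, pheno, design, K_inv, logdet_K, y, *_ = tiny
        a = gibbs_sampler(y, design, K_inv, logdet_K, total_cycles=300, burn_in=50, seed=3)
        b = gibbs_sampler(y, design, K_inv, logdet_K, total_cycles=300, burn_in=50, seed=3)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_chain_length_validation(self, tiny):
        ped, pheno, design, K_inv, logdet_K, y, *_ = tiny
        with pytest.raises(ValueError, match="burn_in"):
            gibbs_sampler(y, design, K_inv, logdet_K, total_cycles=100, burn_in=100)


class TestBivariate:
    SPEC = ModelSpec(traits=("tag_weight_g", "survival_time_d"))

    def make_data(self, seed, rg, identical=False):
        from sibstep import drop_genes, simulate_phenotypes

        # both traits moderately heritable with small family variance so
        # the genetic correlation carries usable information at this size
        cfg = small_config(
            seed=seed, families_per_generation=(10, 9, 5), offspring_mean=10.0,
            sigma_g=60.0, sigma_c=15.0, sigma_e=75.0,
            survival_sigma_g=40.0, survival_sigma_c=10.0, survival_sigma_e=50.0,
            genetic_correlation=rg,
        )
        ped = simulate_pedigree(cfg)
        _, truth = drop_genes(ped, cfg)
        pheno = simulate_phenotypes(ped, truth, cfg)
        if identical:
            # re-measured first trait: same genetics, small independent error
            noise = np.random.default_rng(0).normal(0, 2.0, len(pheno))
            pheno = pheno.assign(survival_time_d=pheno["tag_weight_g"] + noise)
        K_inv, logdet_K, _ = make_kinship_inverse(ped)
        return cfg, ped, pheno, K_inv, logdet_K

    def true_blocks(self, cfg):
        g12 = cfg.genetic_correlation * np.sqrt(cfg.sigma_g * cfg.survival_sigma_g)
        G0 = np.array([[cfg.sigma_g, g12], [g12, cfg.survival_sigma_g]])
        C0 = np.diag([cfg.sigma_c, cfg.survival_sigma_c])
        R0 = np.diag([cfg.sigma_e, cfg.survival_sigma_e])
        return G0, C0, R0

    def test_identical_traits_give_unit_genetic_correlation(self):
        _, ped, pheno, K_inv, logdet_K = self.make_data(31, 0.3, identical=True)
        vc, _ = fit_bivariate(pheno, self.SPEC, ped, K_inv, logdet_K)
        assert vc.genetic_correlation > 0.9

    @pytest.mark.parametrize("rg", [0.0, 0.3])
    def test_genetic_correlation_recovery(self, rg):
        # per-replicate r_g estimates are wide at this scale, so the check
        # is two-fold: the optimizer must reach at least the likelihood of
        # the true covariance blocks, and the mean estimate must sit
        # within its own Monte-Carlo error of the simulated truth
        from sibstep.mixed_model import BivariateModel

        ests = []
        for seed in range(41, 46):
            cfg, ped, pheno, K_inv, logdet_K = self.make_data(seed, rg)
            model = BivariateModel(pheno, self.SPEC, ped, K_inv, logdet_K)
            vc, sol = model.fit_reml()
            ll_truth = model.loglik(*self.true_blocks(cfg))
            assert sol.loglik >= ll_truth - 1e-4
            ests.append(vc.genetic_correlation)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - rg) <= max(0.1, 2.58 * se)

    def test_missing_second_trait_records_are_handled(self):
        _, ped, pheno, K_inv, logdet_K = self.make_data(51, 0.3)
        pheno = pheno.copy()
        pheno.loc[pheno.index[::3], "survival_time_d"] = np.nan
        vc, sol = fit_bivariate(pheno, self.SPEC, ped, K_inv, logdet_K)
        assert np.isfinite(vc.genetic_correlation)
        assert len(sol.u) == ped.n_animals

    def test_loglik_matches_dense_stacked_oracle(self):
        # independent dense-V evaluation of the two-trait restricted
        # likelihood, with missing trait-2 records
        from sibstep.mixed_model import BivariateModel

        _, ped, pheno, K_inv, logdet_K = self.make_data(61, 0.2)
        pheno = pheno.copy()
        pheno.loc[pheno.index[::4], "survival_time_d"] = np.nan
        m = BivariateModel(pheno, self.SPEC, ped, K_inv, logdet_K)
        G0 = np.array([[20.0, 5.0], [5.0, 18.0]])
        C0 = np.array([[90.0, 10.0], [10.0, 14.0]])
        R0 = np.array([[22.0, 6.0], [6.0, 60.0]])
        A = build_A(ped)
        Z1, Z2 = m.d1.Z.toarray(), m.d2.Z.toarray()
        W1, W2 = m.d1.W.toarray(), m.W2.toarray()
        y1, y2 = m.y1, m.y2
        X = np.zeros((len(y1) + len(y2), m.p1 + m.p2))
        X[: len(y1), : m.p1] = m.d1.X
        X[len(y1):, m.p1:] = m.d2.X
        P = np.zeros((len(y1), len(y2)))
        P[m.pair_pos, np.arange(len(y2))] = 1.0
        V11 = G0[0, 0] * Z1 @ A @ Z1.T + C0[0, 0] * W1 @ W1.T + R0[0, 0] * np.eye(len(y1))
        V22 = G0[1, 1] * Z2 @ A @ Z2.T + C0[1, 1] * W2 @ W2.T + R0[1, 1] * np.eye(len(y2))
        V12 = G0[0, 1] * Z1 @ A @ Z2.T + C0[0, 1] * W1 @ W2.T + R0[0, 1] * P
        V = np.block([[V11, V12], [V12.T, V22]])
        y = np.concatenate([y1, y2])
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        beta = np.linalg.solve(XVX, X.T @ Vi @ y)
        r = y - X @ beta
        n, p = X.shape
        oracle = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XVX)[1]
            + r @ Vi @ r
            + (n - p) * np.log(2 * np.pi)
        )
        assert m.loglik(G0, C0, R0) == pytest.approx(oracle, abs=1e-7)


class TestAnimalModelEstimator:
    def test_fit_predict_and_sklearn_conventions(self, tiny):
        ped, pheno, *_ = tiny
        from sklearn.base import clone

        model = AnimalModel(pedigree=ped, varcomp=VarianceComponents(20.0, 25.0, 90.0))
        cloned = clone(model)  # sklearn get_params/set_params round-trip
        cloned.fit(pheno)
        assert hasattr(cloned, "varcomp_") and hasattr(cloned, "solution_")
        ebv = cloned.predict(ped.ids[:5])
        np.testing.assert_allclose(ebv, cloned.solution_.u.to_numpy()[:5])

    def test_pblup_equals_ssgblup_with_no_genotyped_animals(self, tiny):
        ped, pheno, *_ = tiny
        vc = VarianceComponents(20.0, 25.0, 90.0)
        a = AnimalModel(pedigree=ped, relationship="A", varcomp=vc).fit(pheno)
        h = AnimalModel(pedigree=ped, genotypes=None, relationship="H", varcomp=vc).fit(pheno)
        pd.testing.assert_series_equal(a.solution_.u, h.solution_.u)
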