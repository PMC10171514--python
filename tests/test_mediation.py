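"""Single-mediator and regularized multi-mediator mediation models."""

import numpy as np
import pytest

from neuromediate import mediation as md


def standardize(v):
    v = np.asarray(v, float)
    return (v - v.mean(axis=0)) / v.std(axis=0, ddof=1)


def simulate_mediation(seed, n=1000, p=50, n_true=1, a=0.5, b=0.5, c_prime=0.1):
    """Standardized (x, M, y) with the first n_true mediators active."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    M = np.empty((n, p))
    for j in range(p):
        aj = a if j < n_true else 0.0
        M[:, j] = aj * x + np.sqrt(1 - aj**2) * rng.normal(size=n)
    bv = np.zeros(p)
    bv[:n_true] = b
    y = M @ bv + c_prime * x + rng.normal(size=n)
    return standardize(x), standardize(M), standardize(y)


class TestMediateSingle:
    def test_handworked_four_points(self):
        # x=[1,2,3,4], m=[2,3,7,8], y=m: slope of m on x is 11/5 = 2.2 by the
        # normal equations; y==m makes b=1 and c'=0 exactly
        x = [1, 2, 3, 4]
        m = [2, 3, 7, 8]
        res = md.mediate_single(x, m, m)
        assert res.a == pytest.approx(2.2, abs=1e-12)
        assert res.b == pytest.approx(1.0, abs=1e-12)
        assert res.c_prime == pytest.approx(0.0, abs=1e-10)
        assert res.indirect == pytest.approx(2.2, abs=1e-10)
        assert res.total == pytest.approx(2.2, abs=1e-12)

    def test_total_equals_direct_plus_indirect(self, rng):
        for _ in range(10):
            n = 60
            x = rng.normal(size=n)
            m = 0.4 * x + rng.normal(size=n)
            y = 0.3 * m - 0.2 * x + rng.normal(size=n)
            cov = rng.normal(size=(n, 3))
            res = md.mediate_single(x, m, y, covariates=cov)
            assert res.total == pytest.approx(res.c_prime + res.indirect, abs=1e-10)

    def test_null_indirect_centered_on_zero(self):
        estimates = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=300)
            m = rng.normal(size=300)  # independent of x
            y = 0.5 * m + rng.normal(size=300)
            estimates.append(md.mediate_single(x, m, y).indirect)
        assert abs(np.mean(estimates)) < 0.02

    def test_collinear_mediator_rejected(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            md.mediate_single(x, 2 * x, rng.normal(size=50))

    def test_bootstrap_ci_covers_point_estimate(self, rng):
        x = rng.normal(size=200)
        m = 0.5 * x + rng.normal(size=200)
        y = 0.5 * m + rng.normal(size=200)
        res = md.mediate_single(x, m, y, n_boot=200, seed=1)
        lo, hi = res.ci_indirect
        assert lo < res.indirect < hi

    def test_robust_se_option_changes_uncertainty_not_paths(self, rng):
        x = rng.normal(size=150)
        m = 0.4 * x + rng.normal(size=150)
        y = 0.3 * m + rng.normal(size=150) * (1 + np.abs(x))
        plain = md.mediate_single(x, m, y)
        robust = md.mediate_single(x, m, y, robust=True)
        assert robust.a == pytest.approx(plain.a)
        assert robust.indirect == pytest.approx(plain.indirect)
        assert robust.se["c_prime"] != pytest.approx(plain.se["c_prime"], rel=1e-6)


class TestRegularizedMediation:
    def test_pure_noise_selects_nothing(self):
        hits = 0
        for seed in range(20):
            x, M, y = simulate_mediation(seed, n=500, p=50, n_true=0, c_prime=0.0)
            cfg = md.RegularizedMediationConfig(k_folds=10, cv_seed=seed)
            res = md.regularized_mediation(x, M, y, cfg)
            hits += len(res.selected)
        # a handful of spurious selections over 20 null runs is tolerable;
        # systematic selection is not
        assert hits <= 10

    def test_single_true_mediator_recovered_and_debiased(self):
        x, M, y = simulate_mediation(3, n=1000, p=50, n_true=1, a=0.5, b=0.5)
        cfg = md.RegularizedMediationConfig(k_folds=10, cv_seed=3)
        res = md.regularized_mediation(x, M, y, cfg)
        assert "m0" in res.selected
        refit_ab = res.refit.paths["m0"].indirect
        # standardizing y rescales the structural indirect effect:
        # sd(y) = sqrt(b^2 + c'^2 + 2abc' + 1) = sqrt(1.31), so the
        # population value is 0.25/1.1446 = 0.2184
        assert refit_ab == pytest.approx(0.25 / np.sqrt(1.31), abs=0.05)
        # penalized product is biased toward zero relative to the refit
        assert abs(res.indirect[0]) <= abs(refit_ab) + 1e-9

    def test_small_product_below_threshold_not_selected(self):
        # a mediator whose penalized product is 0.0005 sits under the 0.001
        # default threshold by construction of the selection rule
        res = md.RegularizedMediationResult(
            mediator_ids=["m0"], a=np.array([0.05]), b=np.array([0.01]),
            indirect=np.array([0.0005]), c_prime_penalized=0.0, selected=[],
            a_nonzero=[], b_nonzero=[], penalty_a=0.1, penalty_b=0.1,
            refit=None, n=100,
        )
        cfg = md.RegularizedMediationConfig()
        assert abs(res.indirect[0]) <= cfg.mediation_threshold

    def test_requires_standardized_inputs(self, rng):
        x = rng.normal(size=200) * 3  # sd far from 1
        M = standardize(rng.normal(size=(200, 5)))
        y = standardize(rng.normal(size=200))
        with pytest.raises(ValueError, match="standardized"):
            md.regularized_mediation(x, M, y, md.RegularizedMediationConfig(k_folds=5))

    def test_penalty_zero_equals_ols(self):
        x, M, y = simulate_mediation(5, n=300, p=8, n_true=2, a=0.4, b=0.3)
        cfg = md.RegularizedMediationConfig(k_folds=5, penalty_override=0.0)
        res = md.regularized_mediation(x, M, y, cfg)
        import statsmodels.api as sm

        ols_b = sm.OLS(y, sm.add_constant(np.column_stack([M, x]))).fit().params[1:9]
        np.testing.assert_allclose(res.b, ols_b, atol=1e-6)
        ols_a = np.array(
            [sm.OLS(M[:, j], sm.add_constant(x)).fit().params[1] for j in range(8)]
        )
        np.testing.assert_allclose(res.a, ols_a, atol=1e-8)

    def test_huge_penalty_empties_selection(self):
        x, M, y = simulate_mediation(6, n=300, p=8, n_true=2, a=0.4, b=0.4)
        cfg = md.RegularizedMediationConfig(k_folds=5, penalty_override=1e4)
        res = md.regularized_mediation(x, M, y, cfg)
        np.testing.assert_allclose(res.a, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.b, 0.0, atol=1e-12)
        assert res.selected == []

    def test_column_order_invariance(self):
        x, M, y = simulate_mediation(7, n=400, p=10, n_true=2, a=0.4, b=0.4)
        cfg = md.RegularizedMediationConfig(k_folds=8, cv_seed=11)
        res = md.regularized_mediation(x, M, y, cfg)
        perm = np.random.default_rng(0).permutation(10)
        ids = [f"m{j}" for j in perm]
        res_p = md.regularized_mediation(x, M[:, perm], y, cfg, mediator_ids=ids)
        assert set(res.selected) == set(res_p.selected)
        np.testing.assert_allclose(res.indirect[perm], res_p.indirect, atol=1e-5)

    def test_reversed_path_a_formulation_runs(self):
        x, M, y = simulate_mediation(8, n=300, p=6, n_true=1, a=0.5, b=0.5)
        cfg = md.RegularizedMediationConfig(
            k_folds=5, cv_seed=2, path_a_direction="x_on_mediators"
        )
        res = md.regularized_mediation(x, M, y, cfg)
        assert "m0" in res.selected
        # the refit makes final effects insensitive to the formulation;
        # population value is 0.25/sd(y) = 0.2184 (see the recovery test)
        assert res.refit.paths["m0"].indirect == pytest.approx(0.25 / np.sqrt(1.31), abs=0.06)

    def test_k_folds_exceeding_n_rejected(self, rng):
        x = standardize(rng.normal(size=30))
        M = standardize(rng.normal(size=(30, 3)))
        y = standardize(rng.normal(size=30))
        with pytest.raises(ValueError, match="k_folds"):
            md.regularized_mediation(x, M, y, md.RegularizedMediationConfig(k_folds=80))


class TestRefitSelected:
    def test_single_mediator_equals_mediate_single(self, rng):
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.2 * x + rng.normal(size=n)
        single = md.mediate_single(x, m, y)
        refit = md.refit_selected(x, m, y, mediator_ids=["m"])
        assert refit.paths["m"].a == pytest.approx(single.a, abs=1e-10)
        assert refit.paths["m"].b == pytest.approx(single.b, abs=1e-10)
        assert refit.c_prime == pytest.approx(single.c_prime, abs=1e-10)

    def test_orthogonal_mediators_keep_marginal_b(self, rng):
        n = 5000
        x = rng.normal(size=n)
        m1 = rng.normal(size=n)
        m2 = rng.normal(size=n)
        # orthogonalize m2 against m1 and x exactly
        X = np.column_stack([np.ones(n), m1, x])
        m2 = m2 - X @ np.linalg.lstsq(X, m2, rcond=None)[0]
        m1 = m1 - np.column_stack([np.ones(n), x]) @ np.linalg.lstsq(
            np.column_stack([np.ones(n), x]), m1, rcond=None
        )[0]
        y = 0.3 * m1 - 0.2 * m2 + rng.normal(size=n)
        joint = md.refit_selected(x, np.column_stack([m1, m2]), y, mediator_ids=["m1", "m2"])
        b1_single = md.mediate_single(x, m1, y).b
        b2_single = md.mediate_single(x, m2, y).b
        assert joint.paths["m1"].b == pytest.approx(b1_single, abs=1e-10)
        assert joint.paths["m2"].b == pytest.approx(b2_single, abs=1e-10)

    def test_full_selection_matches_direct_joint_ols(self, rng):
        import statsmodels.api as sm

        n, p = 100, 3
        x = rng.normal(size=n)
        M = rng.normal(size=(n, p))
        y = M @ [0.2, -0.1, 0.3] + 0.1 * x + rng.normal(size=n)
        refit = md.refit_selected(x, M, y, mediator_ids=["a", "b", "c"])
        ols = sm.OLS(y, sm.add_constant(np.column_stack([M, x]))).fit()
        for j, mid in enumerate(["a", "b", "c"]):
            assert refit.paths[mid].b == pytest.approx(ols.params[1 + j], abs=1e-10)
        assert refit.c_prime == pytest.approx(ols.params[4], abs=1e-10)

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty selection"):
            md.refit_selected(rng.normal(size=10), np.empty((10, 0)), rng.normal(size=10))


class TestSelectionMetrics:
    def test_perfect_recovery(self):
        cands = [f"m{j}" for j in range(10)]
        out = md.selection_metrics(["m0", "m1"], ["m0", "m1"], cands)
        assert out["sensitivity"] == 1.0
        assert out["fdr"] == 0.0
        assert out["specificity"] == 1.0

    def test_empty_selection_with_truth_present(self):
        out = md.selection_metrics([], ["m0"], ["m0", "m1"])
        assert out["sensitivity"] == 0.0
        assert out["fdr"] == 0.0

    def test_random_half_selection_fdr_expectation(self, rng):
        # 10% of 200 candidates are true; selecting a random half gives an
        # expected FDR of 0.9 (combinatorial expectation)
        cands = [f"m{j}" for j in range(200)]
        truth = cands[:20]
        fdrs = []
        for _ in range(200):
            sel = list(rng.choice(cands, size=100, replace=False))
            fdrs.append(md.selection_metrics(sel, truth, cands)["fdr"])
        assert np.mean(fdrs) == pytest.approx(0.9, abs=0.02)

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            md.selection_metrics(["zzz"], ["m0"], ["m0"])
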