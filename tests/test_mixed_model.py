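"""The correlated direct/social variance-component model."""

import numpy as np
import pytest
from scipy.optimize import minimize

import sgekit.mixed_model as mm
from sgekit import (
    CageDesign,
    ComponentBasis,
    VarianceComponents,
    build_covariance,
    build_reference_design,
    fisher_se,
    fit_reml,
    lrt_sge,
    scenario,
    variance_partition,
)
from sgekit.simulate import PhenotypeSimulator, PopulationSpec, simulate_population


class TestCageDesign:
    def test_indicator_invariants(self):
        cages = CageDesign(ids=list("abcdef"), cages=["x", "x", "x", "y", "y", "z"])
        Z, W = cages.Z, cages.W
        assert np.all(np.diag(Z) == 0)
        assert np.array_equal(Z, Z.T)
        assert np.array_equal(W.sum(axis=1), np.ones(6))
        np.testing.assert_array_equal(Z, W @ W.T - np.eye(6))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            CageDesign(ids=["a", "a"], cages=["x", "y"])


class TestVarianceComponents:
    def test_proportions_roundtrip(self):
        vc = VarianceComponents.from_proportions(0.15, 0.04, 0.5, 0.52, 0.0, 0.0, 0.22)
        assert vc.rho_ads == pytest.approx(0.5)
        assert vc.sigma_ADS == pytest.approx(0.5 * np.sqrt(0.15 * 0.04))

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(sigma2_AD=0.1, sigma_ADS=0.2, sigma2_AS=0.1)


class TestBuildCovariance:
    def test_pure_direct_environment_is_identity(self, small_design):
        vc = VarianceComponents(sigma2_ED=1.0)
        V = build_covariance(vc, small_design.basis)
        np.testing.assert_allclose(V, np.eye(small_design.cages.n), atol=1e-12)

    def test_cage_only_block_structure(self):
        cages = CageDesign(ids=list("abcd"), cages=["x", "x", "y", "y"])
        basis = ComponentBasis.from_design(np.eye(4), cages)
        V = build_covariance(VarianceComponents(sigma2_C=1.0), basis)
        assert V[0, 1] == pytest.approx(V[0, 0])  # constant within cage
        assert V[0, 2] == 0.0  # zero across cages

    def test_full_set_positive_definite(self, small_design, average_vc):
        V = build_covariance(average_vc, small_design.basis)
        assert np.linalg.eigvalsh(V)[0] > 0


class TestRemlFit:
    def test_gradient_matches_finite_differences(self, small_design, rng):
        basis = small_design.basis
        n = basis.n
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        logdetXtX = np.linalg.slogdet(X.T @ X)[1]
        blocks, _ = mm._make_blocks(mm.FULL_COMPONENTS, basis, basis.constant_cage_size)
        npar = sum(b.n_par for b in blocks)
        th = rng.uniform(0.1, 0.7, size=npar)
        _, g = mm._reml_eval(th, blocks, basis, X, y, logdetXtX)
        for i in range(npar):
            e = np.zeros(npar)
            e[i] = 1e-6
            fp = mm._reml_eval(th + e, blocks, basis, X, y, logdetXtX)[0]
            fmi = mm._reml_eval(th - e, blocks, basis, X, y, logdetXtX)[0]
            assert g[i] == pytest.approx((fp - fmi) / 2e-6, rel=1e-4, abs=1e-6)

    def test_null_structure_singleton_cages(self):
        """Unrelated mice in singleton cages: everything collapses to the
        direct environmental variance."""
        pop = simulate_population(
            PopulationSpec(n_families=60, family_size=1, n_loci=10, generations=0),
            seed=2,
        )
        n = len(pop.cohort)
        cages = CageDesign(ids=pop.cohort, cages=[f"c{i}" for i in range(n)])
        basis = ComponentBasis.from_design(np.eye(n), cages)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(n)
        fit = fit_reml(y, np.ones((n, 1)), basis)
        assert fit.components == ("ED",)
        assert fit.coefficients["ED"] == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_optimum_matches_generic_optimizer(self, rng):
        """Restricted likelihood at the reported optimum agrees with an
        independent slogdet-based implementation maximized generically."""
        design = build_reference_design(n_families=14, family_size=3, n_loci=200,
                                        seed=21)
        basis = design.basis
        n = basis.n
        vc = scenario("average")
        y = PhenotypeSimulator(vc, design.scaled, design.cages).draw(seed=3)[:, 0]
        X = np.ones((n, 1))
        fit = fit_reml(y, X, basis)

        names = list(fit.coefficients)
        Ks = [basis.K[nm] for nm in names]
        p = X.shape[1]
        logdetXtX = np.linalg.slogdet(X.T @ X)[1]

        def nll_oracle(theta):
            blocks, _ = mm._make_blocks(fit.components, basis,
                                        basis.constant_cage_size)
            coeffs, _, _ = mm._block_jacobian(theta, blocks)
            V = sum(c * K for c, K in zip(coeffs, Ks))
            sign, logdetV = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e9
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            _, logdetXVX = np.linalg.slogdet(XtViX)
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            return 0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetXVX
                          - logdetXtX + r @ Vi @ r)

        best = np.inf
        for s in range(4):
            th0 = np.abs(rng.normal(0.4, 0.2, size=5))
            res = minimize(nll_oracle, th0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-4)

    def test_restricted_ll_invariances(self, small_design, rng):
        """Translation of y and recoding of the fixed-effect basis leave the
        restricted likelihood unchanged."""
        basis = small_design.basis
        n = basis.n
        y = PhenotypeSimulator(scenario("average"), small_design.scaled,
                               small_design.cages).draw(seed=5)[:, 0]
        x2 = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x2])
        f0 = fit_reml(y, X, basis)
        f_shift = fit_reml(y + 11.3, X, basis)
        T = np.array([[2.0, 0.5], [0.0, -1.5]])  # invertible recoding
        f_recode = fit_reml(y, X @ T, basis)
        assert f_shift.loglik == pytest.approx(f0.loglik, abs=1e-4)
        assert f_recode.loglik == pytest.approx(f0.loglik, abs=1e-4)

    def test_rank_deficient_X_rejected(self, small_design):
        n = small_design.basis.n
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            fit_reml(np.zeros(n), X, small_design.basis)


class TestVariancePartition:
    def test_pure_direct_genetics_is_hundred_percent(self, small_design):
        fit = mm.FitResult(coefficients={"AD": 1.0}, beta=np.zeros(1), loglik=0.0,
                           converged=True, n=small_design.basis.n, p=1,
                           components=("AD",), collapsed=False)
        parts = variance_partition(fit, small_design.basis)
        assert parts["AD"] == pytest.approx(100.0)

    def test_matches_hand_ratio(self, small_design):
        from sgekit import sample_var
        coeffs = {"AD": 0.2, "AS": 0.1, "ED": 0.6, "C": 0.15}
        fit = mm.FitResult(coefficients=coeffs, beta=np.zeros(1), loglik=0.0,
                           converged=True, n=small_design.basis.n, p=1,
                           components=tuple(coeffs), collapsed=False)
        parts = variance_partition(fit, small_design.basis)
        total = sum(c * sample_var(small_design.basis.K[k]) for k, c in coeffs.items())
        assert parts["AS"] == pytest.approx(100 * 0.1 * sample_var(
            small_design.basis.K["AS"]) / total)


class TestFisherInformation:
    def test_se_calibrated_against_replicate_scatter(self):
        """Across replicates, the empirical SD of the social genetic variance
        estimate agrees with the mean reported standard error."""
        design = build_reference_design(n_families=50, family_size=3, n_loci=400,
                                        seed=31)
        vc = scenario("grid", sge=0.2)
        sim = PhenotypeSimulator(vc, design.scaled, design.cages)
        Y = sim.draw(seed=9, n_reps=60)
        X = np.ones((design.basis.n, 1))
        est, ses = [], []
        for r in range(60):
            fit = fit_reml(Y[:, r], X, design.basis, compute_se=True)
            if fit.se and "AS" in fit.se:
                est.append(fit.coefficients["AS"])
                ses.append(fit.se["AS"])
        assert len(est) > 50
        sd = np.std(est, ddof=1)
        assert np.mean(ses) == pytest.approx(sd, rel=0.3)

    def test_expected_information_matches_mc_hessian(self):
        """The expected information equals the Monte-Carlo average of
        finite-difference Hessians of the restricted likelihood over fresh
        data draws at the same parameters."""
        design = build_reference_design(n_families=12, family_size=3, n_loci=100,
                                        seed=41)
        basis = design.basis
        n = basis.n
        coeffs = {"AD": 0.3, "ED": 0.7}
        X = np.ones((n, 1))
        V = basis.assemble(coeffs)
        L = np.linalg.cholesky(V)
        fit = mm.FitResult(coefficients=coeffs, beta=np.zeros(1), loglik=0.0,
                           converged=True, n=n, p=1, components=("AD", "ED"),
                           collapsed=False)
        se_info = fisher_se(fit, basis, X)
        # MC-averaged observed information via finite differences of the
        # coefficient-space restricted likelihood
        names = ["AD", "ED"]
        Ks = [basis.K[nm] for nm in names]
        logdetXtX = np.linalg.slogdet(X.T @ X)[1]

        def nll(c, y):
            Vc = c[0] * Ks[0] + c[1] * Ks[1]
            sign, logdetV = np.linalg.slogdet(Vc)
            Vi = np.linalg.inv(Vc)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            return 0.5 * ((n - 1) * np.log(2 * np.pi) + logdetV
                          + np.linalg.slogdet(XtViX)[1] - logdetXtX + r @ Vi @ r)

        rng = np.random.default_rng(17)
        c0 = np.array([0.3, 0.7])
        h = 1e-4
        H_acc = np.zeros((2, 2))
        reps = 300
        for _ in range(reps):
            y = L @ rng.standard_normal(n)
            for i in range(2):
                for j in range(2):
                    ei = np.eye(2)[i] * h
                    ej = np.eye(2)[j] * h
                    H_acc[i, j] += (nll(c0 + ei + ej, y) - nll(c0 + ei - ej, y)
                                    - nll(c0 - ei + ej, y) + nll(c0 - ei - ej, y)) / (4 * h * h)
        info_mc = H_acc / reps
        cov_mc = np.linalg.inv(info_mc)
        assert se_info["AD"] == pytest.approx(np.sqrt(cov_mc[0, 0]), rel=0.15)
        assert se_info["ED"] == pytest.approx(np.sqrt(cov_mc[1, 1]), rel=0.15)


class TestLrt:
    def test_zero_statistic_gives_p_one(self, small_design):
        """On data carrying no social signal the statistic can hit the
        boundary; p must then be exactly 1 and never exceed it."""
        n = small_design.basis.n
        rng = np.random.default_rng(12)
        vc = VarianceComponents(sigma2_ED=1.0)
        y = PhenotypeSimulator(vc, small_design.scaled, small_design.cages).draw(
            seed=13)[:, 0]
        p, full, null = lrt_sge(y, np.ones((n, 1)), small_design.basis)
        assert 0.0 <= p <= 1.0
        stat = 2 * (full.loglik - null.loglik)
        if stat <= 1e-8:
            assert p == 1.0

    def test_power_under_strong_social_signal(self, reference_design):
        """With 27% social genetic variance in a 600-mouse cohort the test
        rejects in the vast majority of replicates."""
        vc = scenario("high-sge")
        sim = PhenotypeSimulator(vc, reference_design.scaled, reference_design.cages)
        n_reps = 25
        Y = sim.draw(seed=19, n_reps=n_reps)
        X = np.ones((reference_design.basis.n, 1))
        rejections = sum(
            lrt_sge(Y[:, r], X, reference_design.basis)[0] < 0.05
            for r in range(n_reps)
        )
        assert rejections >= 20  # >= 80% observed at 25 replicates
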