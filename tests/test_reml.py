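"""Model assembly, EM-REML behaviour, BLUPs and derived quantities."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crossblup import (
    CrossbredGBLUP,
    SimConfig,
    backsolve_snp_variances,
    blup_solutions,
    build_model,
    build_relationships,
    em_reml,
    genotypic_correlations,
    qc_filter,
    simulate,
)
from crossblup.reml import ComponentEstimates, _Workspace

from conftest import make_geno


def tiny_phenotypes():
    return pd.DataFrame({
        "individual_id": ["i0", "i1", "i2"],
        "population": ["P1", "P2", "F1"],
        "phenotype": [1.0, 2.0, 3.0],
    })


def tiny_geno():
    rng = np.random.default_rng(2)
    return make_geno(rng.choice([0.0, 1.0, 2.0], size=(3, 30)),
                     pops=["P1", "P2", "F1"])


def dummy_estimates(G_o, D_o, perm, resid, tZ=1.0, tW=1.0, pops=("P1", "P2", "F1"),
                    ai_cov=None, labels=()):
    P = len(pops)
    return ComponentEstimates(
        populations=list(pops), G_o=np.asarray(G_o, float),
        D_o=np.asarray(D_o, float), perm_env=np.asarray(perm, float),
        residual=np.asarray(resid, float), beta=np.zeros(1), fixed_names=["mu"],
        se_G_o=np.full((P, P), np.nan), se_D_o=np.full((P, P), np.nan),
        se_perm_env=np.full(P, np.nan), se_residual=np.full(P, np.nan),
        ai_matrix=None, ai_cov=ai_cov, param_labels=list(labels),
        converged=True, n_iter=0, loglik_trace=np.zeros(1),
        tZ=tZ, tW=tW, n_markers=10,
    )


class TestBuildModel:
    def test_smallest_valid_model(self):
        md = build_model(tiny_phenotypes(), tiny_geno(),
                         include_homozygosity=False)
        assert md.n_individuals == 3 and md.n_records == 3
        assert md.populations == ["P1", "P2", "F1"]
        assert md.fixed_names == ["mu:P1", "mu:P2", "mu:F1"]
        np.testing.assert_array_equal(md.rec_ind, [0, 1, 2])

    def test_repeated_records_share_individual(self):
        phen = pd.concat([tiny_phenotypes()] * 4, ignore_index=True)
        md = build_model(phen, tiny_geno(), include_homozygosity=False)
        assert md.n_individuals == 3 and md.n_records == 12
        assert len(np.unique(md.rec_ind)) == 3

    def test_unknown_individual_is_an_error(self):
        phen = tiny_phenotypes()
        phen.loc[0, "individual_id"] = "ghost"
        with pytest.raises(ValueError, match="without genotypes"):
            build_model(phen, tiny_geno())

    def test_population_mismatch_is_an_error(self):
        phen = tiny_phenotypes()
        phen.loc[0, "population"] = "P2"
        with pytest.raises(ValueError, match="do not match"):
            build_model(phen, tiny_geno())

    def test_homozygosity_columns_present(self):
        # needs within-population F_Ho variation, so two individuals per pop
        rng = np.random.default_rng(12)
        pops = ["P1", "P1", "P2", "P2", "F1", "F1"]
        geno = make_geno(rng.choice([0.0, 1.0, 2.0], size=(6, 40)), pops=pops)
        phen = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(6)],
            "population": pops,
            "phenotype": np.arange(6.0),
        })
        md = build_model(phen, geno)
        assert [n for n in md.fixed_names if n.startswith("F_Ho")] == \
            ["F_Ho:P1", "F_Ho:P2", "F_Ho:F1"]

    def test_confounded_fixed_effects_reported(self):
        phen = tiny_phenotypes()
        phen["dup"] = phen["population"]  # aliases the population means
        with pytest.raises(ValueError, match="rank deficient"):
            build_model(phen, tiny_geno(), fixed_effects=("dup",),
                        include_homozygosity=False)


class TestBacksolve:
    def test_simple_division(self):
        est = dummy_estimates(np.diag([2.0, 1.0, 3.0]), np.zeros((3, 3)),
                              np.ones(3), np.ones(3), tZ=4.0, tW=2.0)
        sv = backsolve_snp_variances(est)
        assert sv.sigma2_a[0] == pytest.approx(0.5)
        np.testing.assert_allclose(sv.sigma2_d, 0.0)

    def test_zero_scale_is_an_error(self):
        est = dummy_estimates(np.eye(3), np.eye(3), np.ones(3), np.ones(3))
        with pytest.raises(ValueError, match="positive"):
            backsolve_snp_variances(est, tZ=0.0)


class TestCorrelations:
    def test_unit_variance_covariance_is_correlation(self):
        G_o = np.array([[1.0, 0.78], [0.78, 1.0]])
        est = dummy_estimates(G_o, np.eye(2), np.ones(2), np.ones(2),
                              pops=("P1", "P2"))
        corr_A, corr_D, _, _ = genotypic_correlations(est)
        assert corr_A.loc["P1", "P2"] == pytest.approx(0.78)
        assert corr_D.loc["P1", "P2"] == pytest.approx(0.0)

    def test_matches_naive_formula(self):
        rng = np.random.default_rng(5)
        L = rng.standard_normal((3, 3))
        G_o = L @ L.T
        est = dummy_estimates(G_o, np.eye(3), np.ones(3), np.ones(3))
        corr_A, *_ = genotypic_correlations(est)
        for i in range(3):
            for j in range(3):
                naive = G_o[i, j] / np.sqrt(G_o[i, i] * G_o[j, j])
                assert corr_A.iloc[i, j] == pytest.approx(naive, rel=1e-12)

    def test_zero_variance_flagged_nan(self):
        est = dummy_estimates(np.diag([0.0, 1.0]), np.eye(2), np.ones(2),
                              np.ones(2), pops=("P1", "P2"))
        corr_A, *_ = genotypic_correlations(est)
        assert np.isnan(corr_A.loc["P1", "P2"])


@pytest.fixture(scope="module")
def fitted_small():
    cfg = SimConfig(seed=77, m=150, n1=60, n2=60, n12=60)
    geno, truth, phen = simulate(cfg)
    geno = qc_filter(geno)
    md = build_model(phen, geno, fixed_effects=("parity",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = em_reml(md, tol=1e-6, max_iter=80)
    return md, est


class TestEMREML:
    def test_loglik_monotone(self, fitted_small):
        _, est = fitted_small
        ll = est.loglik_trace
        assert np.all(np.diff(ll) >= -1e-7 * np.abs(ll[:-1]))

    def test_psd_estimates(self, fitted_small):
        _, est = fitted_small
        assert np.linalg.eigvalsh(est.G_o).min() >= -1e-10
        assert np.linalg.eigvalsh(est.D_o).min() >= -1e-10
        assert np.all(est.perm_env >= 0) and np.all(est.residual > 0)

    def test_se_available(self, fitted_small):
        _, est = fitted_small
        assert np.all(np.isfinite(np.diag(est.se_G_o)))
        assert est.ai_matrix.shape == (18, 18)

    def test_invariant_to_record_order(self):
        cfg = SimConfig(seed=31, m=100, n1=40, n2=40, n12=40)
        geno, _, phen = simulate(cfg)
        geno = qc_filter(geno)
        shuffled = phen.sample(frac=1.0, random_state=5).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = em_reml(build_model(phen, geno, fixed_effects=("parity",)),
                         max_iter=30, compute_se=False)
            e2 = em_reml(build_model(shuffled, geno, fixed_effects=("parity",)),
                         max_iter=30, compute_se=False)
        np.testing.assert_allclose(e1.G_o, e2.G_o, atol=1e-6)
        np.testing.assert_allclose(e1.residual, e2.residual, atol=1e-6)

    def test_invariant_to_allele_relabelling(self):
        cfg = SimConfig(seed=32, m=100, n1=40, n2=40, n12=40)
        geno, _, phen = simulate(cfg)
        flipped = make_geno(2.0 - geno.dosages, pops=list(geno.pop_labels),
                            ind_ids=list(geno.individual_ids))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = em_reml(build_model(phen, geno, include_homozygosity=False),
                         max_iter=25, compute_se=False)
            e2 = em_reml(build_model(phen, flipped, include_homozygosity=False),
                         max_iter=25, compute_se=False)
        np.testing.assert_allclose(e1.G_o, e2.G_o, atol=1e-8)
        np.testing.assert_allclose(e1.D_o, e2.D_o, atol=1e-8)


class TestBlup:
    @staticmethod
    def _dense_gls_blups(md, est):
        """Dense GLS oracle: explicit record-level covariance matrix."""
        N, n = md.n_records, md.n_individuals
        Zr = np.zeros((N, n))
        Zr[np.arange(N), md.rec_ind] = 1.0
        popi = md.ind_pop
        K = (est.G_o[np.ix_(popi, popi)] * md.G
             + est.D_o[np.ix_(popi, popi)] * md.D
             + np.diag(est.perm_env[popi]))
        V = Zr @ K @ Zr.T + np.diag(est.residual[md.rec_pop])
        Vi = np.linalg.inv(V)
        X = md.X
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ md.y)
        Py = Vi @ (md.y - X @ beta)
        r = Zr.T @ Py
        u = np.vstack([(est.G_o[k, popi] * r) @ md.G for k in range(len(est.populations))])
        return beta, u

    def test_matches_dense_gls_oracle(self):
        cfg = SimConfig(seed=55, m=60, n1=10, n2=10, n12=10)
        geno, _, phen = simulate(cfg)
        md = build_model(phen, geno, include_homozygosity=False)
        est = dummy_estimates(
            np.array([[1.0, 0.5, 0.4], [0.5, 1.2, 0.3], [0.4, 0.3, 0.9]]),
            np.diag([0.4, 0.3, 0.5]), [0.3, 0.4, 0.2], [1.0, 1.1, 0.9])
        sol = blup_solutions(md, est)
        beta, u = self._dense_gls_blups(md, est)
        np.testing.assert_allclose(sol.beta, beta, atol=1e-8)
        np.testing.assert_allclose(sol.u, u, atol=1e-8)

    def test_zero_genetic_variance_shrinks_to_zero(self):
        cfg = SimConfig(seed=56, m=60, n1=10, n2=10, n12=10)
        geno, _, phen = simulate(cfg)
        md = build_model(phen, geno, include_homozygosity=False)
        est = dummy_estimates(np.eye(3) * 1e-12, np.eye(3) * 1e-12,
                              [0.3, 0.3, 0.3], [1.0, 1.0, 1.0])
        sol = blup_solutions(md, est)
        assert np.max(np.abs(sol.u)) < 1e-9
        assert np.max(np.abs(sol.v)) < 1e-9

    def test_identical_data_gives_identical_solutions(self):
        """Two individuals with identical genotypes and identical records
        receive identical BLUPs."""
        rng = np.random.default_rng(8)
        dos = rng.choice([0.0, 1.0, 2.0], size=(6, 40))
        dos[5] = dos[4]  # clone individual i4
        geno = make_geno(dos, pops=["P1", "P1", "P2", "P2", "F1", "F1"])
        phen = pd.DataFrame({
            "individual_id": ["i0", "i1", "i2", "i3", "i4", "i5"] * 2,
            "population": ["P1", "P1", "P2", "P2", "F1", "F1"] * 2,
            "phenotype": [1.0, 2.0, 1.5, 2.5, 3.0, 3.0] * 2,
        })
        md = build_model(phen, geno, include_homozygosity=False)
        est = dummy_estimates(np.eye(3) * 0.5 + 0.2, np.eye(3) * 0.3,
                              [0.2] * 3, [1.0] * 3)
        sol = blup_solutions(md, est)
        i4 = list(sol.individual_ids).index("i4")
        i5 = list(sol.individual_ids).index("i5")
        np.testing.assert_allclose(sol.u[:, i4], sol.u[:, i5], atol=1e-10)
        np.testing.assert_allclose(sol.v[:, i4], sol.v[:, i5], atol=1e-10)

    def test_mixed_model_equation_residual(self):
        """BLUP solutions satisfy the normal equations of the equivalent
        single-kernel mixed model to high accuracy."""
        cfg = SimConfig(seed=57, m=80, n1=12, n2=12, n12=12)
        geno, _, phen = simulate(cfg)
        md = build_model(phen, geno, include_homozygosity=False)
        est = dummy_estimates(np.eye(3) * 0.8 + 0.1, np.diag([0.4, 0.5, 0.3]),
                              [0.3, 0.2, 0.4], [1.0, 0.9, 1.1])
        ws = _Workspace(md, est.G_o, est.D_o, est.perm_env, est.residual)
        # the projected residual must be orthogonal to the fixed design
        # (X'Py = 0) and reproduce y through V P y + X beta
        assert np.max(np.abs(md.X.T @ ws.Py)) < 1e-8
        N, n = md.n_records, md.n_individuals
        Zr = np.zeros((N, n))
        Zr[np.arange(N), md.rec_ind] = 1.0
        popi = md.ind_pop
        K = (est.G_o[np.ix_(popi, popi)] * md.G
             + est.D_o[np.ix_(popi, popi)] * md.D
             + np.diag(est.perm_env[popi]))
        V = Zr @ K @ Zr.T + np.diag(est.residual[md.rec_pop])
        np.testing.assert_allclose(V @ ws.Py + md.X @ ws.beta, md.y, atol=1e-8)


class TestEstimator:
    def test_sklearn_interface(self):
        mdl = CrossbredGBLUP(max_iter=10)
        params = mdl.get_params()
        assert params["max_iter"] == 10
        mdl.set_params(tol=1e-3)
        assert mdl.tol == 1e-3

    def test_fit_predict(self):
        cfg = SimConfig(seed=99, m=120, n1=40, n2=40, n12=40)
        geno, _, phen = simulate(cfg)
        geno = qc_filter(geno)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mdl = CrossbredGBLUP(fixed_effects=("parity",), max_iter=40,
                                 tol=1e-6).fit(phen, geno)
        assert mdl.G_o_.shape == (3, 3)
        assert mdl.u_.shape == (3, mdl.model_.n_individuals)
        pred = mdl.predict()
        assert pred.shape == (mdl.model_.n_individuals,)
        # own-scale prediction equals the matching rows of u_ + v_
        own = mdl.model_.ind_pop
        idx = np.arange(len(own))
        np.testing.assert_allclose(pred, mdl.u_[own, idx] + mdl.v_[own, idx])

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            CrossbredGBLUP().predict()
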