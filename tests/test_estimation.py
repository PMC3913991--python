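"""Likelihood evaluation, two-level ML fitting, and single-level fits."""

import math

import numpy as np
import pytest
from scipy import optimize

import mlsemfit as m
from mlsemfit.estimation import (_Discrepancy, _ParamMap, _default_start,
                                 _level_grads, _level_sigma_and_cache)
from mlsemfit.model import WITHIN, BETWEEN


def uni_loglik_oracle(mu, s2w, s2b):
    """Term-by-term evaluation of the exact two-level log-likelihood for the
    univariate clusters {0,2} and {4,6}."""
    total = 0.0
    for ybarj, ys in ((1.0, (0.0, 2.0)), (5.0, (4.0, 6.0))):
        nj, p = 2, 1
        sg = s2w + nj * s2b
        cj = -(nj * p / 2) * math.log(2 * math.pi)
        total += cj - 0.5 * math.log(sg) - nj / 2 * (ybarj - mu) ** 2 / sg
        total += -(nj - 1) / 2 * math.log(s2w)
        total += -0.5 * sum((y - ybarj) ** 2 for y in ys) / s2w
    return total


class TestLikelihood:
    def test_univariate_oracle(self, uni_stats, uni_sat_spec):
        ll = m.log_likelihood(uni_sat_spec, [2.0, 3.0], uni_stats, mu=np.array([3.0]))
        assert ll == pytest.approx(uni_loglik_oracle(3.0, 2.0, 3.0), abs=1e-12)

    def test_profiled_mean_is_optimal(self, uni_stats, uni_sat_spec):
        ll_prof = m.log_likelihood(uni_sat_spec, [2.0, 3.0], uni_stats)
        for mu in (2.5, 3.0, 3.5):
            assert ll_prof >= m.log_likelihood(uni_sat_spec, [2.0, 3.0], uni_stats,
                                               mu=np.array([mu])) - 1e-12

    def test_balanced_fml_equals_m2ll_difference(self, uni_stats, uni_sat_spec):
        """For balanced data the discrepancy difference between any two
        parameter points equals the -2 log-likelihood difference."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            t1 = [rng.uniform(0.5, 4.0), rng.uniform(0.1, 4.0)]
            t2 = [rng.uniform(0.5, 4.0), rng.uniform(0.1, 4.0)]
            df = m.f_ml(uni_sat_spec, t1, uni_stats) - m.f_ml(uni_sat_spec, t2, uni_stats)
            dll = m.log_likelihood(uni_sat_spec, t1, uni_stats) - \
                m.log_likelihood(uni_sat_spec, t2, uni_stats)
            assert df == pytest.approx(-2.0 * dll, abs=1e-9)

    def test_grouped_fml_matches_per_cluster_loop(self):
        """The size-grouped evaluation equals a naive per-cluster sum on
        unbalanced data."""
        rng = np.random.default_rng(3)
        design = m.SimulationDesign(
            sigma_b=0.3 * np.eye(2), sigma_w=np.eye(2), mu=np.zeros(2),
            J=7, cluster_sizes=[2, 3, 3, 4, 5, 2, 6], seed=1)
        data = m.generate(design)
        st = m.compute_sufficient_stats(data)
        sw = np.array([[1.2, 0.2], [0.2, 0.9]])
        sb = np.array([[0.4, 0.1], [0.1, 0.3]])
        F = _Discrepancy(st).value(sb, sw)
        # naive Eq-style loop
        naive = 0.0
        for k in range(st.J):
            sg = sw + st.n_j[k] * sb
            naive += np.linalg.slogdet(sg)[1] + np.trace(np.linalg.solve(sg, st.S_Bj[k]))
            naive += (st.n_j[k] - 1) * (np.linalg.slogdet(sw)[1]
                                        + np.trace(np.linalg.solve(sw, st.S_Wj[k])))
        assert F == pytest.approx(naive, rel=1e-12)

    def test_infeasible_point_raises(self, uni_stats, uni_sat_spec):
        with pytest.raises(ValueError, match="infeasible|not PD|non-PD|PD"):
            m.f_ml(uni_sat_spec, [-1.0, 0.0], uni_stats)


class TestGradient:
    def test_analytic_matches_numerical(self, timss_spec):
        st = m.compute_sufficient_stats(
            m.generate(m.timss_like_design(seed=3, J=40))).subset(timss_spec.observed)
        pm = _ParamMap(timss_spec)
        disc = _Discrepancy(st)
        x0 = _default_start(pm, st) + np.random.default_rng(0).normal(scale=0.01, size=pm.k)

        def obj(x):
            A, S = pm.matrices(x)
            sw, Bw, Sw = _level_sigma_and_cache(timss_spec.within, A[WITHIN], S[WITHIN])
            sb, Bb, Sb = _level_sigma_and_cache(timss_spec.between, A[BETWEEN], S[BETWEEN])
            F, W_B, W_W, _ = disc.value(sb, sw, weights=True)
            Tw, Xw = _level_grads(timss_spec.within, Bw, Sw, W_W)
            Tb, Xb = _level_grads(timss_spec.between, Bb, Sb, W_B)
            return F, pm.gather_gradient({(WITHIN, "S"): Tw, (WITHIN, "A"): Xw,
                                          (BETWEEN, "S"): Tb, (BETWEEN, "A"): Xb})

        F0, g0 = obj(x0)
        gn = np.zeros(pm.k)
        for k in range(pm.k):
            h = 1e-6 * (1 + abs(x0[k]))
            e = np.zeros(pm.k); e[k] = h
            gn[k] = (obj(x0 + e)[0] - obj(x0 - e)[0]) / (2 * h)
        np.testing.assert_allclose(g0, gn, rtol=1e-5, atol=1e-6 * np.max(np.abs(gn)))


class TestFit:
    def test_saturated_univariate_closed_form(self, uni_stats, uni_sat_spec):
        fr = m.fit(uni_sat_spec, uni_stats)
        assert fr.converged and fr.n_iter == 0
        assert fr.mu_hat == pytest.approx([3.0])
        np.testing.assert_allclose(fr.sigma_w, [[2.0]], atol=1e-12)
        np.testing.assert_allclose(fr.sigma_b, [[3.0]], atol=1e-12)

    def test_saturated_univariate_vs_generic_optimizer(self, uni_stats, uni_sat_spec):
        """Independent numeric maximization of the exact likelihood finds the
        same optimum as the closed form."""
        res = optimize.minimize(
            lambda t: -uni_loglik_oracle(t[0], t[1], t[2]),
            x0=[2.0, 1.0, 1.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert res.x == pytest.approx([3.0, 2.0, 3.0], abs=1e-5)

    def test_nothing_free_returns_same_m2ll(self, uni_stats):
        spec = m.parse_model(
            "variables: [y]\nwithin: |\n  y ~~ fix(2)*y\nbetween: |\n  y ~~ fix(3)*y")
        fr = m.fit(spec, uni_stats)
        assert fr.n_iter == 0 and fr.converged
        assert fr.minus2ll == pytest.approx(-2 * uni_loglik_oracle(3.0, 2.0, 3.0), abs=1e-10)

    def test_nested_models_monotone(self, timss_spec):
        st = m.compute_sufficient_stats(m.generate(m.timss_like_design(seed=2, J=100)))
        f_sat = m.fit(m.saturate(m.saturate(timss_spec, m.WITHIN), m.BETWEEN), st)
        f_hyp = m.fit(timss_spec, st)
        f_mb = m.fit(m.timss_like_spec(drop_between_female=True), st)
        assert f_hyp.f_value >= f_sat.f_value - 1e-6
        assert f_mb.f_value >= f_hyp.f_value - 1e-6

    def test_shift_invariance(self, timss_spec):
        data = m.generate(m.timss_like_design(seed=4, J=60))
        st1 = m.compute_sufficient_stats(data)
        data2 = m.TwoLevelDataset(data.values + np.array([1.0, -2.0, 3.0, 0.5, 10.0]),
                                  data.cluster_id, data.variable_names)
        st2 = m.compute_sufficient_stats(data2)
        fr1, fr2 = m.fit(timss_spec, st1), m.fit(timss_spec, st2)
        # covariance estimates are location-invariant; the iterative optimum
        # is reproduced to well below any statistically meaningful digit
        np.testing.assert_allclose(fr1.sigma_w, fr2.sigma_w, atol=1e-6)
        np.testing.assert_allclose(fr1.sigma_b, fr2.sigma_b, atol=1e-6)
        np.testing.assert_allclose(fr2.mu_hat - fr1.mu_hat,
                                   [1.0, -2.0, 3.0, 0.5, 10.0], atol=1e-8)

    def test_parameter_recovery_from_simulated_data(self):
        """Estimates on a large simulated mediation dataset are close to the
        generating values."""
        design = m.simulate.mediation_design(seed=11, J=500, n=20)
        st = m.compute_sufficient_stats(m.generate(design))
        fr = m.fit(m.simulate.mediation_spec(), st)
        assert fr.converged
        th = fr.theta_hat
        assert th["w:med~x"] == pytest.approx(0.5, abs=0.03)
        assert th["w:y~med"] == pytest.approx(0.6, abs=0.03)
        assert th["b:med~x"] == pytest.approx(0.5, abs=0.15)
        assert th["b:y~med"] == pytest.approx(0.6, abs=0.15)
        np.testing.assert_allclose(fr.sigma_w, m.simulate.mediation_truth()[1], atol=0.05)


class TestFitSaturated:
    def test_balanced_closed_form(self, uni_stats):
        sat = m.fit_saturated(uni_stats)
        assert sat.mu_hat == pytest.approx([3.0])
        np.testing.assert_allclose(sat.sigma_w_hat, [[2.0]], atol=1e-12)
        np.testing.assert_allclose(sat.sigma_b_hat, [[3.0]], atol=1e-12)
        assert sat.sigma_b_psd

    def test_balanced_closed_form_matches_general(self, timss_spec):
        st = m.compute_sufficient_stats(m.generate(m.timss_like_design(seed=6, J=80)))
        sat = m.fit_saturated(st)
        n = int(st.n_j[0])
        np.testing.assert_allclose(sat.sigma_w_hat, st.pooled_within, atol=1e-8)
        np.testing.assert_allclose(
            sat.sigma_b_hat, (st.mean_S_B() - st.pooled_within) / n, atol=1e-8)

    def test_unbalanced_matches_bruteforce_likelihood_maximization(self):
        """J=3 clusters of sizes 2, 3, 4: the saturated fit agrees with a
        generic optimizer maximizing the exact likelihood."""
        values = np.array([[0.1], [1.9], [4.2], [5.6], [5.0], [1.0], [2.5],
                           [3.1], [2.2]])
        cluster = np.array([0, 0, 1, 1, 1, 2, 2, 2, 2])
        st = m.compute_sufficient_stats(m.TwoLevelDataset(values, cluster, ["y"]))
        sat = m.fit_saturated(st)

        def neg_ll(t):
            mu, s2w, s2b = t
            if s2w <= 1e-8:
                return 1e10
            total = 0.0
            for k in range(st.J):
                nj = st.n_j[k]
                sg = s2w + nj * s2b
                if sg <= 1e-8:
                    return 1e10
                total += -0.5 * math.log(sg) - nj / 2 * (st.cluster_means[k, 0] - mu) ** 2 / sg
                total += -(nj - 1) / 2 * math.log(s2w) \
                    - 0.5 * (nj - 1) * st.S_Wj[k, 0, 0] / s2w
            return -total

        res = optimize.minimize(neg_ll, [2.5, 2.0, 0.5], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-13,
                                         "maxiter": 10000})
        assert sat.mu_hat[0] == pytest.approx(res.x[0], abs=1e-6)
        assert sat.sigma_w_hat[0, 0] == pytest.approx(res.x[1], abs=1e-6)
        assert sat.sigma_b_hat[0, 0] == pytest.approx(res.x[2], abs=1e-6)

    def test_acov_dimensions_p5(self, timss_spec):
        st = m.compute_sufficient_stats(m.generate(m.timss_like_design(seed=8, J=60)))
        sat = m.fit_saturated(st)
        assert sat.acov_w.shape == (15, 15) and sat.acov_b.shape == (15, 15)
        assert np.all(np.diag(sat.acov_w) > 0)

    def test_identical_cluster_means_flagged(self):
        """Fully degenerate between variation: estimates returned with a
        warning, not an exception."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 1))
        values = np.vstack([base - base.mean(axis=0) for _ in range(5)])
        cluster = np.repeat(np.arange(5), 4)
        st = m.compute_sufficient_stats(m.TwoLevelDataset(values, cluster, ["y"]))
        sat = m.fit_saturated(st)
        assert not sat.sigma_b_psd
        assert sat.warnings
        np.testing.assert_allclose(sat.sigma_b_hat, -sat.sigma_w_hat / 4, atol=1e-12)

    def test_zero_between_variance_recovered_near_zero(self):
        """Generating Sigma_B = 0: the unrestricted between estimate is within
        sampling error of zero and may be indefinite (then flagged)."""
        design = m.SimulationDesign(sigma_b=np.zeros((2, 2)), sigma_w=np.eye(2),
                                    mu=np.zeros(2), J=40, cluster_sizes=5, seed=3)
        st = m.compute_sufficient_stats(m.generate(design))
        sat = m.fit_saturated(st)
        assert np.max(np.abs(sat.sigma_b_hat)) < 0.15
        if np.linalg.eigvalsh(sat.sigma_b_hat).min() < 0:
            assert not sat.sigma_b_psd


class TestFitSingleLevel:
    def test_saturated_model_chi2_zero(self):
        lm = m.LevelModel.saturated(["a", "b"])
        S = np.array([[1.0, 0.3], [0.3, 2.0]])
        fr, rep = m.fit_single_level(lm, S, 100)
        assert rep.chi2 == pytest.approx(0.0) and rep.df == 0

    def test_perfect_fit_at_truth(self):
        spec = m.simulate.mediation_spec()
        sigma = m.simulate.mediation_truth()[1]
        fr, rep = m.fit_single_level(spec.within, sigma, 500)
        assert rep.chi2 == pytest.approx(0.0, abs=1e-6)
        assert rep.cfi == 1.0 and rep.rmsea == 0.0

    def test_perturbed_factor_matrix_vs_bruteforce(self):
        """One-factor model fit to its implied matrix with one covariance
        perturbed: chi-square matches a brute-force minimization oracle."""
        S = np.array([[1.5, 0.8, 0.5],
                      [0.8, 1.14, 0.4],
                      [0.5, 0.4, 0.75]])
        S[0, 1] = S[1, 0] = 0.9  # perturb one off-diagonal by +0.1
        cfg = ("variables: [x1, x2, x3]\nwithin: |\n  f =~ x1 + x2 + x3\n"
               "between: saturated")
        model = m.parse_model(cfg).within
        fr, rep = m.fit_single_level(model, S, 200)
        assert fr.converged

        labels = model.free_params()
        logdet_s = np.linalg.slogdet(S)[1]

        def F(theta):
            A = model.a_value.copy()
            Sm = model.s_value.copy()
            for slot in model.free_slots():
                v = theta[labels.index(model.slot_label(slot))]
                mat, i, j = slot
                if mat == "A":
                    A[i, j] = v
                else:
                    Sm[i, j] = Sm[j, i] = v
            sigma = model.implied_cov_from(A, Sm)
            sgn, ld = np.linalg.slogdet(sigma)
            if sgn <= 0:
                return 1e10
            return ld + np.trace(np.linalg.solve(sigma, S)) - logdet_s - 3

        best = np.inf
        rng = np.random.default_rng(1)
        x0 = np.array([fr.theta_hat[lab] for lab in labels])
        for trial in range(4):
            xs = x0 * (1 + 0.2 * rng.normal(size=len(x0))) if trial else x0
            res = optimize.minimize(F, xs, method="Nelder-Mead",
                                    options={"maxiter": 20000, "xatol": 1e-10,
                                             "fatol": 1e-13})
            best = min(best, res.fun)
        assert fr.f_value == pytest.approx(best, abs=1e-6)
        assert rep.chi2 == pytest.approx(199 * best, rel=1e-4)

    def test_non_pd_input_rejected(self):
        lm = m.LevelModel.saturated(["a", "b"])
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            m.fit_single_level(lm, S, 50)
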