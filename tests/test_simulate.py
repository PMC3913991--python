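"""Two-level data generation, non-normal margins, replication driver."""

import numpy as np
import pytest
from scipy import stats as sps

import mlsemfit as m
from mlsemfit.simulate import _sizes_with_total


class TestGenerate:
    def test_same_seed_identical(self):
        d1 = m.generate(m.timss_like_design(seed=9))
        d2 = m.generate(m.timss_like_design(seed=9))
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(d1.cluster_id, d2.cluster_id)

    def test_different_seed_differs(self):
        d1 = m.generate(m.timss_like_design(seed=9))
        d2 = m.generate(m.timss_like_design(seed=10))
        assert not np.array_equal(d1.values, d2.values)

    def test_zero_between_cluster_mean_covariance(self):
        """With Sigma_B = 0 the covariance of cluster means approaches
        Sigma_W / n."""
        sigma_w = np.array([[1.0, 0.4], [0.4, 2.0]])
        design = m.SimulationDesign(sigma_b=np.zeros((2, 2)), sigma_w=sigma_w,
                                    mu=np.zeros(2), J=4000, cluster_sizes=8, seed=1)
        st = m.compute_sufficient_stats(m.generate(design))
        means_cov = np.cov(st.cluster_means.T)
        # sampling error of a variance over J=4000 clusters is ~ v*sqrt(2/J)
        np.testing.assert_allclose(means_cov, sigma_w / 8, rtol=0.12, atol=0.01)

    def test_mu_added(self):
        design = m.timss_like_design(seed=0, J=300)
        data = m.generate(design)
        np.testing.assert_allclose(data.values.mean(axis=0), design.mu,
                                   atol=3 * np.sqrt(np.diag(design.sigma_b)[4]))

    def test_non_pd_sigma_w_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            m.SimulationDesign(sigma_b=np.eye(1), sigma_w=np.zeros((1, 1)),
                               mu=np.zeros(1), J=5, cluster_sizes=3)


class TestNonNormal:
    def test_fleishman_moment_targets(self):
        """Skewness 2, excess kurtosis 7 (the bias rule-of-thumb cutoffs):
        sample moments over 10^6 draws land within 5% of the targets."""
        a, b, c, d = m.fleishman_coefficients(2.0, 7.0)
        z = np.random.default_rng(1).standard_normal(1_000_000)
        y = a + b * z + c * z ** 2 + d * z ** 3
        assert abs(y.mean()) < 0.01
        assert y.var() == pytest.approx(1.0, rel=0.02)
        assert sps.skew(y) == pytest.approx(2.0, rel=0.05)
        assert sps.kurtosis(y) == pytest.approx(7.0, rel=0.05)

    def test_normal_limit(self):
        a, b, c, d = m.fleishman_coefficients(0.0, 0.0)
        assert (a, b, c, d) == pytest.approx((0.0, 1.0, 0.0, 0.0), abs=1e-8)

    def test_infeasible_targets_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="infeasible|no Fleishman"):
            m.SimulationDesign(sigma_b=np.eye(1), sigma_w=np.eye(1),
                               mu=np.zeros(1), J=5, cluster_sizes=3,
                               dist_within=(3.0, -1.0))

    def test_nonnormal_preserves_covariance(self):
        sigma_w = np.array([[1.0, 0.5], [0.5, 1.0]])
        design = m.SimulationDesign(sigma_b=0.2 * np.eye(2), sigma_w=sigma_w,
                                    mu=np.zeros(2), J=2000, cluster_sizes=20,
                                    dist_within=(2.0, 7.0), seed=4)
        st = m.compute_sufficient_stats(m.generate(design))
        np.testing.assert_allclose(st.pooled_within, sigma_w, atol=0.03)

    def test_level_specific_nonnormality(self):
        """Skewing the within components leaves the between components
        normal: within margins are skewed, cluster means much less so."""
        design = m.SimulationDesign(sigma_b=0.2 * np.eye(1), sigma_w=np.eye(1),
                                    mu=np.zeros(1), J=500, cluster_sizes=40,
                                    dist_within=(2.0, 7.0), seed=6)
        data = m.generate(design)
        st = m.compute_sufficient_stats(data)
        centered = data.values[:, 0] - np.repeat(st.cluster_means[:, 0], st.n_j)
        assert sps.skew(centered) > 1.5
        assert abs(sps.skew(st.cluster_means[:, 0])) < 0.5


class TestClusterSizes:
    def test_sizes_with_total_exact(self):
        rng = np.random.default_rng(0)
        sizes = _sizes_with_total(164, 26, 42, 5928, rng)
        assert sizes.sum() == 5928
        assert sizes.min() >= 26 and sizes.max() <= 42

    def test_unreachable_total_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="unreachable"):
            _sizes_with_total(10, 5, 6, 100, rng)

    def test_explicit_vector(self):
        design = m.SimulationDesign(sigma_b=0.2 * np.eye(1), sigma_w=np.eye(1),
                                    mu=np.zeros(1), J=3, cluster_sizes=[2, 3, 4],
                                    seed=0)
        st = m.compute_sufficient_stats(m.generate(design))
        assert st.n_j.tolist() == [2, 3, 4]


class TestPresets:
    def test_mediation_truth_icc(self):
        sb, sw, _ = m.simulate.mediation_truth()
        icc = np.diag(sb) / (np.diag(sb) + np.diag(sw))
        np.testing.assert_allclose(icc, 0.2, atol=1e-12)

    def test_timss_truth_iccs_near_point_two(self):
        sb, sw, _ = m.timss_like_truth()
        icc = np.diag(sb) / (np.diag(sb) + np.diag(sw))
        np.testing.assert_allclose(icc[:4], 0.2, atol=0.01)
        assert np.linalg.eigvalsh(sb).min() > 0
        assert np.linalg.eigvalsh(sw).min() > 0

    def test_timss_spec_fits_its_own_truth_exactly(self):
        """The hypothesized model reproduces the generating covariance
        matrices (zero population discrepancy)."""
        sb, sw, mu = m.timss_like_truth()
        design = m.timss_like_design(seed=0, J=300)
        st = m.compute_sufficient_stats(m.generate(design))
        fr = m.fit(m.timss_like_spec(), st)
        assert fr.converged
        np.testing.assert_allclose(fr.sigma_w, sw, atol=0.2)


class TestSimulationStudy:
    def test_summary_structure_and_determinism(self):
        design = m.simulate.mediation_design(seed=5, J=60, n=6, replications=4)
        spec = m.simulate.mediation_spec()
        s1 = m.simulation_study(design, {"true": spec},
                                approaches=("standard", "level_specific"))
        s2 = m.simulation_study(design, {"true": spec},
                                approaches=("standard", "level_specific"))
        assert set(s1["approach"]) == {"standard", "PS_B", "PS_W"}
        assert (s1["n_reps"] == 4).all()
        np.testing.assert_allclose(s1["mean_chi2"], s2["mean_chi2"])
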