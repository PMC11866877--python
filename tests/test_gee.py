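import math

import numpy as np
import pytest
from scipy.special import expit

from pairedni import (MISSING, PairOutcome, PairedCountTable, build_design,
                      gee_ci, gee_fit, generate_pairs, joint_from_marginals,
                      rd_from_fit, tabulate, theta_complete)
from pairedni.exceptions import SeparationError
from pairedni.gee import GeeDesign

from conftest import random_table


class TestDesign:
    def test_complete_pair_becomes_size_two_cluster(self):
        d = build_design([PairOutcome(1, 0)])
        (X, y, w), = d.types
        assert X.shape == (2, 2) and list(y) == [1.0, 0.0] and w == 1

    def test_half_observed_pair_becomes_singleton(self):
        d = build_design([PairOutcome(MISSING, 1)])
        (X, y, w), = d.types
        assert X.tolist() == [[1.0, 1.0]] and list(y) == [1.0]

    def test_row_and_cluster_counts(self, rng):
        pairs = [PairOutcome(1, 0)] * 4 + [PairOutcome(0, 0)] * 3 \
            + [PairOutcome(1, MISSING)] * 2 + [PairOutcome(MISSING, 0)]
        d = build_design(pairs)
        assert d.n_clusters == 10
        assert d.n_obs == 17


class TestFit:
    def test_saturated_model_reproduces_group_proportions_on_complete_data(self):
        t = PairedCountTable(n00=35, n01=15, n10=25, n11=25)
        fit = gee_fit(GeeDesign.from_table(t))
        mu1 = expit(fit.beta[0])
        mu2 = expit(fit.beta[0] + fit.beta[1])
        assert mu1 == pytest.approx(t.n1p / t.n_pp, abs=1e-10)
        assert mu2 == pytest.approx(t.np1 / t.n_pp, abs=1e-10)
        rd = rd_from_fit(fit)
        assert rd.theta_gee == pytest.approx(theta_complete(t).value,
                                             abs=1e-10)

    def test_exchangeable_alpha_near_zero_for_independent_pairs(self, rng):
        dist = joint_from_marginals(0.6, 0.6, 0.0)
        pairs = generate_pairs(dist, 5000, rng)
        fit = gee_fit(build_design(pairs))
        assert abs(fit.alpha_exch) < 4 / math.sqrt(5000)

    def test_estimating_equation_solved_at_convergence(self):
        for seed in range(10):
            t = random_table(np.random.default_rng(seed), min_complete=10)
            fit = gee_fit(GeeDesign.from_table(t))
            assert fit.converged
            assert fit.score_norm < 1e-8

    def test_sandwich_matches_bruteforce_cluster_accumulation(self):
        for seed in range(5):
            t = random_table(np.random.default_rng(40 + seed), min_complete=10)
            design = GeeDesign.from_table(t)
            fit = gee_fit(design)
            beta, alpha = fit.beta, fit.alpha_exch
            I0 = np.zeros((2, 2))
            I1 = np.zeros((2, 2))
            for X, y, w in design.types:
                for _ in range(w):  # explicit per-cluster accumulation
                    mu = expit(X @ beta)
                    A = np.diag(mu * (1 - mu))
                    R = np.eye(len(y)) * (1 - alpha) + alpha if len(y) == 2 \
                        else np.eye(1)
                    rootA = np.sqrt(A)
                    V = rootA @ R @ rootA
                    D = A @ X
                    Vinv = np.linalg.inv(V)
                    r = y - mu
                    I0 += D.T @ Vinv @ D
                    u = D.T @ Vinv @ r
                    I1 += np.outer(u, u)
            sandwich = np.linalg.inv(I0) @ I1 @ np.linalg.inv(I0)
            assert np.allclose(fit.cov_sandwich, sandwich, atol=1e-8)
            assert np.allclose(fit.cov_model, np.linalg.inv(I0), atol=1e-8)

    def test_permuting_cluster_order_leaves_fit_unchanged(self, rng):
        t = random_table(np.random.default_rng(7), min_complete=10)
        design = GeeDesign.from_table(t)
        fit = gee_fit(design)
        perm = list(design.types)
        rng.shuffle(perm)
        fit2 = gee_fit(GeeDesign(types=perm))
        assert np.allclose(fit.beta, fit2.beta, atol=1e-12)
        assert np.allclose(fit.cov_sandwich, fit2.cov_sandwich, atol=1e-12)

    def test_separation_raises(self):
        with pytest.raises(SeparationError):
            gee_fit(GeeDesign.from_table(PairedCountTable(n10=10, n11=10)))

    def test_matches_statsmodels_under_working_independence(self):
        sm = pytest.importorskip("statsmodels.api")
        t = PairedCountTable(n00=40, n01=10, n10=20, n11=30, n0x=5, n1x=7,
                             nx0=3, nx1=6)
        fit = gee_fit(GeeDesign.from_table(t), working_alpha=0.0)
        rows, cid = [], 0
        for pair in t.expand():
            if pair.y1 is not MISSING:
                rows.append((cid, 0.0, float(pair.y1)))
            if pair.y2 is not MISSING:
                rows.append((cid, 1.0, float(pair.y2)))
            cid += 1
        arr = np.array(rows)
        X = sm.add_constant(arr[:, 1])
        res = sm.GEE(arr[:, 2], X, groups=arr[:, 0],
                     family=sm.families.Binomial(),
                     cov_struct=sm.cov_struct.Independence()).fit()
        assert np.allclose(fit.beta, res.params, atol=1e-8)
        assert np.allclose(fit.cov_sandwich, np.asarray(res.cov_robust),
                           atol=1e-10)

    def test_close_to_statsmodels_exchangeable(self):
        sm = pytest.importorskip("statsmodels.api")
        t = PairedCountTable(n00=40, n01=10, n10=20, n11=30, n0x=5, n1x=7,
                             nx0=3, nx1=6)
        fit = gee_fit(GeeDesign.from_table(t))
        rows, cid = [], 0
        for pair in t.expand():
            if pair.y1 is not MISSING:
                rows.append((cid, 0.0, float(pair.y1)))
            if pair.y2 is not MISSING:
                rows.append((cid, 1.0, float(pair.y2)))
            cid += 1
        arr = np.array(rows)
        X = sm.add_constant(arr[:, 1])
        res = sm.GEE(arr[:, 2], X, groups=arr[:, 0],
                     family=sm.families.Binomial(),
                     cov_struct=sm.cov_struct.Exchangeable()).fit()
        # conventions for the moment estimator of the working correlation
        # differ slightly between implementations
        assert np.allclose(fit.beta, res.params, atol=5e-3)
        assert np.allclose(fit.cov_sandwich, np.asarray(res.cov_robust),
                           rtol=0.02, atol=1e-4)

    def test_model_and_sandwich_agree_under_true_exchangeable(self, rng):
        dist = joint_from_marginals(0.7, 0.7, 0.4)
        pairs = generate_pairs(dist, 5000, rng)
        fit = gee_fit(build_design(pairs))
        assert np.allclose(fit.cov_model, fit.cov_sandwich, rtol=0.15)


class TestDelta:
    def test_symmetric_logistic_point(self):
        fit = _fit_with_beta(np.array([0.0, 0.0]))
        rd = rd_from_fit(fit)
        assert rd.theta_gee == 0.0
        assert np.allclose(rd.gradient, [0.0, -0.25])

    def test_null_effect_gives_zero_difference(self):
        b0 = math.log(0.8 / 0.2)
        rd = rd_from_fit(_fit_with_beta(np.array([b0, 0.0])))
        assert rd.theta_gee == pytest.approx(0.0, abs=1e-15)

    def test_se_matches_finite_difference_jacobian(self):
        for seed in range(5):
            t = random_table(np.random.default_rng(70 + seed), min_complete=10)
            fit = gee_fit(GeeDesign.from_table(t))
            rd = rd_from_fit(fit)
            h = 1e-6

            def theta(b):
                return expit(b[0]) - expit(b[0] + b[1])

            g_fd = np.array([
                (theta(fit.beta + [h, 0]) - theta(fit.beta - [h, 0])) / (2 * h),
                (theta(fit.beta + [0, h]) - theta(fit.beta - [0, h])) / (2 * h),
            ])
            se_fd = math.sqrt(g_fd @ fit.cov_sandwich @ g_fd)
            assert rd.se == pytest.approx(se_fd, rel=1e-6)


def _fit_with_beta(beta):
    from pairedni.gee import GeeFit
    return GeeFit(beta=beta, cov_model=np.eye(2), cov_sandwich=np.eye(2),
                  alpha_exch=0.0, phi=1.0, n_clusters=10, iterations=1,
                  converged=True)


class TestCI:
    def test_midpoint_equals_complete_case_estimate_on_complete_data(self):
        t = PairedCountTable(n00=200, n01=40, n10=60, n11=200)
        ci = gee_ci(t, alpha=0.05)
        mid = (ci.lower + ci.upper) / 2
        assert mid == pytest.approx(theta_complete(t).value, abs=1e-9)

    def test_accepts_pairs_and_tables(self):
        t = PairedCountTable(n00=30, n01=10, n10=15, n11=25, n1x=5, nx0=5)
        a = gee_ci(t)
        b = gee_ci(t.expand())
        assert a.lower == pytest.approx(b.lower, abs=1e-12)
        assert a.n_used == t.n
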