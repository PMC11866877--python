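import math

import numpy as np
import pytest
from scipy.stats import norm

from pairedni import (PairedCountTable, nam_asymptotic_power, nam_sample_size,
                      nam_score_test, tango_ci, theta_complete)
from pairedni.exceptions import (InvalidParameterError, NoInformationError,
                                 UndefinedEstimateError)
from pairedni.tango import rmle_at_boundary, restricted_variance

from conftest import random_table


class TestRmle:
    def test_zero_margin_collapses_to_mid_discordant_probability(self):
        r = rmle_at_boundary(p01_hat=0.1, theta_cc=0.1, delta_eff=0.0)
        assert r.a1 == pytest.approx(-0.3)
        assert r.b1 == 0.0
        # at delta=0 the root is (p01 + p10)/2 = (0.1 + 0.2)/2
        assert r.p101 == pytest.approx(0.15)
        assert r.p110 == pytest.approx(0.15)

    def test_all_zero_discordance(self):
        r = rmle_at_boundary(0.0, 0.0, 0.0)
        assert r.p101 == 0.0 and r.p110 == 0.0

    def test_root_satisfies_the_quadratic(self):
        # independent polynomial-root check: the printed root solves the
        # quadratic 2 p^2 + a1 p + b1 = 0 (from 4p = -a1 + sqrt(a1^2 - 8 b1))
        r = rmle_at_boundary(p01_hat=0.2, theta_cc=0.0, delta_eff=0.05)
        roots = np.roots([2.0, r.a1, r.b1])
        feasible = [x.real for x in roots if abs(x.imag) < 1e-12 and
                    -1e-9 <= x.real <= 1.0]
        assert r.p101 == pytest.approx(max(feasible), abs=1e-12)
        assert r.p110 == pytest.approx(r.p101 - 0.05)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            rmle_at_boundary(1.5, 0.0, 0.0)


class TestScoreTest:
    def test_symmetric_table_at_zero_margin_not_rejected(self):
        t = PairedCountTable(n00=40, n01=15, n10=15, n11=30)
        res = nam_score_test(t, delta=0.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.reject

    @pytest.mark.parametrize("seed", range(20))
    def test_zero_margin_statistic_squares_to_mcnemar(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        res = nam_score_test(t, delta=0.0)
        mcnemar = (t.n10 - t.n01) ** 2 / (t.n10 + t.n01)
        assert res.statistic ** 2 == pytest.approx(mcnemar, abs=1e-10)

    def test_degenerate_concordant_table_carries_no_information(self):
        with pytest.raises(NoInformationError):
            nam_score_test(PairedCountTable(n00=50, n11=50), delta=0.0)

    def test_requires_complete_pairs(self):
        with pytest.raises(UndefinedEstimateError):
            nam_score_test(PairedCountTable(n0x=10), delta=0.05)


def _grid_oracle_ci(table, alpha, step=1e-6):
    """Dense-grid inversion of the score inequalities (independent oracle)."""
    n = table.n_pp
    theta_cc = (table.n10 - table.n01) / n
    p01 = table.n01 / n
    z = norm.ppf(1 - alpha)
    t0 = np.arange(-1.0, 1.0 + step, step)
    de = -t0
    a1 = -theta_cc * (1 - de) - 2 * (p01 + de)
    b1 = de * (1 + de) * p01
    p101 = (-a1 + np.sqrt(np.maximum(a1 * a1 - 8 * b1, 0))) / 4
    var = (2 * p101 - de - de ** 2) / n
    sig = np.sqrt(np.maximum(var, 0))
    num = theta_cc - t0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(sig > 0, num / np.where(sig > 0, sig, 1.0),
                     np.where(num > 0, np.inf, np.where(num < 0, -np.inf, 0.0)))
    lower = t0[s < z][0]        # inf{theta0 : score < z}
    upper = t0[s > -z][-1]      # sup{theta0 : score > -z}
    return lower, upper


class TestTangoCI:
    def test_symmetric_table_gives_symmetric_interval(self):
        t = PairedCountTable(n00=40, n01=12, n10=12, n11=36)
        ci = tango_ci(t, alpha=0.05)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_interval_contains_point_estimate(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_table(rng)
        ci = tango_ci(t, alpha=0.05)
        assert ci.lower - 1e-9 <= theta_complete(t).value <= ci.upper + 1e-9

    def test_endpoints_match_dense_grid_oracle(self):
        t = PairedCountTable(n00=40, n01=10, n10=20, n11=30)
        ci = tango_ci(t, alpha=0.05)
        lo, up = _grid_oracle_ci(t, alpha=0.05)
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(up, abs=1e-6)

    def test_wider_for_smaller_alpha(self):
        t = PairedCountTable(n00=40, n01=10, n10=20, n11=30)
        assert tango_ci(t, 0.01).width > tango_ci(t, 0.05).width > \
            tango_ci(t, 0.10).width

    def test_depends_only_on_discordant_cells_and_total(self):
        a = tango_ci(PairedCountTable(n00=60, n01=10, n10=20, n11=10), 0.05)
        b = tango_ci(PairedCountTable(n00=10, n01=10, n10=20, n11=60), 0.05)
        assert a.lower == pytest.approx(b.lower, abs=1e-12)
        assert a.upper == pytest.approx(b.upper, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_duality_with_score_test(self, seed):
        """Rejection of H0: theta <= -delta coincides with the CI lower
        bound exceeding -delta (away from the root-finder tie region)."""
        rng = np.random.default_rng(200 + seed)
        t = random_table(rng)
        delta = float(rng.uniform(0.0, 0.3))
        ci = tango_ci(t, alpha=0.05)
        if abs(ci.lower - (-delta)) < 1e-7:
            return
        try:
            res = nam_score_test(t, delta=delta, alpha=0.05)
        except NoInformationError:
            return
        assert res.reject == (ci.lower > -delta)


class TestSampleSize:
    def test_reference_paired_design_needs_507(self):
        assert nam_sample_size(0.8, 0.8, 0.375, delta=0.05, alpha=0.05,
                               power=0.80) == 507

    def test_complete_case_inflation_with_20pct_missing(self):
        n = nam_sample_size(0.8, 0.8, 0.375, delta=0.05, alpha=0.05,
                            power=0.80, p_complete=0.8)
        assert n == math.ceil(507 / 0.8) == 634

    def test_power_equal_alpha_degenerates_to_minimal_n(self):
        n = nam_sample_size(0.8, 0.8, 0.375, delta=0.05, alpha=0.05,
                            power=0.05)
        assert n <= 3

    def test_returned_n_is_minimal(self):
        n = nam_sample_size(0.8, 0.8, 0.375, delta=0.05, alpha=0.05,
                            power=0.80)
        from pairedni import joint_from_marginals
        d = joint_from_marginals(0.8, 0.8, 0.375)
        assert nam_asymptotic_power(n, d.p10, d.p01, 0.05) >= 0.80
        assert nam_asymptotic_power(n - 1, d.p10, d.p01, 0.05) < 0.80

    def test_infeasible_design_raises(self):
        with pytest.raises(InvalidParameterError):
            nam_sample_size(0.5, 0.8, 0.0, delta=0.05)  # theta + delta < 0
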