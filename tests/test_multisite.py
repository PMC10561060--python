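"""Sequential multisite methylation model: stationary distribution,
saturation thresholds, Hill coefficients, robustness ordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg

from cheradapt import multisite as ms


def birth_death_stationary(theta, P):
    """Null-space oracle: stationary vector of the explicit (n+1)-state
    birth-death rate matrix with forward rates theta*P[i] and unit
    backward rates."""
    n = len(P)
    Q = np.zeros((n + 1, n + 1))
    for i in range(n):
        Q[i, i + 1] = theta * P[i]  # methylation i -> i+1
        Q[i + 1, i] = 1.0  # demethylation i+1 -> i
    np.fill_diagonal(Q, -Q.sum(axis=1))
    ns = linalg.null_space(Q.T)
    v = np.abs(ns[:, 0])
    return v / v.sum()


class TestStationaryDistribution:
    def test_theta_zero_all_unmethylated(self):
        pm = ms.stationary_distribution(0.0, ms.CASES["case1"])
        np.testing.assert_array_equal(pm, [1, 0, 0, 0, 0])

    def test_theta_large_all_saturated(self):
        pm = ms.stationary_distribution(1e12, ms.CASES["case1"])
        assert pm[-1] == pytest.approx(1.0, abs=1e-10)

    def test_equal_weights_at_theta_four(self):
        # P_i = 1/4 and theta = 4 make every unnormalised weight 1
        pm = ms.stationary_distribution(4.0, ms.CASES["case1"])
        np.testing.assert_allclose(pm, np.full(5, 0.2), rtol=1e-12)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            ms.stationary_distribution(-1.0, ms.CASES["case1"])

    def test_probabilities_renormalised_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="cheradapt.multisite"):
            case = ms.MultisiteCase((0.3, 0.3, 0.3, 0.2), "off-by-0.1")
        assert sum(case.P) == pytest.approx(1.0, abs=1e-12)
        assert caplog.records

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(theta=st.floats(1e-3, 1e3),
           raw=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_matches_birth_death_null_space(self, theta, raw):
        P = tuple(x / sum(raw) for x in raw)
        case = ms.MultisiteCase(P)
        pm = ms.stationary_distribution(theta, case)
        np.testing.assert_allclose(pm, birth_death_stationary(theta, P),
                                   atol=1e-12)


class TestSaturationCurve:
    def test_pm4_trivials(self):
        assert ms.pm4(0.0, ms.CASES["case1"]) == 0.0
        assert ms.pm4(4.0, ms.CASES["case1"]) == pytest.approx(0.2)

    def test_pm4_strictly_increasing(self):
        grid = np.geomspace(1e-2, 1e4, 60)
        for case in ms.CASES.values():
            vals = [ms.pm4(t, case) for t in grid]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_theta_at_pm4_round_trip(self):
        for case in ms.CASES.values():
            for target in (0.1, 0.5, 0.9):
                t = ms.theta_at_pm4(target, case)
                assert ms.pm4(t, case) == pytest.approx(target, abs=1e-9)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            ms.theta_at_pm4(0.0, ms.CASES["case1"])
        with pytest.raises(ValueError):
            ms.theta_at_pm4(1.0, ms.CASES["case1"])

    def test_mean_m_increases_from_zero_to_four(self):
        case = ms.CASES["case4"]
        grid = np.geomspace(1e-4, 1e8, 80)
        means = [ms.mean_and_sigma(t, case)[0] for t in grid]
        assert all(b > a for a, b in zip(means, means[1:]))
        assert means[0] < 0.01 and means[-1] > 3.99


class TestHillCoefficient:
    def test_single_site_is_exactly_hyperbolic(self):
        # pm1 = theta/(1+theta): theta_0.1 = 1/9, theta_0.9 = 9, H = 1
        case = ms.MultisiteCase((1.0,), "single")
        assert ms.theta_at_pm4(0.1, case) == pytest.approx(1 / 9, rel=1e-9)
        assert ms.theta_at_pm4(0.9, case) == pytest.approx(9.0, rel=1e-9)
        assert ms.hill_coefficient(case) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("name,H", [("case1", 1.7), ("case2", 1.3),
                                        ("case3", 2.2), ("case4", 1.1)])
    def test_printed_hill_coefficients(self, name, H):
        assert ms.hill_coefficient(ms.CASES[name]) == pytest.approx(
            H, rel=0.03)

    def test_robustness_ordering(self):
        H = {n: ms.hill_coefficient(c) for n, c in ms.CASES.items()}
        assert H["case4"] < H["case2"] < H["case1"] < H["case3"]
        t01 = {n: ms.theta_at_pm4(0.1, c) for n, c in ms.CASES.items()}
        assert t01["case4"] > t01["case2"] > max(t01["case1"], t01["case3"])


class TestThresholds:
    @pytest.mark.parametrize("name,t01", [("case1", 3.0), ("case3", 3.2),
                                          ("case4", 65.6)])
    def test_printed_theta_thresholds(self, name, t01):
        assert ms.theta_at_pm4(0.1, ms.CASES[name]) == pytest.approx(
            t01, rel=0.03)

    def test_case2_theta_threshold_known_print_deviation(self):
        """The printed 5.3 differs from the recomputed 5.208 by ~1.7%,
        a print-level rounding; asserted at 3% rather than loosening the
        other thresholds."""
        t = ms.theta_at_pm4(0.1, ms.CASES["case2"])
        assert t == pytest.approx(5.3, rel=0.03)
        assert t == pytest.approx(5.208, abs=0.001)

    @pytest.mark.parametrize("name,m01", [("case1", 1.4), ("case3", 0.9),
                                          ("case4", 2.8)])
    def test_printed_mean_m_thresholds(self, name, m01):
        assert ms.m_threshold(ms.CASES[name], 0.1) == pytest.approx(
            m01, rel=0.03)

    def test_threshold_limit_at_full_saturation(self):
        assert ms.m_threshold(ms.CASES["case1"], 0.999) > 3.9

    def test_case4_saturation_probability_at_threshold(self):
        t = ms.theta_at_pm4(0.1, ms.CASES["case4"])
        pm = ms.stationary_distribution(t, ms.CASES["case4"])
        assert pm[4] == pytest.approx(0.1, abs=1e-9)


class TestScans:
    def test_case4_sharply_peaked_at_mean_two(self):
        """At <m> = 2 the tether-matched case concentrates near m = 2
        with the least probability at the m = 0 and 4 boundaries."""
        boundary = {}
        for name, case in ms.CASES.items():
            pm = ms.stationary_distribution(ms.theta_at_mean(2.0, case),
                                            case)
            boundary[name] = pm[0] + pm[4]
            if name == "case4":
                assert np.argmax(pm) == 2
                assert pm[2] > 0.5
                assert pm[0] < 0.02 and pm[4] < 0.01
        assert boundary["case4"] == min(boundary.values())

    def test_case3_sigma_exceeds_case4_everywhere(self):
        for mean in np.linspace(0.3, 3.7, 15):
            s3 = ms.mean_and_sigma(
                ms.theta_at_mean(mean, ms.CASES["case3"]),
                ms.CASES["case3"])[1]
            s4 = ms.mean_and_sigma(
                ms.theta_at_mean(mean, ms.CASES["case4"]),
                ms.CASES["case4"])[1]
            assert s3 > s4

    def test_scan_rows_normalised(self):
        scans = ms.scan_cases(np.geomspace(0.1, 100, 30))
        for scan in scans.values():
            np.testing.assert_allclose(scan.pm.sum(axis=1), 1.0, rtol=1e-12)
            df = scan.to_frame()
            assert {"theta", "pm0", "pm4", "mean_m", "sigma_m"} <= set(
                df.columns)

    def test_five_site_generalisation(self):
        # Tsr-like five-site case runs through the same machinery
        case = ms.MultisiteCase((0.5, 0.25, 0.15, 0.07, 0.03), "tsr-like")
        pm = ms.stationary_distribution(10.0, case)
        assert pm.size == 6
        assert pm.sum() == pytest.approx(1.0)
        assert ms.hill_coefficient(case) > 0
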