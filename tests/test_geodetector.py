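import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vegtrend import (StrataAssignment, discretize, ecological_detect,
                      factor_q, interaction_detect, optimal_discretize,
                      risk_detect)
from vegtrend.geodetector import (DISCRETIZE_METHODS, DetectorError,
                                  _categorize_interaction, detector_report)


def brute_q(y, labels):
    """Grouped-loop oracle for q = 1 - SSW/SST."""
    y = np.asarray(y, dtype=float)
    sst = sum((v - y.mean()) ** 2 for v in y)
    ssw = 0.0
    for h in np.unique(labels):
        yh = y[labels == h]
        ssw += sum((v - yh.mean()) ** 2 for v in yh)
    return 1.0 - ssw / sst


class TestFactorQ:
    def test_perfect_stratification(self):
        r = factor_q([1, 1, 2, 2], StrataAssignment([1, 1, 2, 2]))
        assert r.q == pytest.approx(1.0)

    def test_uninformative_stratification(self):
        r = factor_q([1, 2, 1, 2], StrataAssignment([1, 1, 2, 2]))
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums(self):
        r = factor_q([1, 2, 3, 6], StrataAssignment([1, 1, 2, 2]))
        assert r.SST == pytest.approx(14.0)
        assert r.SSW == pytest.approx(5.0)
        assert r.q == pytest.approx(9 / 14)

    def test_constant_response_rejected(self):
        with pytest.raises(DetectorError, match="SST"):
            factor_q([3, 3, 3, 3], StrataAssignment([1, 1, 2, 2]))

    def test_single_stratum_rejected(self):
        with pytest.raises(DetectorError):
            factor_q([1, 2, 3], StrataAssignment([1, 1, 1]))

    def test_oracle_and_range_on_random_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            L = int(rng.integers(2, 6))
            y = rng.normal(0, 1, n)
            labels = rng.integers(1, L + 1, n)
            if np.unique(labels).size < 2:
                continue
            s = StrataAssignment(labels)
            q = factor_q(y, s, p_method="none").q
            assert abs(q - brute_q(y, s.labels)) < 1e-12
            assert -1e-12 <= q <= 1 + 1e-12

    def test_affine_invariance(self, rng):
        y = rng.normal(0, 1, 100)
        s = StrataAssignment(rng.integers(1, 4, 100))
        q0 = factor_q(y, s, p_method="none").q
        q1 = factor_q(3.7 * y - 2.2, s, p_method="none").q
        assert q1 == pytest.approx(q0, abs=1e-9)

    def test_refinement_never_decreases_q(self, rng):
        y = rng.normal(0, 1, 120)
        labels = rng.integers(1, 4, 120)
        s = StrataAssignment(labels.copy())
        q0 = factor_q(y, s, p_method="none").q
        # split stratum 1 randomly into two
        refined = labels.copy()
        in1 = np.flatnonzero(labels == 1)
        refined[in1[rng.random(in1.size) < 0.5]] = 10
        q1 = factor_q(y, StrataAssignment(refined), p_method="none").q
        assert q1 >= q0 - 1e-12

    def test_permutation_p_small_for_real_effect(self, rng):
        labels = rng.integers(1, 3, 200)
        y = (labels == 2) * 2.0 + rng.normal(0, 0.5, 200)
        r = factor_q(y, StrataAssignment(labels), p_method="perm",
                     n_perm=199, seed=1)
        assert r.p_value < 0.01

    def test_ncf_p_large_under_null(self, rng):
        y = rng.normal(0, 1, 300)
        s = StrataAssignment(rng.integers(1, 4, 300))
        r = factor_q(y, s, p_method="ncf")
        assert 0.0 <= r.p_value <= 1.0


class TestDiscretize:
    def test_equal_width_split(self):
        s = discretize(np.arange(1, 11, dtype=float), "equal", 2)
        assert s.break_spec["breaks"] == [5.5]
        assert np.bincount(s.labels)[1:].tolist() == [5, 5]

    def test_quantile_equal_counts(self):
        s = discretize(np.arange(1, 11, dtype=float), "quantile", 5)
        assert np.bincount(s.labels)[1:].tolist() == [2, 2, 2, 2, 2]

    def test_natural_breaks_finds_gap(self):
        x = np.array([1, 2, 3, 100, 101, 102], dtype=float)
        s = discretize(x, "natural_breaks", 2)
        assert 3 < s.break_spec["breaks"][0] < 100
        assert s.labels.tolist() == [1, 1, 1, 2, 2, 2]

    def test_natural_breaks_matches_exhaustive_sse(self, rng):
        x = np.sort(rng.normal(0, 1, 30))
        s = discretize(x, "natural_breaks", 2)
        # exhaustive single-break minimization of within-class SSE
        best = min(range(1, 30), key=lambda i: np.sum((x[:i] - x[:i].mean()) ** 2)
                   + np.sum((x[i:] - x[i:].mean()) ** 2))
        assert s.labels.tolist() == [1] * best + [2] * (30 - best)

    @pytest.mark.parametrize("method", DISCRETIZE_METHODS)
    def test_all_methods_produce_valid_strata(self, method, rng):
        x = rng.gamma(2.0, 1.0, 200)
        s = discretize(x, method, 4)
        assert s.L >= 2
        assert s.labels.min() == 1 and s.labels.max() == s.L
        assert all(np.sum(s.labels == h) > 0 for h in range(1, s.L + 1))

    def test_constant_covariate_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            s = discretize(np.ones(10), "equal", 3)
        assert s.L == 1 and not s.break_spec["usable"]

    def test_k_below_two_rejected(self):
        with pytest.raises(DetectorError):
            discretize(np.arange(10.0), "equal", 1)


class TestOptimalDiscretize:
    def test_step_function_reaches_q_one(self, rng):
        levels = rng.integers(0, 3, 300)
        x = levels + rng.uniform(0, 0.8, 300)  # separable level ranges
        y = levels.astype(float)  # 3 exact levels
        s, q = optimal_discretize(y, x)
        assert q == pytest.approx(1.0)

    def test_independent_covariate_gives_small_q(self, rng):
        y = rng.normal(0, 1, 1000)
        x = rng.uniform(0, 1, 1000)
        _, q = optimal_discretize(y, x)
        assert q < 0.05

    def test_matches_exhaustive_grid(self, rng):
        y = rng.normal(0, 1, 150)
        x = rng.uniform(0, 1, 150)
        s, q = optimal_discretize(y, x)
        best = -1.0
        for k in range(3, 9):
            for m in DISCRETIZE_METHODS:
                try:
                    cand = discretize(x, m, k)
                except DetectorError:
                    continue
                if cand.L >= 2:
                    best = max(best, factor_q(y, cand, p_method="none").q)
        assert q == pytest.approx(best, abs=1e-12)


class TestInteraction:
    def test_xor_nonlinear_enhancement(self):
        s1 = StrataAssignment(np.array([1, 1, 2, 2] * 10))
        s2 = StrataAssignment(np.array([1, 2, 1, 2] * 10))
        y = (s1.labels == s2.labels).astype(float)
        r = interaction_detect(y, s1, s2)
        assert r.q1 == pytest.approx(0.0, abs=1e-12)
        assert r.q2 == pytest.approx(0.0, abs=1e-12)
        assert r.q12 == pytest.approx(1.0)
        assert r.category == "nonlinear enhancement"

    def test_duplicated_factor_two_factor_enhancement(self, rng):
        labels = rng.integers(1, 4, 200)
        y = labels * 1.0 + rng.normal(0, 0.5, 200)
        s = StrataAssignment(labels)
        r = interaction_detect(y, s, StrataAssignment(labels.copy()))
        assert r.q12 == pytest.approx(r.q1, abs=1e-12)
        assert r.category == "two-factor enhancement"

    def test_additive_construction_at_least_max(self, rng):
        l1 = rng.integers(1, 4, 500)
        l2 = rng.integers(1, 4, 500)
        y = l1 * 1.0 + l2 * 0.7 + rng.normal(0, 0.5, 500)
        r = interaction_detect(y, StrataAssignment(l1), StrataAssignment(l2))
        assert r.q12 >= max(r.q1, r.q2) - 1e-12

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_category_function_total(self, q1, q2, q12):
        cat = _categorize_interaction(q1, q2, q12)
        assert cat in ("nonlinear weaken", "single-factor nonlinear weaken",
                       "two-factor enhancement", "independent",
                       "nonlinear enhancement")


class TestEcologicalDetect:
    def test_hand_example_f_ratio(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        s1 = StrataAssignment([1, 1, 2, 2])   # SSW = 5
        s2 = StrataAssignment([2, 2, 1, 2])   # SSW = 14 (= SST)
        r = ecological_detect(y, s1, s2)
        assert r.F == pytest.approx(5 / 14, abs=1e-12)
        assert not r.significant  # critical F(3,3) ~ 9.28

    def test_same_factor_f_one(self, rng):
        y = rng.normal(0, 1, 50)
        labels = rng.integers(1, 4, 50)
        r = ecological_detect(y, StrataAssignment(labels),
                              StrataAssignment(labels.copy()))
        assert r.F == pytest.approx(1.0)
        assert not r.significant

    def test_zero_ssw_degenerate(self):
        y = np.array([1.0, 1.0, 2.0, 2.0])
        s_perfect = StrataAssignment([1, 1, 2, 2])
        s_other = StrataAssignment([1, 2, 1, 2])
        r = ecological_detect(y, s_other, s_perfect)
        assert np.isinf(r.F) and r.significant and r.degenerate


class TestRiskDetect:
    def test_hand_welch_example(self):
        r = risk_detect(np.array([1.0, 2.0, 3.0, 6.0]),
                        StrataAssignment([1, 1, 2, 2]))
        assert r.mean_h.tolist() == [1.5, 4.5]
        assert r.t_matrix[0, 1] == pytest.approx(-3 / np.sqrt(2.5), abs=1e-3)
        assert r.df_matrix[0, 1] == pytest.approx(1.2195, abs=1e-3)
        assert r.best_stratum == 2

    def test_identical_strata_t_zero(self):
        y = np.array([1.0, 2.0, 1.0, 2.0])
        r = risk_detect(y, StrataAssignment([1, 1, 2, 2]))
        assert r.t_matrix[0, 1] == 0.0
        assert not r.sig_matrix[0, 1]

    def test_antisymmetry_and_argmax(self, rng):
        labels = rng.integers(1, 4, 90)
        y = np.array([0.1, 0.8, 0.3])[labels - 1] + rng.normal(0, 0.05, 90)
        r = risk_detect(y, StrataAssignment(labels))
        assert r.best_stratum == 2
        assert r.t_matrix[0, 1] == pytest.approx(-r.t_matrix[1, 0])

    def test_small_stratum_excluded_from_tests(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        r = risk_detect(y, StrataAssignment([1, 1, 2, 2, 3]))
        assert np.isnan(r.t_matrix[0, 2])
        assert r.mean_h[2] == 10.0  # still reported in means


class TestDetectorReport:
    def test_full_report_structure(self, rng):
        n = 300
        labels = rng.integers(1, 4, n)
        x1 = labels + rng.random(n)
        y = labels * 1.0 + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"ndvi": y, "x1": x1, "cat": labels})
        rep = detector_report(table, "ndvi", factor_types={"cat": "categorical"},
                              k_range=range(3, 5))
        assert set(rep) == {"factor", "interaction", "ecological", "risk"}
        assert len(rep["factor"]) == 2
        assert len(rep["interaction"]) == 1
        assert rep["factor"]["q"].between(0, 1).all()
        assert rep["ecological"]["significant"].isin(["Y", "N"]).all()
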