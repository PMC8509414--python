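"""Hill regulation-curve fitting: IC50/EC50, X-fold, condition comparison."""

import itertools

import numpy as np
import pytest

from casensor import (DoseResponseSeries, NoiseSpec, compare_conditions,
                      fit_activation, fit_ca_inhibition, gen_dose_response,
                      hill_activation, hill_inhibition, x_fold)


class TestHillModels:
    def test_inhibition_midpoint_definitional(self):
        a = hill_inhibition(0.26e-6, 0.26e-6, 2.05, 8.4, 1.0)
        assert a == pytest.approx((8.4 + 1.0) / 2)

    def test_activation_zero_dose_is_bottom(self):
        assert hill_activation(0.0, 1.6e-6, 2.0, 4.9, 1.0) == 1.0

    def test_activation_midpoint_definitional(self):
        a = hill_activation(1.6e-6, 1.6e-6, 2.0, 4.9, 1.0)
        assert a == pytest.approx((4.9 + 1.0) / 2)


class TestInhibitionFit:
    def test_noise_free_round_trip(self):
        s = gen_dose_response(0.26e-6, 2.05, 8.4, 1.0, "free_ca", noise=NoiseSpec())
        f = fit_ca_inhibition(s)
        assert f.converged
        assert f.half_point == pytest.approx(0.26e-6, rel=1e-3)
        assert f.hill == pytest.approx(2.05, rel=1e-3)
        assert f.a_top == pytest.approx(8.4, rel=1e-3)
        assert f.a_bottom == pytest.approx(1.0, rel=1e-3)

    def test_unit_rescaling_leaves_midpoint_and_h(self):
        s = gen_dose_response(0.52e-6, 1.77, 4.9, 1.0, "free_ca",
                              noise=NoiseSpec("proportional", 0.05, 7))
        f1 = fit_ca_inhibition(s)
        s2 = DoseResponseSeries(dose=s.dose, activity=s.activity * 37.0, axis="free_ca")
        f2 = fit_ca_inhibition(s2)
        assert f2.half_point == pytest.approx(f1.half_point, rel=1e-4)
        assert f2.hill == pytest.approx(f1.hill, rel=1e-4)
        assert f2.a_top == pytest.approx(37.0 * f1.a_top, rel=1e-4)

    def test_grid_search_oracle_h1(self):
        """Brute-force RSS profile over (IC50, h) locates the same optimum."""
        s = gen_dose_response(1e-6, 1.0, 5.0, 1.0, "free_ca",
                              noise=NoiseSpec("proportional", 0.03, 11))
        f = fit_ca_inhibition(s)
        mids = np.geomspace(1e-7, 1e-5, 120)
        hs = np.linspace(0.3, 3.0, 100)
        best = (np.inf, None, None)
        for m in mids:
            for h in hs:
                # model is linear in (bottom, top): profile them out by OLS
                basis = 1.0 / (1.0 + (s.dose / m) ** h)
                X = np.column_stack([1.0 - basis, basis])
                coef, rss_arr, *_ = np.linalg.lstsq(X, s.activity, rcond=None)
                rss = float(rss_arr[0]) if len(rss_arr) else \
                    float(((X @ coef - s.activity) ** 2).sum())
                if rss < best[0]:
                    best = (rss, m, h)
        # profiled (IC50, h) grid vs free 4-par fit: optima agree to grid step
        assert abs(np.log(f.half_point) - np.log(best[1])) < 2 * np.log(mids[1] / mids[0])
        assert abs(f.hill - best[2]) < 2 * (hs[1] - hs[0])

    def test_rising_data_flagged(self):
        s = DoseResponseSeries(dose=np.geomspace(1e-8, 1e-4, 8),
                               activity=np.linspace(1, 5, 8), axis="free_ca")
        f = fit_ca_inhibition(s)
        assert not f.converged

    def test_wrong_axis_rejected(self):
        s = gen_dose_response(1.6e-6, 2.0, 4.9, 1.0, "activator_conc", noise=NoiseSpec())
        with pytest.raises(ValueError):
            fit_ca_inhibition(s)


class TestActivationFit:
    def test_noise_free_round_trip(self):
        s = gen_dose_response(1.6e-6, 2.0, 4.9, 1.0, "activator_conc", noise=NoiseSpec())
        f = fit_activation(s)
        assert f.converged
        assert f.half_point == pytest.approx(1.6e-6, rel=1e-3)

    def test_zero_dose_baseline_consistency(self):
        s = gen_dose_response(1.6e-6, 2.0, 4.9, 1.0, "activator_conc",
                              noise=NoiseSpec("proportional", 0.05, 3))
        f = fit_activation(s)
        zero_activity = s.activity[s.dose == 0][0]
        tol = 3 * f.se.get("a_bottom", 0.3) + 0.3
        assert abs(f.a_bottom - zero_activity) < tol

    def test_doubling_activities_scales_plateaus_only(self):
        s = gen_dose_response(1.6e-6, 2.0, 4.9, 1.0, "activator_conc", noise=NoiseSpec())
        f1 = fit_activation(s)
        s2 = DoseResponseSeries(dose=s.dose, activity=2 * s.activity, axis="activator_conc")
        f2 = fit_activation(s2)
        assert f2.half_point == pytest.approx(f1.half_point, rel=1e-4)
        assert f2.hill == pytest.approx(f1.hill, rel=1e-4)
        assert f2.a_top == pytest.approx(2 * f1.a_top, rel=1e-4)
        assert f2.a_bottom == pytest.approx(2 * f1.a_bottom, rel=1e-3, abs=1e-6)

    def test_inhibition_fit_of_reflected_activation_data(self):
        """Fitting the mirrored response recovers the same midpoint."""
        doses = np.geomspace(1e-8, 1e-4, 12)
        act = hill_activation(doses, 1e-6, 1.5, 6.0, 1.0)
        mirrored = 7.0 - act  # decreasing curve, same midpoint dose
        s = DoseResponseSeries(dose=doses, activity=mirrored, axis="free_ca")
        f = fit_ca_inhibition(s)
        assert f.half_point == pytest.approx(1e-6, rel=1e-3)
        assert f.hill == pytest.approx(1.5, rel=1e-3)


class TestXFold:
    def test_no_dynamic_range(self):
        assert x_fold(2.0, 2.0) == 0.0

    @pytest.mark.parametrize("ratio,expected", [(8.4, 7.4), (4.9, 3.9)])
    def test_ratio_arithmetic(self, ratio, expected):
        assert x_fold(ratio * 3.0, 3.0) == pytest.approx(expected)

    def test_zero_min_rejected(self):
        with pytest.raises(ValueError):
            x_fold(5.0, 0.0)


class TestCompareConditions:
    def test_identical_groups_degenerate(self):
        out = compare_conditions([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert out == {"t": 0.0, "p": 1.0, "degenerate": True}

    def test_equal_groups_t_zero(self):
        out = compare_conditions([1, 2, 3], [1, 2, 3])
        assert out["t"] == pytest.approx(0.0)

    def test_small_groups_required(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])

    def test_against_exhaustive_permutation_oracle(self):
        """t-test direction/magnitude consistent with the exact permutation
        null on a tiny two-group design."""
        a = [4.1, 4.4, 4.0]
        b = [2.9, 3.1, 3.3]
        out = compare_conditions(a, b)
        pooled = a + b
        obs = np.mean(a) - np.mean(b)
        count = 0
        total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            if abs(np.mean(ga) - np.mean(gb)) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        p_perm = count / total
        assert out["t"] > 0  # group A larger, consistent direction
        assert out["p"] < 0.05 and p_perm <= 0.15  # both calls: clearly separated
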