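"""Enzyme-kinetics fits and the surrounding statistical tests."""

import itertools
import math

import numpy as np
import pytest

from evosuppress.kinetics import (
    KineticsDataset,
    competition_check,
    fit_ec50,
    fit_mm,
    fit_quadratic,
    forward_reverse_ratio,
    mann_whitney,
    standard_curve_quantify,
    welch_t,
)

GRID = np.array([0.0125, 0.025, 0.05, 0.1, 0.2, 0.3, 0.45, 0.6])


def mm_dataset(vmax=10.0, km=0.1, grid=GRID, noise=None, seed=0, enzyme="wt"):
    rate = vmax * grid / (km + grid)
    if noise:
        rate = rate + np.random.default_rng(seed).normal(0, noise, size=grid.shape)
    return KineticsDataset(enzyme, grid, rate)


class TestFitMM:
    def test_noiseless_exact_recovery(self):
        fit = fit_mm(mm_dataset())
        assert fit.vmax == pytest.approx(10.0, rel=1e-8)
        assert fit.km == pytest.approx(0.1, rel=1e-8)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_half_saturation_identity(self):
        fit = fit_mm(mm_dataset())
        rate_at_km = fit.vmax * fit.km / (fit.km + fit.km)
        assert rate_at_km == pytest.approx(fit.vmax / 2)

    def test_row_order_invariance(self):
        ds = mm_dataset()
        perm = np.random.default_rng(1).permutation(len(GRID))
        shuffled = KineticsDataset("wt", np.asarray(ds.substrate_mM)[perm], np.asarray(ds.rate)[perm])
        f1, f2 = fit_mm(ds), fit_mm(shuffled)
        assert f1.vmax == pytest.approx(f2.vmax, rel=1e-9)
        assert f1.km == pytest.approx(f2.km, rel=1e-9)

    def test_kcat_conversion_explicit(self):
        fit = fit_mm(mm_dataset(), enzyme_mg_per_mol=63e6)
        # kcat = 10 umol/min/mg * 63e6 mg/mol / 60 s/min * 1e-6 mol/umol
        assert fit.kcat_over_km == pytest.approx(10 * 63e6 / 60 * 1e-6 / 0.1, rel=1e-6)
        assert fit_mm(mm_dataset()).kcat_over_km is None

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_mm(KineticsDataset("wt", GRID, np.zeros_like(GRID)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mm(KineticsDataset("wt", GRID[:3], GRID[:3]))

    def test_ci_coverage_and_bias_monte_carlo(self):
        """Across simulated noisy assays (noise = 2% of Vmax) the 95% CI
        covers the true Vmax at ~95% and the estimate is unbiased."""
        from evosuppress.synthdata import gen_kinetics

        vmax, km, noise = 10.0, 0.1, 0.2
        n_sims = 500
        covered, ests = 0, []
        for seed in range(n_sims):
            df = gen_kinetics(vmax, km, GRID, noise, seed=seed)
            fit = fit_mm(KineticsDataset("sim", df["substrate_mM"], df["rate"]))
            ests.append(fit.vmax)
            covered += abs(fit.vmax - vmax) <= fit.vmax_ci95
        bias = np.mean(ests) - vmax
        assert abs(bias) < 0.1
        coverage = covered / n_sims
        assert abs(coverage - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n_sims) + 0.01


class TestFitEC50:
    def test_noiseless_exact(self):
        A = np.array([0.5, 1, 2, 5, 10, 20, 50])
        rate = 8.0 * A / (5.0 + A)
        res = fit_ec50(A, rate)
        assert res["ec50"] == pytest.approx(5.0, rel=1e-8)
        assert res["vmax"] == pytest.approx(8.0, rel=1e-8)

    def test_half_maximum_definition(self):
        A = np.array([1.0, 2, 5, 10, 40])
        res = fit_ec50(A, 6.0 * A / (5.0 + A))
        a = res["ec50"]
        assert res["vmax"] * a / (a + a) == pytest.approx(res["vmax"] / 2)

    def test_decreasing_data_rejected(self):
        A = np.array([1.0, 2, 5, 10])
        with pytest.raises(ValueError, match="decrease"):
            fit_ec50(A, np.array([10.0, 8, 5, 2]))

    def test_unsaturated_curve_flagged(self):
        A = np.array([0.01, 0.02, 0.04, 0.08])
        res = fit_ec50(A, 10.0 * A / (5.0 + A))
        assert res["warning"] is not None


class TestCompetitionCheck:
    def test_no_effect(self):
        ctrl = mm_dataset()
        comp = {c: mm_dataset() for c in (10.0, 50.0, 200.0)}
        res = competition_check(ctrl, comp)
        assert res["flag"] == "no inhibition"
        for c in (10.0, 50.0, 200.0):
            assert res["ratios"][c]["mean_ratio"] == pytest.approx(1.0)

    def test_halved_rates_flag_inhibition(self):
        ctrl = mm_dataset()
        comp = {
            10.0: KineticsDataset("wt", GRID, np.asarray(ctrl.rate) * 0.8),
            50.0: KineticsDataset("wt", GRID, np.asarray(ctrl.rate) * 0.5),
            200.0: KineticsDataset("wt", GRID, np.asarray(ctrl.rate) * 0.3),
        }
        assert competition_check(ctrl, comp)["flag"] == "inhibition"

    def test_single_level_monotonicity_undefined(self):
        ctrl = mm_dataset()
        res = competition_check(ctrl, {10.0: mm_dataset()})
        assert res["monotonicity"] == "undefined"

    def test_mismatched_grids_rejected(self):
        ctrl = mm_dataset()
        with pytest.raises(ValueError):
            competition_check(ctrl, {10.0: mm_dataset(grid=GRID[:-1])})


class TestForwardReverseRatio:
    def test_equal_rates(self):
        assert forward_reverse_ratio([3.0, 4.0], [3.0, 4.0]) == (
            pytest.approx(1.0),
            pytest.approx(0.0),
        )

    def test_hand_computed(self):
        mean, sd = forward_reverse_ratio([2.0, 4.0], [1.0, 1.0])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2), abs=0.005)

    def test_three_replicates(self):
        mean, sd = forward_reverse_ratio([6.0, 8.0, 8.2], [1.0, 1.0, 1.0])
        assert mean == pytest.approx(7.4, abs=0.01)
        assert sd == pytest.approx(1.22, abs=0.01)

    def test_zero_reverse_excluded(self):
        with pytest.warns(UserWarning):
            mean, _ = forward_reverse_ratio([2.0, 4.0, 9.0], [1.0, 1.0, 0.0])
        assert mean == pytest.approx(3.0)


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form(self):
        # means 10 vs 12, sds 1 vs 2, n=10 each
        x = np.array([10 - 1, 10 + 1] * 5, dtype=float)
        y = np.array([12 - 2, 12 + 2] * 5, dtype=float)
        # force exact sample sds of 1 and 2
        x = 10 + (x - x.mean()) / x.std(ddof=1)
        y = 12 + 2 * (y - y.mean()) / y.std(ddof=1)
        t, df, p = welch_t(x, y)
        se = math.sqrt(1 / 10 + 4 / 10)
        assert t == pytest.approx(-2 / se, rel=1e-10)
        assert t == pytest.approx(-2.828, abs=0.001)
        assert df == pytest.approx((0.1 + 0.4) ** 2 / (0.1**2 / 9 + 0.4**2 / 9), rel=1e-10)
        assert df == pytest.approx(13.24, abs=0.01)

    def test_df_bounded_by_pooled(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(0, 1, 6), rng.normal(0, 3, 9)
            _, df, _ = welch_t(x, y)
            assert df <= len(x) + len(y) - 2 + 1e-9


class TestMannWhitney:
    def test_complete_separation_small_n(self):
        W, p = mann_whitney([4.0, 5.0, 6.0], [1.0, 2.0, 3.0])
        assert W == 9.0
        assert p == pytest.approx(0.1)

    def test_enumeration_oracle_small_samples(self):
        """Exact p matches full enumeration of rank arrangements."""
        x, y = [1.3, 2.7, 4.1], [0.6, 2.0, 3.5, 5.2]
        W, p = mann_whitney(x, y)
        n, m = len(x), len(y)
        pooled = sorted(x + y)
        count_extreme = 0
        total = 0
        w_obs = sum(1 for xi in x for yj in y if xi > yj)
        for positions in itertools.combinations(range(n + m), n):
            xs = [pooled[i] for i in positions]
            ys = [pooled[i] for i in range(n + m) if i not in positions]
            w = sum(1 for xi in xs for yj in ys if xi > yj)
            total += 1
            if abs(w - n * m / 2) >= abs(w_obs - n * m / 2):
                count_extreme += 1
        assert W == w_obs
        assert p == pytest.approx(count_extreme / total)

    def test_identical_multisets(self):
        W, _ = mann_whitney([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert W == 4.5  # nm/2 with ties

    def test_swap_antisymmetry(self):
        x, y = [5.0, 7.0, 9.0, 11.0], [4.0, 6.0, 8.0]
        Wxy, _ = mann_whitney(x, y)
        Wyx, _ = mann_whitney(y, x)
        assert Wxy + Wyx == len(x) * len(y)


class TestFitQuadratic:
    def test_exact_recovery(self):
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = 1 + 2 * x - 0.5 * x**2
        fit = fit_quadratic(x, y)
        assert (fit.b0, fit.b1, fit.b2) == (
            pytest.approx(1.0),
            pytest.approx(2.0),
            pytest.approx(-0.5),
        )
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        fit = fit_quadratic([0.0, 1, 2, 3], [5.0, 5, 5, 5])
        assert fit.b1 == pytest.approx(0.0, abs=1e-10)
        assert fit.b2 == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == 0.0

    def test_f_and_r2_match_sum_of_squares_oracle(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 8)
        y = 3 + 0.5 * x - 0.1 * x**2 + rng.normal(0, 0.5, 8)
        fit = fit_quadratic(x, y)
        X = np.column_stack([np.ones(8), x, x**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        ss_res = float(((y - X @ beta) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        F = ((ss_tot - ss_res) / 2) / (ss_res / 5)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.F == pytest.approx(F, rel=1e-10)
        assert (fit.df_model, fit.df_resid) == (2, 5)

    def test_quadratic_beats_linear_on_humps(self):
        """On hump-shaped data the quadratic wins on adjusted R^2 in nearly
        every simulation."""
        rng = np.random.default_rng(12)
        wins = 0
        n_sims = 200
        x = np.linspace(0, 300, 7)
        for _ in range(n_sims):
            y = 14.6 + 0.046 * x - 0.00014 * x**2 + rng.normal(0, 1.0, len(x))
            q = fit_quadratic(x, y)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (intercept + slope * x)
            ss_res = (resid**2).sum()
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2_lin = 1 - ss_res / ss_tot
            r2_lin_adj = 1 - (1 - r2_lin) * (len(x) - 1) / (len(x) - 2)
            wins += q.r2_adj > r2_lin_adj
        assert wins / n_sims >= 0.95

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 2.0, 2.0], [1.0, 2, 3, 4])


class TestStandardCurve:
    def test_linear_inversion(self):
        standards = [(0.0, 0.0), (0.05, 0.1), (0.1, 0.2), (0.15, 0.3)]
        df = standard_curve_quantify(standards, [0.1])
        assert df.loc[0, "concentration"] == pytest.approx(0.05)
        assert not df.loc[0, "extrapolated"]

    def test_extrapolation_flagged(self):
        standards = [(0.0, 0.0), (0.05, 0.1), (0.1, 0.2)]
        df = standard_curve_quantify(standards, [0.5])
        assert bool(df.loc[0, "extrapolated"])

    def test_replicates_averaged_before_inversion(self):
        standards = [(0.0, 0.0), (0.05, 0.1), (0.1, 0.2)]
        df = standard_curve_quantify(standards, [[0.08, 0.1, 0.12]])
        assert df.loc[0, "concentration"] == pytest.approx(0.05)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            standard_curve_quantify([(0.0, 1.0), (0.1, 1.0), (0.2, 1.0)], [1.0])
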