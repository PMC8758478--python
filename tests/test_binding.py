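"""Two-site equilibrium solver, titration forward models, and Kd fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfapp.binding import (
    FluorParams, FluorTitration, SwTitration, TwoSiteParams, compare_models,
    fit_binding, fluor_model, fluor_model_one_site, runs_test_exact,
    solve_equilibrium, stoichiometry_select, sw_model, sw_model_one_site,
)
from lfapp.synthetic_data import (FLUOR_L_GRID, SimTitrationDesign,
                                  simulate_fluor_titration, simulate_sw_titration)

PAPER_SW = TwoSiteParams(kd1=620e-9, kd2=8.2e-6)
PAPER_FLUOR = FluorParams(f0=1.0, df1=0.10, df2=0.05, kd1=690e-9, kd2=9.4e-6)


class TestEquilibrium:
    def test_no_ligand(self):
        st_ = solve_equilibrium(2.5e-6, 0.0, 1e-6, 1e-5)
        assert st_.conc_A == 2.5e-6
        assert st_.conc_AL == st_.conc_AL2 == st_.conc_L == 0.0

    def test_weak_binding_limit(self):
        st_ = solve_equilibrium(2.5e-6, 5e-6, 1e3, 1e3)  # Kd ~ molar scale
        assert st_.conc_AL < 1e-11
        assert st_.conc_AL2 < 1e-15
        assert st_.conc_L == pytest.approx(5e-6, rel=1e-4)

    def test_against_dense_grid_oracle(self):
        """Species match a brute-force grid search over free ligand."""
        a, l, k1, k2 = 2.5e-6, 5e-6, 0.62e-6, 8.2e-6
        grid = np.linspace(0, l, 2_000_001)
        p = grid / k1 + grid ** 2 / (k1 * k2)
        a_free = a / (1 + p)
        al = a_free * grid / k1
        al2 = al * grid / k2
        l_star = grid[np.argmin(np.abs(grid + al + 2 * al2 - l))]
        st_ = solve_equilibrium(a, l, k1, k2)
        assert st_.conc_L == pytest.approx(l_star, rel=1e-4)

    @given(a=st.floats(1e-9, 1e-4), l=st.floats(1e-9, 1e-4),
           k1=st.floats(1e-9, 1e-3), k2=st.floats(1e-9, 1e-3))
    @settings(max_examples=200, deadline=None)
    def test_conservation_and_mass_action(self, a, l, k1, k2):
        """Balances hold to 1e-9 and mass action to 1e-8 relative."""
        st_ = solve_equilibrium(a, l, k1, k2)
        assert st_.conc_A + st_.conc_AL + st_.conc_AL2 == pytest.approx(a, rel=1e-9)
        assert (st_.conc_L + st_.conc_AL + 2 * st_.conc_AL2
                == pytest.approx(l, rel=1e-9))
        if st_.conc_A > 0 and st_.conc_L > 0:
            assert st_.conc_AL * k1 == pytest.approx(
                st_.conc_A * st_.conc_L, rel=1e-8)
            assert st_.conc_AL2 * k2 == pytest.approx(
                st_.conc_AL * st_.conc_L, rel=1e-8)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium(-1e-6, 1e-6, 1e-6, 1e-6)


class TestSwModel:
    def test_zero_ligand_gives_free_acceptor_s(self):
        assert sw_model(PAPER_SW, 2.5e-6, 0.0) == pytest.approx(3.9)

    def test_excess_ligand_approaches_free_ligand_s(self):
        assert sw_model(PAPER_SW, 2.5e-6, 1.0) == pytest.approx(5.1, abs=1e-3)

    def test_matches_scalar_solver(self):
        """Vectorised forward model equals the bracketing solver route."""
        p = PAPER_SW
        for l_tot in [0.5e-6, 2.5e-6, 5e-6]:
            st_ = solve_equilibrium(2.5e-6, l_tot, p.kd1, p.kd2)
            w = np.array([p.signal_weight_A, p.signal_weight_L,
                          p.signal_weight_AL, p.signal_weight_AL2])
            s = np.array([p.s_A, p.s_L, p.s_AL, p.s_AL2])
            c = st_.as_array()
            expected = np.sum(w * s * c) / np.sum(w * c)
            assert sw_model(p, 2.5e-6, l_tot) == pytest.approx(expected, rel=1e-6)

    def test_continuous_nondecreasing_while_complex_forms(self):
        l_grid = np.linspace(0, 5e-6, 200)
        sw = sw_model(PAPER_SW, 2.5e-6, l_grid)
        assert np.all(np.diff(sw) > -1e-9)
        assert np.max(np.abs(np.diff(sw))) < 0.5  # no jumps

    def test_sequential_with_huge_kd2_matches_one_site_closed_form(self):
        p = TwoSiteParams(kd1=620e-9, kd2=1e3)
        l_grid = np.linspace(0, 5e-6, 9)
        two = sw_model(p, 2.5e-6, l_grid)
        one = sw_model_one_site(620e-9, 2.5e-6, l_grid, s_AL=p.s_AL,
                                w_AL=p.signal_weight_AL)
        np.testing.assert_allclose(two, one, rtol=1e-6)

    def test_zero_weights_rejected(self):
        p = TwoSiteParams(kd1=1e-6, kd2=1e-5, signal_weight_A=0,
                          signal_weight_L=0, signal_weight_AL=0,
                          signal_weight_AL2=0)
        with pytest.raises(ValueError):
            sw_model(p, 2.5e-6, 1e-6)


class TestFluorModel:
    def test_zero_ligand_gives_baseline(self):
        assert fluor_model(PAPER_FLUOR, 2.5e-6, 0.0) == pytest.approx(1.0)

    def test_single_site_closed_form(self):
        """df2=0 with a non-binding second site reduces to the exact 1:1
        quadratic-depletion closed form."""
        p = FluorParams(f0=1.0, df1=0.2, df2=0.0, kd1=1e-6, kd2=1e3)
        l_grid = np.linspace(0, 25e-6, 15)
        two = fluor_model(p, 2.5e-6, l_grid)
        one = fluor_model_one_site(1.0, 0.2, 1e-6, 2.5e-6, l_grid)
        np.testing.assert_allclose(two, one, rtol=1e-9, atol=1e-12)

    def test_no_depletion_limit(self):
        """a_tot -> 0 gives theta_i = l/(kd_i + l) exactly."""
        l_grid = np.linspace(0, 25e-6, 9)
        f = fluor_model(PAPER_FLUOR, 0.0, l_grid)
        th1 = l_grid / (PAPER_FLUOR.kd1 + l_grid)
        th2 = l_grid / (PAPER_FLUOR.kd2 + l_grid)
        np.testing.assert_allclose(f, 1.0 + 0.10 * th1 + 0.05 * th2, rtol=1e-9)


class TestFitBinding:
    def test_noise_free_two_site_recovery(self):
        """Noise-free data return the generating Kds to 1e-4 relative."""
        design = SimTitrationDesign(noise_cv=0.0, seed=0)
        tit = simulate_sw_titration(PAPER_SW, design)
        fit = fit_binding(tit, "two-site", n_starts=8, seed=1)
        assert fit.converged
        assert fit.estimates["kd1"] == pytest.approx(620e-9, rel=1e-4)
        assert fit.estimates["kd2"] == pytest.approx(8.2e-6, rel=1e-4)

    def test_noise_free_fluor_recovery(self):
        design = SimTitrationDesign(l_tot_grid=FLUOR_L_GRID, noise_cv=0.0, seed=0)
        tit = simulate_fluor_titration(PAPER_FLUOR, design)
        fit = fit_binding(tit, "two-site", n_starts=16, seed=3)
        assert fit.estimates["kd1"] == pytest.approx(690e-9, rel=1e-3)
        assert fit.estimates["f0"] == pytest.approx(1.0, rel=1e-4)

    def test_one_site_fits_worse_on_two_site_data(self):
        design = SimTitrationDesign(noise_cv=0.01, seed=7)
        tit = simulate_sw_titration(PAPER_SW, design)
        two = fit_binding(tit, "two-site", n_starts=8, seed=2)
        one = fit_binding(tit, "one-site", n_starts=8, seed=2)
        assert two.r_squared > one.r_squared

    def test_seeded_determinism(self):
        design = SimTitrationDesign(noise_cv=0.01, seed=5)
        tit = simulate_sw_titration(PAPER_SW, design)
        a = fit_binding(tit, "two-site", n_starts=1, seed=42)
        b = fit_binding(tit, "two-site", n_starts=1, seed=42)
        assert a.estimates == b.estimates
        np.testing.assert_array_equal(a.residuals, b.residuals)

    def test_unit_rescaling_invariance(self):
        """Fitting in nM instead of M rescales the Kds and nothing else."""
        design = SimTitrationDesign(noise_cv=0.01, seed=9)
        tit = simulate_sw_titration(PAPER_SW, design)
        scaled = SwTitration(tit.points.assign(
            a_tot_molar=tit.points["a_tot_molar"] * 1e3,
            l_tot_molar=tit.points["l_tot_molar"] * 1e3))
        fit = fit_binding(tit, "two-site", n_starts=8, seed=4)
        fit_s = fit_binding(scaled, "two-site", n_starts=8, seed=4)
        assert fit_s.estimates["kd1"] == pytest.approx(1e3 * fit.estimates["kd1"],
                                                       rel=1e-3)
        assert fit_s.estimates["kd2"] == pytest.approx(1e3 * fit.estimates["kd2"],
                                                       rel=1e-3)

    def test_degenerate_data_rejected(self):
        df = pd.DataFrame({"a_tot_molar": [1e-6] * 5, "l_tot_molar": [1e-6] * 5,
                           "observable": [4.0] * 5, "sigma": [0.01] * 5})
        with pytest.raises(ValueError):
            fit_binding(SwTitration(df), "two-site")


class TestModelComparison:
    def test_identical_fits_no_preference(self):
        design = SimTitrationDesign(noise_cv=0.01, seed=3)
        tit = simulate_sw_titration(PAPER_SW, design)
        fit = fit_binding(tit, "two-site", n_starts=4, seed=1)
        cmp = compare_models(fit, fit)
        assert cmp.delta_r_squared == 0.0
        assert cmp.preferred == "none"

    def test_two_site_preferred_and_one_site_residuals_clustered(self):
        """On a 16-point two-site titration the one-site fit leaves
        sign-clustered residuals that fail the runs test at alpha=0.05."""
        design = SimTitrationDesign(
            l_tot_grid=tuple(np.linspace(0, 5e-6, 16)), noise_cv=0.005, seed=2)
        tit = simulate_sw_titration(PAPER_SW, design)
        two = fit_binding(tit, "two-site", n_starts=8, seed=1)
        one = fit_binding(tit, "one-site", n_starts=8, seed=1)
        cmp = compare_models(one, two)
        assert cmp.preferred == "two-site"
        assert cmp.runs_p_one_site < 0.05

    def test_mismatched_data_rejected(self):
        d1 = SimTitrationDesign(noise_cv=0.01, seed=1)
        d2 = SimTitrationDesign(noise_cv=0.01, seed=2)
        f1 = fit_binding(simulate_sw_titration(PAPER_SW, d1), "one-site",
                         n_starts=2, seed=0)
        f2 = fit_binding(simulate_sw_titration(PAPER_SW, d2), "two-site",
                         n_starts=2, seed=0)
        with pytest.raises(ValueError):
            compare_models(f1, f2)


class TestRunsTest:
    def test_matches_exact_enumeration(self):
        """p for a +/- sequence equals enumeration over all arrangements."""
        seq = [1, 1, -1, -1, 1, 1, -1, -1]
        n1 = sum(1 for s in seq if s > 0)

        def runs(arr):
            return 1 + sum(arr[i] != arr[i - 1] for i in range(1, len(arr)))

        from itertools import combinations
        n = len(seq)
        r_obs = runs(seq)
        count = total = 0
        for pos in combinations(range(n), n1):
            arr = [1 if i in pos else -1 for i in range(n)]
            total += 1
            if runs(arr) <= r_obs:
                count += 1
        assert runs_test_exact(seq) == pytest.approx(count / total)

    def test_alternating_sequence_has_high_p(self):
        assert runs_test_exact([1, -1, 1, -1, 1, -1]) == pytest.approx(1.0)

    def test_fully_clustered_sequence_has_min_p(self):
        p = runs_test_exact([1] * 5 + [-1] * 5)
        assert p == pytest.approx(2 / math.comb(10, 5))


class TestStoichiometry:
    def test_one_app_two_lf(self):
        """61 + 2x79 kDa best matches the 223 kDa complex peak."""
        n_a, n_l, err = stoichiometry_select(61e3, 79e3, 223e3, 4)
        assert (n_a, n_l) == (1, 2)
        assert err < 0.02

    def test_one_to_one(self):
        assert stoichiometry_select(61e3, 79e3, 140e3, 4)[:2] == (1, 1)

    def test_exact_dimer(self):
        n_a, n_l, err = stoichiometry_select(50e3, 50e3, 100e3, 3)
        assert (n_a, n_l) == (1, 1)
        assert err == 0.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            stoichiometry_select(-1, 79e3, 223e3, 4)
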