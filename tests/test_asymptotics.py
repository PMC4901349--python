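"""Matched-asymptotics, coefficient exactness and scaling-fit tests."""

import math

import numpy as np
import pytest
import sympy as sp

import mechanoscale as ms


class TestIntermediateCoefficient:
    @pytest.mark.parametrize("d,expected", [(1, 6.0), (2, 4.0), (3, 2.0)])
    def test_closed_form(self, d, expected):
        assert ms.intermediate_coefficient(d) == expected

    def test_symbolic_uniqueness(self):
        # C a^2/r^2 solves the d-dimensional pure-quadratic equation iff
        # C = 8 - 2d (nonzero root)
        r, a, C = sp.symbols("r a C", positive=True)
        for d in (1, 2, 3):
            phi = C * a**2 / r**2
            laplacian = sp.diff(r ** (d - 1) * sp.diff(phi, r), r) / r ** (d - 1)
            roots = sp.solve(sp.simplify(laplacian - phi**2 / a**2), C)
            assert sp.Integer(8 - 2 * d) in roots

    def test_numeric_search_recovers_two(self):
        assert ms.coefficient_search(3) == pytest.approx(2.0, abs=1e-5)

    def test_1d_inner_power_law_exact(self):
        # residual of phi'' = phi^2 on 6/x^2 vanishes identically
        x = sp.symbols("x", positive=True)
        phi = 6 / x**2
        assert sp.simplify(sp.diff(phi, x, 2) - phi**2) == 0


class TestOuterPrefactorMatching:
    def test_3d_crossover_at_lambda(self):
        # slope matching puts the 3D crossover exactly at r = lambda,
        # giving A = 2e/lambda
        for lam in (100.0, 1000.0):
            assert ms.match_outer_prefactor(lam, 3) == pytest.approx(
                2 * math.e / lam, rel=1e-10
            )

    def test_3d_slope(self):
        lams = np.geomspace(1e2, 1e4, 9)
        prefs = [ms.match_outer_prefactor(l, 3) for l in lams]
        slope = np.polyfit(np.log(lams), np.log(prefs), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-10)

    def test_2d_slope(self):
        lams = np.geomspace(1e2, 1e4, 9)
        prefs = [ms.match_outer_prefactor(l, 2) for l in lams]
        slope = np.polyfit(np.log(lams), np.log(prefs), 1)[0]
        assert slope == pytest.approx(-1.5, abs=1e-10)

    def test_doubling_lambda_halves_3d_prefactor(self):
        a1 = ms.match_outer_prefactor(500.0, 3)
        a2 = ms.match_outer_prefactor(1000.0, 3)
        assert a2 / a1 == pytest.approx(0.5, rel=1e-10)


class TestPiecewiseProfile:
    def _decomp(self, lam=1000.0):
        return ms.AsymptoticDecomposition(
            r0=50.0, lambda_eff=lam, dimension=3, system_size=20000.0
        )

    def test_pieces_cross_at_twice_r0(self):
        # a^2/(r r0) = 2 a^2/r^2 at r = 2 r0
        from scipy.optimize import brentq

        d = self._decomp()
        f = lambda r: 1.0 / (r * d.r0) - 2.0 / r**2
        assert brentq(f, 10.0, 1000.0) == pytest.approx(2 * d.r0, rel=1e-12)

    def test_intermediate_value_scale(self):
        # the intermediate piece extrapolated to r = a gives C_3 = 2
        assert ms.intermediate_coefficient(3) * 1.0**2 / 1.0**2 == 2.0

    def test_separation_flag(self):
        tight = ms.AsymptoticDecomposition(
            r0=2.0, lambda_eff=4.0, dimension=3, system_size=50.0
        )
        assert not tight.separated
        assert self._decomp().separated

    def test_out_of_domain(self):
        with pytest.raises(ms.OutOfDomainError):
            ms.piecewise_profile(0.5, self._decomp())

    def test_region_integral_scalings(self):
        # the self-consistency integral int phi r^2 dr is ~ r0-dominated in
        # region 1 and ~ lambda-dominated in regions 2-3
        def region_integrals(r0, lam):
            d = ms.AsymptoticDecomposition(
                r0=r0, lambda_eff=lam, dimension=3, system_size=100 * lam
            )
            r1 = np.geomspace(1.0, r0, 800)
            r23 = np.geomspace(r0, 20 * lam, 4000)
            i1 = np.trapezoid(ms.piecewise_profile(r1, d) * r1**2, r1)
            i23 = np.trapezoid(ms.piecewise_profile(r23, d) * r23**2, r23)
            return i1, i23

        i1_a, i23_a = region_integrals(50.0, 1000.0)
        i1_b, i23_b = region_integrals(100.0, 1000.0)
        assert i1_b / i1_a == pytest.approx(2.0, rel=0.1)  # region 1 ~ r0
        _, i23_c = region_integrals(50.0, 10000.0)
        assert i23_c / i23_a == pytest.approx(10.0, rel=0.1)  # regions 2-3 ~ lam

    def test_against_numerical_profile(self, anchor_profile):
        # at the canonical separation (lambda/r0 = 20) the pieces capture the
        # profile region by region: within 6% at the source, within a factor
        # 5 everywhere (crossover effects peak just above r0), and with the
        # exact outer decay length
        decomp = self._decomp(lam=anchor_profile.lambda_used)
        approx = ms.piecewise_profile(anchor_profile.grid, decomp)
        ratio = approx / anchor_profile.values
        assert ratio[0] == pytest.approx(1.0, abs=0.06)
        assert np.all((ratio > 1 / 5) & (ratio < 5))
        # outer decay length from the numerical tail
        g, v = anchor_profile.grid, anchor_profile.values
        mask = (g > 2000.0) & (g < 8000.0)
        slope = np.polyfit(g[mask], np.log(v[mask] * g[mask]), 1)[0]
        assert -1.0 / slope == pytest.approx(decomp.lambda_eff, rel=5e-3)


class TestPredictLambdaScaling:
    @pytest.mark.parametrize(
        "d,regime,exponent,logflag",
        [
            (1, "large", 0.5, False),
            (2, "large", 1.0, True),
            (3, "large", 1.0, False),
            (1, "small", 0.25, False),
            (2, "small", 0.5, False),
            (3, "small", 0.75, False),
        ],
    )
    def test_exponents(self, d, regime, exponent, logflag):
        assert ms.predict_lambda_scaling(d, regime) == (exponent, logflag)

    def test_small_flux_3d_regenerated_by_sweep_oracle(self):
        # linearized regime (j lambda^2 << 1): the numerical sweep must
        # reproduce the stored d/4 exponent
        p = ms.ModelParams(3, "free", 8000.0, 1e-6, 1.0)
        v0 = ms.calibrate_V0(8000.0, 250.0, p)
        sizes = [2000.0, 4000.0, 8000.0]
        lams = [
            ms.self_consistent_solve(
                p.replace(system_size=R, interaction_mag=v0),
                lambda_init=250.0 * (R / 8000.0) ** 0.75,
            ).lambda_star
            for R in sizes
        ]
        fit = ms.fit_scaling_exponent(sizes, lams)
        assert fit.exponent == pytest.approx(0.75, abs=0.02)

    def test_small_flux_2d_regenerated_by_sweep_oracle(self):
        p = ms.ModelParams(2, "free", 8000.0, 1e-6, 1.0)
        v0 = ms.calibrate_V0(8000.0, 250.0, p)
        sizes = [2000.0, 4000.0, 8000.0]
        lams = [
            ms.self_consistent_solve(
                p.replace(system_size=R, interaction_mag=v0),
                lambda_init=250.0 * (R / 8000.0) ** 0.5,
            ).lambda_star
            for R in sizes
        ]
        fit = ms.fit_scaling_exponent(sizes, lams)
        assert fit.exponent == pytest.approx(0.5, abs=0.05)

    def test_small_flux_1d_regenerated_by_exact_oracle(self):
        j, v0 = 1e-7, 1.0 / (1.0 + 8.1e-6)
        sizes = [1e4, 1e5, 1e6]
        lams = [ms.self_consistent_lambda_1d(L, j, v0) for L in sizes]
        fit = ms.fit_scaling_exponent(sizes, lams)
        assert fit.exponent == pytest.approx(0.25, abs=0.02)


class TestFitScalingExponent:
    def test_exact_power_law(self):
        sizes = np.geomspace(10, 1000, 6)
        lams = 3.7 * sizes**0.73
        fit = ms.fit_scaling_exponent(sizes, lams)
        assert fit.exponent == pytest.approx(0.73, abs=1e-10)
        assert fit.exponent_stderr < 1e-10

    def test_constant_lambda(self):
        fit = ms.fit_scaling_exponent([10.0, 100.0, 1000.0], [5.0, 5.0, 5.0])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_log_correction_strips_logarithm(self):
        # synthesize lambda obeying lambda^-2 = R^-2 log(lambda/r0): the
        # corrected fit recovers an effective exponent of 1
        from scipy.optimize import brentq

        r0 = 10.0
        sizes = np.geomspace(1e3, 1e5, 6)
        lams = [
            brentq(
                lambda lam, R=R: 1 / lam**2 - np.log(lam / r0) / R**2, 20, 1e6
            )
            for R in sizes
        ]
        fit = ms.fit_scaling_exponent(sizes, lams, log_correction=True, r0=r0)
        assert fit.exponent == pytest.approx(1.0, abs=0.01)
        plain = ms.fit_scaling_exponent(sizes, lams)
        assert abs(fit.exponent - 1.0) < abs(plain.exponent - 1.0)

    def test_insufficient_range(self):
        with pytest.raises(ms.InsufficientRangeError):
            ms.fit_scaling_exponent([10.0, 12.0, 14.0], [1.0, 1.1, 1.2])

    def test_too_few_points(self):
        with pytest.raises(ms.InvalidParameterError):
            ms.fit_scaling_exponent([10.0, 100.0], [1.0, 2.0])


class TestCollapseTransform:
    def test_pure_outer_profiles_coincide(self):
        # phi = a^2 e^(-r/lam)/(lam r) with equal R/lam collapses exactly
        curves = {}
        for R, lam in ((1000.0, 50.0), (2000.0, 100.0)):
            params = ms.ModelParams(3, "free", R, 0.1, 0.5)
            grid = np.geomspace(1.0, R, 800)
            prof = ms.Profile(
                grid=grid,
                values=np.exp(-grid / lam) / (lam * grid),
                lambda_used=lam,
                params=params,
            )
            x, y = ms.collapse_transform(prof)
            curves[R] = (x, y)
        x_ref = np.linspace(0.05, 0.95, 100)
        y_interp = [
            np.interp(x_ref, x, np.log(y)) for x, y in curves.values()
        ]
        np.testing.assert_allclose(y_interp[0], y_interp[1], atol=1e-6)

    def test_short_profile_rejected(self):
        params = ms.ModelParams(3, "free", 100.0, 0.1, 0.5)
        prof = ms.Profile(
            grid=np.array([1.0, 100.0]),
            values=np.array([1.0, 0.5]),
            lambda_used=10.0,
            params=params,
        )
        with pytest.raises(ms.InvalidParameterError):
            ms.collapse_transform(prof)
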