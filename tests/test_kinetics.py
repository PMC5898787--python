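import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synstress.kinetics import (
    CoreParameters,
    CoreState,
    SCurve,
    SCurveShape,
    core_jacobian,
    core_rhs,
    dimer_pools,
    k0_rate,
    k4_rate,
)

conc = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)


class TestSCurve:
    def test_plateaus(self):
        for shape in SCurveShape:
            c = SCurve(0.5, 3.0, 0.4, 0.6, shape)
            assert c(0.0) == pytest.approx(0.5, abs=1e-6)
            assert c(100.0) == pytest.approx(3.0, abs=1e-6)

    def test_piecewise_midpoint_is_mean(self):
        c = SCurve(1.0, 3.0, 0.4, 0.6)
        assert c(0.5) == pytest.approx(2.0)

    @pytest.mark.parametrize("shape", list(SCurveShape))
    def test_monotone_nondecreasing(self, shape):
        c = SCurve(0.2, 2.5, 0.66, 0.74, shape)
        u = np.linspace(0, 2, 500)
        v = np.asarray(c(u))
        assert np.all(np.diff(v) >= -1e-12)

    def test_shapes_agree_at_plateaus(self):
        pw = SCurve(0.2, 2.5, 0.6, 0.8, "piecewise_linear")
        sm = SCurve(0.2, 2.5, 0.6, 0.8, "smooth_sigmoid")
        for u in (0.0, 0.05, 2.0, 5.0):
            assert pw(u) == pytest.approx(sm(u), abs=0.03)

    def test_mirrored_is_nonincreasing(self):
        c = SCurve.mirrored(3.0, 0.5, 0.4, 0.6)
        u = np.linspace(0, 2, 300)
        assert np.all(np.diff(np.asarray(c(u))) <= 1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            SCurve(-0.1, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            SCurve(1.0, 2.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            SCurve(2.0, 1.0, 0.0, 1.0)  # decreasing needs mirrored()
        with pytest.raises(ValueError):
            SCurve.mirrored(1.0, 2.0, 0.0, 1.0)

    def test_negative_argument_rejected(self):
        c = SCurve(1.0, 2.0, 0.4, 0.6)
        with pytest.raises(ValueError):
            c(-0.5)
        with pytest.raises(ValueError):
            k0_rate(-1.0, c)
        with pytest.raises(ValueError):
            k4_rate(-1.0, c)

    def test_rate_within_plateau_bounds(self):
        c = SCurve(0.3, 4.0, 0.2, 0.9)
        u = np.linspace(0, 3, 200)
        v = np.asarray(c(u))
        assert np.all(v >= 0.3 - 1e-12) and np.all(v <= 4.0 + 1e-12)

    @pytest.mark.parametrize("shape", list(SCurveShape))
    def test_derivative_matches_finite_difference(self, shape):
        c = SCurve(0.5, 3.0, 0.4, 0.6, shape)
        for u in (0.1, 0.45, 0.5, 0.55, 0.9):
            h = 1e-6
            fd = (c(u + h) - c(u - h)) / (2 * h)
            # at the kinks of the piecewise shape one-sided slopes differ
            if shape is SCurveShape.PIECEWISE_LINEAR and u in (0.4, 0.6):
                continue
            assert c.derivative(u) == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestDimerPools:
    def test_zero_activated_means_no_homomers(self, config):
        hom, het = dimer_pools(1.5, 0.0, config.core)
        assert hom == 0.0 and het > 0

    def test_mass_action_arithmetic(self):
        p = CoreParameters(k1=1, k2=1, k5=1, k6=1, R_L_pool=1)
        hom, het = dimer_pools(2.0, 0.5, p)
        assert het == pytest.approx(2.0)
        assert hom == pytest.approx(0.25)

    def test_doubling_activated_quadruples_homomers(self, config):
        h1, _ = dimer_pools(1.0, 0.7, config.core)
        h2, _ = dimer_pools(1.0, 1.4, config.core)
        assert h2 == pytest.approx(4 * h1)

    def test_negative_rejected(self, config):
        with pytest.raises(ValueError):
            dimer_pools(-1.0, 0.0, config.core)


class TestCoreRHS:
    @settings(max_examples=60, derandomize=True)
    @given(NSF=conc, RS=conc, RpS=conc, pn=conc, pr=conc)
    def test_interaction_term_conservation(self, NSF, RS, RpS, pn, pr):
        """The nonlinear interaction term cancels from d[NSF]-d[R_S] and
        from d[R_S]+d[R'_S], leaving purely linear expressions."""
        params = CoreParameters()
        d = core_rhs(CoreState(NSF, RS, RpS), pn, pr, params)
        lin1 = (pn - params.z_NSF * NSF) - (pr - params.z_RS * RS)
        lin2 = pr - params.z_RS * RS - params.z_RpS * RpS
        assert d[0] - d[1] == pytest.approx(lin1, abs=1e-12)
        assert d[1] + d[2] == pytest.approx(lin2, abs=1e-12)

    def test_vanishes_at_stationary_points(self, config, stationary_points):
        for p in stationary_points:
            d = core_rhs(p.as_core_state(), config.core.p_NSF,
                         config.core.p_RS, config.core)
            assert np.max(np.abs(d)) < 1e-8

    def test_forward_invariance(self, config):
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: core_rhs(y, 1.0, 1.0, config.core),
            (0, 50.0), [0.0, 0.0, 0.0], method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        assert sol.success
        assert sol.y.min() > -1e-10

    def test_jacobian_matches_finite_differences(self, config):
        y0 = np.array([0.61, 0.58, 0.35])
        J = core_jacobian(y0, config.core)
        h = 1e-7
        for j in range(3):
            e = np.zeros(3); e[j] = h
            fd = (core_rhs(y0 + e, 1.0, 1.0, config.core)
                  - core_rhs(y0 - e, 1.0, 1.0, config.core)) / (2 * h)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-7)


def test_linear_kinetics_limit_has_unique_stationary_point():
    """With constant (degenerate) kinetics the system is effectively linear
    in its stationary structure: exactly one equilibrium, matching the
    closed form of the complementary relation."""
    from synstress.equilibrium import find_stationary_points

    flat_k0 = SCurve(0.8, 0.8, 0.4, 0.6)
    flat_k4 = SCurve(0.5, 0.5, 0.4, 0.6)
    params = CoreParameters(k0_curve=flat_k0, k4_curve=flat_k4)
    pts = find_stationary_points(params)
    assert len(pts) == 1
    assert pts[0].stability.value == "stable"
    # closed-form check: residual of the reduced scalar equation
    x = pts[0].RpS
    rs = 1 - x
    nsf = 1 - x
    assert -(1 + 0.5) * x + 0.8 * rs * nsf == pytest.approx(0.0, abs=1e-9)
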