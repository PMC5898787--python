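import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from synstress.cascade import (
    CASCADE_SPECIES,
    CascadeParameters,
    CascadeState,
    cascade_rhs,
    cascade_rhs_sigma,
    effective_production,
    receptor_expression_rates,
    receptor_occupancy,
    silent_steady_state,
)

cort = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


class TestReceptorOccupancy:
    def test_zero_ligand(self, config):
        assert receptor_occupancy(0.0, config.cascade) == (0.0, 0.0)

    def test_half_saturation_at_michaelis_constants(self, config):
        # GR half-saturated at C = M_GR = 5, MR at C = M_MR = 1e-4
        _, gr = receptor_occupancy(5.0, config.cascade)
        mr, _ = receptor_occupancy(1e-4, config.cascade)
        assert gr == pytest.approx(0.5)
        assert mr == pytest.approx(0.5)

    def test_negative_rejected(self, config):
        with pytest.raises(ValueError):
            receptor_occupancy(-1.0, config.cascade)

    @settings(max_examples=60, derandomize=True)
    @given(c1=cort, c2=cort)
    def test_monotone_and_bounded(self, c1, c2):
        params = CascadeParameters()
        lo, hi = sorted((c1, c2))
        mr1, gr1 = receptor_occupancy(lo, params)
        mr2, gr2 = receptor_occupancy(hi, params)
        assert 0 <= mr1 <= mr2 < 1
        assert 0 <= gr1 <= gr2 < 1
        # MR is the high-affinity receptor: occupied first
        assert mr1 >= gr1

    def test_mr_exceeds_gr_for_positive_cortisol(self, config):
        for c in (1e-5, 1e-2, 1.0, 50.0):
            mr, gr = receptor_occupancy(c, config.cascade)
            assert mr > gr


class TestReceptorExpression:
    def test_no_occupancy_no_induced_expression(self, config):
        assert receptor_expression_rates(0.0, 0.0, config.cascade) == (0.0, 0.0)

    def test_full_mr_maximizes_trkb(self, config):
        trkb, _ = receptor_expression_rates(1.0, 0.0, config.cascade)
        assert trkb == pytest.approx(config.cascade.p_TrkB_expr)

    def test_gr_suppresses_trkb_and_drives_p75(self, config):
        t1, p1 = receptor_expression_rates(1.0, 0.1, config.cascade)
        t2, p2 = receptor_expression_rates(1.0, 0.8, config.cascade)
        assert t2 < t1
        assert p2 > p1

    def test_steady_state_trkb_is_bell_shaped_in_cortisol(self, config):
        """TrkB expression peaks at an interior (low-normal) cortisol level
        and is low both without glucocorticoids and under stress."""
        C = np.logspace(-7, 2, 120)
        trkb = np.array([
            silent_steady_state(c, config.cascade).TrkB for c in C
        ])
        imax = int(np.argmax(trkb))
        assert 0 < imax < len(C) - 1
        assert trkb[imax] > 2 * trkb[0]
        assert trkb[imax] > 2 * trkb[-1]


class TestCascadeRHS:
    def test_quiescence_is_fixed_point(self, config):
        """With no stimulation and no cortisol the silent steady state
        (all activity-driven species zero, p75 at its constitutive floor)
        is a fixed point."""
        rest = silent_steady_state(0.0, config.cascade)
        d = cascade_rhs(rest, 0.0, 0.0, config.cascade)
        assert np.allclose(d, 0.0, atol=1e-12)
        # without the constitutive p75 floor the all-zero state is inert
        bare = CascadeParameters(p_p75_basal=0.0)
        d0 = cascade_rhs(CascadeState(), 0.0, 0.0, bare)
        assert np.allclose(d0, 0.0)

    def test_tpa_steady_state_closed_form(self):
        params = CascadeParameters(sigma=0.7)
        s_bar = 0.9
        rhs = lambda t, y: cascade_rhs(y, s_bar, 0.0, params)
        sol = solve_ivp(rhs, (0, 60), np.zeros(9), method="LSODA",
                        rtol=1e-10, atol=1e-12)
        tpa = sol.y[CASCADE_SPECIES.index("tPA"), -1]
        expected = params.p_tPA * params.sigma * s_bar / params.z_tPA
        assert tpa == pytest.approx(expected, rel=1e-6)

    def test_no_coincidence_no_mature_bdnf(self):
        """Without coincidence (sigma = 0) no tPA is released, so proBDNF
        accumulates to its production/decay balance and mBDNF stays absent
        (checked in the catalytic-binding variant where the closed form of
        the decoupled linear subsystem applies)."""
        params = CascadeParameters(sigma=0.0, consume_on_binding=False)
        s_bar = 0.5
        rhs = lambda t, y: cascade_rhs(y, s_bar, 0.0, params)
        sol = solve_ivp(rhs, (0, 400), np.zeros(9), method="LSODA",
                        rtol=1e-10, atol=1e-12)
        pro = sol.y[CASCADE_SPECIES.index("proBDNF"), -1]
        mb = sol.y[CASCADE_SPECIES.index("mBDNF"), -1]
        assert mb == pytest.approx(0.0, abs=1e-8)
        assert pro == pytest.approx(params.p_BDNF * s_bar / params.z_proBDNF,
                                    rel=1e-4)

    def test_steady_mbdnf_nondecreasing_in_sigma(self):
        """The coincidence gain is a monotone dial on mature-BDNF output."""
        s_bar = 0.2
        levels = []
        for sigma in (0.0, 0.5, 2.0, 8.0):
            params = CascadeParameters(consume_on_binding=False)
            rhs = lambda t, y: cascade_rhs_sigma(y, s_bar, sigma, 0.05, params)
            sol = solve_ivp(rhs, (0, 200), np.zeros(9), method="LSODA",
                            rtol=1e-9, atol=1e-11)
            levels.append(sol.y[CASCADE_SPECIES.index("mBDNF"), -1])
        assert all(b >= a - 1e-9 for a, b in zip(levels, levels[1:]))

    def test_silence_decays_to_silent_steady_state(self, config):
        y0 = np.full(9, 0.8)
        C = 0.05
        rhs = lambda t, y: cascade_rhs(y, 0.0, C, config.cascade)
        sol = solve_ivp(rhs, (0, 80), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        target = silent_steady_state(C, config.cascade).as_array()
        assert np.max(np.abs(sol.y[:, -1] - target)) < 1e-6

    def test_printed_sign_convention_flips_drive(self, config):
        flipped = CascadeParameters(a_sign_convention="p75_positive")
        state = CascadeState(actTrkB=0.4, actp75=0.1)
        d_text = cascade_rhs(state, 0.0, 0.0, CascadeParameters())
        d_printed = cascade_rhs(state, 0.0, 0.0, flipped)
        ia = CASCADE_SPECIES.index("a")
        assert d_text[ia] == pytest.approx(-d_printed[ia])


class TestEffectiveProduction:
    def test_neutral_modulation(self, config):
        assert effective_production(0.0, 1.0, 1.0, config.cascade) == (1.0, 1.0)

    def test_clipping_at_zero(self, config):
        u = config.cascade.u_NSF
        a = -(1.0 / u) - 1.0
        p_nsf, _ = effective_production(a, 1.0, 1.0, config.cascade)
        assert p_nsf == 0.0

    def test_nsf_channel_is_most_sensitive(self, config):
        """u_NSF = 3 amplifies the modulation three-fold on the NSF channel
        relative to a unit-sensitivity channel."""
        assert config.cascade.u_NSF == 3.0
        a = 0.05
        p_nsf, _ = effective_production(a, 1.0, 1.0, config.cascade)
        assert p_nsf - 1.0 == pytest.approx(3 * a)

    def test_negative_base_rejected(self, config):
        with pytest.raises(ValueError):
            effective_production(0.0, -1.0, 1.0, config.cascade)


def test_mmr_must_be_below_mgr():
    with pytest.raises(ValueError):
        CascadeParameters(M_MR=5.0, M_GR=5.0)
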