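import io

import numpy as np
import pytest

from synstress.equilibrium import (
    Regime,
    Stability,
    StateLabel,
    admissible_interval,
    classify_stability,
    find_stationary_points,
    pnsf_sweep,
    residual_slope,
    scissors_terms,
    stationary_residual,
)
from synstress.kinetics import CoreParameters, SCurveShape


class TestScissors:
    def test_at_origin(self, config):
        P, D = scissors_terms(0.0, config.core)
        k0_at_zero = config.core.k0_curve(0.0)
        assert D == 0.0
        assert P == pytest.approx(k0_at_zero * 1.0 * 1.0)

    def test_sign_structure(self, config):
        lo, hi = admissible_interval(config.core, 1.0, 1.0)
        for x in np.linspace(lo, hi, 50):
            P, D = scissors_terms(float(x), config.core)
            assert P >= 0.0
            assert D <= 0.0

    def test_production_blade_increases_with_pnsf(self, config):
        x = 0.3
        grid = np.linspace(0.8, 2.0, 25)
        P = [scissors_terms(x, config.core, p, 1.0)[0] for p in grid]
        assert np.all(np.diff(P) > 0)

    def test_outside_admissible_interval_rejected(self, config):
        with pytest.raises(ValueError):
            scissors_terms(1.5, config.core)

    def test_empty_interval_rejected(self, config):
        with pytest.raises(ValueError):
            admissible_interval(config.core, 0.0, 1.0)


class TestStationaryPoints:
    def test_default_structure_five_points_alternating(self, stationary_points):
        assert len(stationary_points) == 5
        pattern = [p.stability for p in stationary_points]
        assert pattern == [
            Stability.STABLE, Stability.UNSTABLE, Stability.STABLE,
            Stability.UNSTABLE, Stability.STABLE,
        ]
        labels = [p.label for p in stationary_points if p.stability is Stability.STABLE]
        assert labels == [StateLabel.LTD, StateLabel.ACTIVE, StateLabel.LTP]

    def test_smooth_sigmoid_preserves_structure(self, config):
        pts = find_stationary_points(config.core.with_shape(SCurveShape.SMOOTH_SIGMOID))
        assert len(pts) == 5
        assert [p.stability.value for p in pts] == [
            "stable", "unstable", "stable", "unstable", "stable"]

    def test_complementary_relation_holds(self, config, stationary_points):
        c = config.core
        for p in stationary_points:
            assert p.RS == pytest.approx(
                (c.p_RS - c.z_RpS * p.RpS) / c.z_RS, abs=1e-9)
            assert p.NSF == pytest.approx(
                (c.p_NSF - c.z_RpS * p.RpS) / c.z_NSF, abs=1e-9)

    def test_residual_vanishes_at_roots(self, config, stationary_points):
        for p in stationary_points:
            assert abs(stationary_residual(p.RpS, config.core)) < 1e-9

    def test_residual_positive_at_zero(self, config):
        assert stationary_residual(0.0, config.core) > 0

    def test_grid_oracle_sign_changes_match_root_count(self, config):
        """Brute-force sign-change count on a dense grid agrees with the
        number of simple roots the finder returns."""
        lo, hi = admissible_interval(config.core, 1.0, 1.0)
        xs = np.linspace(lo, hi, 20001)
        res = np.array([stationary_residual(float(x), config.core) for x in xs])
        sign_changes = int(np.sum(np.sign(res[:-1]) * np.sign(res[1:]) < 0))
        assert sign_changes == len(find_stationary_points(config.core))

    def test_low_pnsf_single_ltd_point(self, config):
        pts = find_stationary_points(config.core, 0.4, 1.0)
        stable = [p for p in pts if p.stability is Stability.STABLE]
        assert len(stable) == 1
        assert stable[0].label is StateLabel.LTD
        assert stable[0].RpS == min(p.RpS for p in pts)

    def test_high_pnsf_single_ltp_point(self, config):
        pts = find_stationary_points(config.core, 3.0, 1.0)
        stable = [p for p in pts if p.stability is Stability.STABLE]
        assert len(stable) == 1
        assert stable[0].label is StateLabel.LTP
        assert stable[0].RpS == max(p.RpS for p in pts)

    def test_coarse_grid_rejected(self, config):
        with pytest.raises(ValueError):
            find_stationary_points(config.core, grid_resolution=100)


class TestStability:
    def test_dual_oracle_agreement(self, config, stationary_points):
        """The 3-D eigenvalue test and the 1-D residual-slope test agree on
        every stationary point."""
        for p in stationary_points:
            eig = classify_stability(p, config.core)
            slope = residual_slope(p.RpS, config.core)
            assert (slope < 0) == (eig is Stability.STABLE)

    def test_non_stationary_point_rejected(self, config, stationary_points):
        from synstress.equilibrium import StationaryPoint

        bogus = StationaryPoint(0.3, 0.7, 0.7, Stability.STABLE)
        with pytest.raises(ValueError):
            classify_stability(bogus, config.core)


@pytest.fixture(scope="module")
def table(config):
    return pnsf_sweep((0.5, 2.0), 41, config.core)


class TestSweep:

    def test_regime_sequence(self, table):
        vals = [r.value for r in table.regime]
        assert vals[0] == "monostable_LTD"
        assert vals[-1] == "monostable_LTP"
        transitions = [(a, b) for a, b in zip(vals[:-1], vals[1:]) if a != b]
        assert transitions == [
            ("monostable_LTD", "tristable"),
            ("tristable", "monostable_LTP"),
        ]

    def test_odd_point_counts(self, table):
        assert all(len(pts) % 2 == 1 for pts in table.points_per_p)

    def test_stable_branches_continuous(self, table):
        """Within each regime, stable-point positions move continuously
        with p_NSF (no jumps beyond a grid-adaptive bound)."""
        dp = table.p_NSF_grid[1] - table.p_NSF_grid[0]
        prev = None
        for pts, reg in zip(table.points_per_p, table.regime):
            stable = sorted(
                p.RpS for p in pts if p.stability is Stability.STABLE)
            if prev is not None and reg == prev[1] and len(stable) == len(prev[0]):
                deltas = np.abs(np.array(stable) - np.array(prev[0]))
                # stable branches have bounded slope away from the folds
                assert np.max(deltas) < 3.0 * dp + 0.02
            prev = (stable, reg)

    def test_middle_state_disappears_not_destabilizes(self, config, table):
        """The active point leaves by fold annihilation: no grid value shows
        a formerly-stable active point reclassified unstable."""
        for pts in table.points_per_p:
            for p in pts:
                if p.label is StateLabel.ACTIVE:
                    assert p.stability is Stability.STABLE

    def test_csv_export_schema(self, table):
        buf = io.StringIO()
        table.to_csv(buf)
        header = buf.getvalue().splitlines()[0]
        assert header == "p_NSF,RpS,RS,NSF,stability,label,regime"

    def test_fold_interval_brackets_window(self, table):
        lo, hi = table.fold_interval()
        assert 0.5 < lo < 1.0 < hi < 2.0
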