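"""Stationary-point and bifurcation analysis of the core activation system.

Because the interaction term k0 [R_S][NSF] - k4 [R'_S] enters all three core
equations with matching signs, every stationary point satisfies the
complementary relation

    p_NSF - z_NSF [NSF]  =  p_RS - z_RS [R_S]  =  z_RpS [R'_S],

which expresses [R_S] and [NSF] through [R'_S] alone and reduces the
stationary condition to a scalar equation in x = [R'_S]:

    0 = -(z_RpS + k4(RS(x))) x  +  k0(x) RS(x) NSF(x)  =  D(x) + P(x).

D is the (nonpositive) decay term and P the (nonnegative) production term —
the two "blades of the scissors" whose intersections are the stationary
points.  Under the default calibration there are five of them, alternating
stable/unstable, and the three stable ones are the LTD, active and LTP
states of the synapse.  Raising or lowering the NSF production rate p_NSF
shears the production blade and annihilates equilibria pairwise at two
folds, leaving a single LTP (high p_NSF) or LTD (low p_NSF) state; the
resulting hysteresis is what makes a transient production change a lasting
change of synaptic strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import CoreParameters, CoreState, core_jacobian, core_rhs, k0_rate, k4_rate

__all__ = [
    "Stability",
    "StateLabel",
    "Regime",
    "StationaryPoint",
    "BifurcationTable",
    "MarginalStabilityError",
    "admissible_interval",
    "scissors_terms",
    "stationary_residual",
    "find_stationary_points",
    "classify_stability",
    "pnsf_sweep",
]

RESIDUAL_TOL = 1e-9
ROOT_XTOL = 1e-10
#: eigenvalue real parts closer to zero than this are considered marginal
MARGINAL_TOL = 1e-7


class Stability(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"


class StateLabel(str, Enum):
    LTD = "LTD"
    ACTIVE = "active"
    LTP = "LTP"
    UNLABELED = "unlabeled"


class Regime(str, Enum):
    MONOSTABLE_LTD = "monostable_LTD"
    TRISTABLE = "tristable"
    MONOSTABLE_LTP = "monostable_LTP"


class MarginalStabilityError(RuntimeError):
    """A stationary point sits (numerically) on a fold: an eigenvalue or the
    1-D residual slope vanishes within tolerance, so stable/unstable cannot
    be decided."""


@dataclass(frozen=True)
class StationaryPoint:
    """One equilibrium of the core system, on the complementary relation."""

    RpS: float
    RS: float
    NSF: float
    stability: Stability
    label: StateLabel = StateLabel.UNLABELED

    def as_core_state(self) -> CoreState:
        return CoreState(NSF=self.NSF, RS=self.RS, RpS=self.RpS)


@dataclass(frozen=True)
class BifurcationTable:
    """Stationary points along a p_NSF grid, with the regime at each value."""

    p_NSF_grid: np.ndarray
    points_per_p: list[list[StationaryPoint]]
    regime: list[Regime]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, pts, reg in zip(self.p_NSF_grid, self.points_per_p, self.regime):
            for pt in pts:
                rows.append(
                    dict(
                        p_NSF=p,
                        RpS=pt.RpS,
                        RS=pt.RS,
                        NSF=pt.NSF,
                        stability=pt.stability.value,
                        label=pt.label.value,
                        regime=reg.value,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["p_NSF", "RpS", "RS", "NSF", "stability", "label", "regime"],
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def fold_interval(self) -> tuple[float, float]:
        """(largest monostable-LTD grid p_NSF, smallest monostable-LTP one):
        brackets of the two folds at the grid resolution."""
        grid = np.asarray(self.p_NSF_grid)
        ltd = grid[[r is Regime.MONOSTABLE_LTD for r in self.regime]]
        ltp = grid[[r is Regime.MONOSTABLE_LTP for r in self.regime]]
        if len(ltd) == 0 or len(ltp) == 0:
            raise ValueError("sweep range does not cover both folds")
        return float(ltd.max()), float(ltp.min())


def _complementary(RpS, params: CoreParameters, p_NSF_eff, p_RS_eff):
    RS = (p_RS_eff - params.z_RpS * RpS) / params.z_RS
    NSF = (p_NSF_eff - params.z_RpS * RpS) / params.z_NSF
    return RS, NSF


def admissible_interval(
    params: CoreParameters, p_NSF_eff: float, p_RS_eff: float
) -> tuple[float, float]:
    """[R'_S] interval on which the complementary relation keeps both
    implied concentrations nonnegative."""
    hi = min(p_NSF_eff, p_RS_eff) / params.z_RpS
    if hi <= 0:
        raise ValueError(
            "empty admissible interval: nonpositive effective production"
        )
    return 0.0, hi


def scissors_terms(
    RpS: float,
    params: CoreParameters,
    p_NSF_eff: Optional[float] = None,
    p_RS_eff: Optional[float] = None,
) -> tuple[float, float]:
    """Production blade P >= 0 and decay blade D <= 0 at ``RpS``.

    Both are evaluated on the complementary relation; their sum is the
    stationary residual.  Raises if ``RpS`` lies outside the admissible
    interval (an implied concentration would be negative).
    """
    if p_NSF_eff is None:
        p_NSF_eff = params.p_NSF
    if p_RS_eff is None:
        p_RS_eff = params.p_RS
    lo, hi = admissible_interval(params, p_NSF_eff, p_RS_eff)
    if RpS < lo or RpS > hi:
        raise ValueError(
            f"RpS={RpS} outside admissible interval [{lo}, {hi:.6g}]"
        )
    RS, NSF = _complementary(RpS, params, p_NSF_eff, p_RS_eff)
    P = k0_rate(RpS, params.k0_curve) * RS * NSF
    D = -(params.z_RpS + k4_rate(RS, params.k4_curve)) * RpS
    return P, D


def stationary_residual(
    RpS: float,
    params: CoreParameters,
    p_NSF_eff: Optional[float] = None,
    p_RS_eff: Optional[float] = None,
) -> float:
    """P(RpS) + D(RpS); zero exactly at the stationary points."""
    P, D = scissors_terms(RpS, params, p_NSF_eff, p_RS_eff)
    return P + D


#: per-parameter-set reference labels (RpS of LTD/active/LTP at baseline
#: productions); used to label points when fewer than three stable ones exist.
_REFERENCE_RPS: dict[CoreParameters, dict[StateLabel, float]] = {}


def _label_points(
    points: list[StationaryPoint],
    reference: dict[StateLabel, float],
) -> list[StationaryPoint]:
    stable = [p for p in points if p.stability is Stability.STABLE]
    out = []
    if len(stable) == 3:
        order = {id(p): lab for p, lab in zip(
            sorted(stable, key=lambda p: p.RpS),
            (StateLabel.LTD, StateLabel.ACTIVE, StateLabel.LTP),
        )}
        for p in points:
            lab = order.get(id(p), StateLabel.UNLABELED)
            out.append(StationaryPoint(p.RpS, p.RS, p.NSF, p.stability, lab))
    elif reference:
        for p in points:
            if p.stability is Stability.STABLE:
                lab = min(
                    reference, key=lambda k: abs(reference[k] - p.RpS)
                )
            else:
                lab = StateLabel.UNLABELED
            out.append(StationaryPoint(p.RpS, p.RS, p.NSF, p.stability, lab))
    else:
        out = list(points)
    return out


def _reference_labels(params: CoreParameters) -> dict[StateLabel, float]:
    """Tristable reference labels at the baseline productions of ``params``
    (used for nearest-label assignment outside the tristable window)."""
    if params not in _REFERENCE_RPS:
        pts = find_stationary_points(params, params.p_NSF, params.p_RS,
                                     _set_reference=False)
        stable = sorted(
            (p for p in pts if p.stability is Stability.STABLE),
            key=lambda p: p.RpS,
        )
        ref: dict[StateLabel, float] = {}
        if len(stable) == 3:
            ref[StateLabel.LTD] = stable[0].RpS
            ref[StateLabel.ACTIVE] = stable[1].RpS
            ref[StateLabel.LTP] = stable[2].RpS
        _REFERENCE_RPS[params] = ref
    return _REFERENCE_RPS[params]


def find_stationary_points(
    params: CoreParameters,
    p_NSF_eff: Optional[float] = None,
    p_RS_eff: Optional[float] = None,
    grid_resolution: int = 4000,
    _set_reference: bool = True,
) -> list[StationaryPoint]:
    """All stationary points of the core system, ascending in [R'_S].

    Simple roots of the reduced scalar equation are bracketed on a uniform
    grid over the admissible interval and refined by Brent's method to a
    residual below 1e-9.  Stability is attached from the core Jacobian; when
    three stable points exist they are labeled LTD/active/LTP in ascending
    [R'_S] order, otherwise stable points inherit the nearest reference
    label of the baseline tristable set.
    """
    if grid_resolution < 1000:
        raise ValueError("grid_resolution must be at least 1000")
    if p_NSF_eff is None:
        p_NSF_eff = params.p_NSF
    if p_RS_eff is None:
        p_RS_eff = params.p_RS
    lo, hi = admissible_interval(params, p_NSF_eff, p_RS_eff)
    xs = np.linspace(lo, hi, grid_resolution + 1)
    res = np.array(
        [stationary_residual(x, params, p_NSF_eff, p_RS_eff) for x in xs]
    )

    roots: list[float] = []
    for i in range(len(xs) - 1):
        a, b = res[i], res[i + 1]
        if a == 0.0:
            roots.append(float(xs[i]))
        elif a * b < 0:
            roots.append(
                float(
                    brentq(
                        stationary_residual,
                        xs[i],
                        xs[i + 1],
                        args=(params, p_NSF_eff, p_RS_eff),
                        xtol=ROOT_XTOL,
                        rtol=4 * np.finfo(float).eps,
                    )
                )
            )
    if res[-1] == 0.0:
        roots.append(float(xs[-1]))

    points = []
    for x in sorted(set(roots)):
        if abs(stationary_residual(x, params, p_NSF_eff, p_RS_eff)) > RESIDUAL_TOL:
            continue
        RS, NSF = _complementary(x, params, p_NSF_eff, p_RS_eff)
        pt = StationaryPoint(x, RS, NSF, Stability.UNSTABLE)
        stab = classify_stability(pt, params, p_NSF_eff, p_RS_eff)
        points.append(StationaryPoint(x, RS, NSF, stab))

    reference = _reference_labels(params) if _set_reference else {}
    return _label_points(points, reference)


def classify_stability(
    point: StationaryPoint,
    params: CoreParameters,
    p_NSF_eff: Optional[float] = None,
    p_RS_eff: Optional[float] = None,
) -> Stability:
    """Stable iff all eigenvalues of the 3x3 core Jacobian have negative
    real part.

    A one-dimensional criterion is available independently — on the slow
    manifold defined by the complementary relation the point is stable iff
    the residual slope d(P+D)/d[R'_S] is negative — and the two tests agree
    for this system; the test suite checks that agreement.  Eigenvalues
    within ``MARGINAL_TOL`` of the imaginary axis raise
    :class:`MarginalStabilityError` (fold point).
    """
    if p_NSF_eff is None:
        p_NSF_eff = params.p_NSF
    if p_RS_eff is None:
        p_RS_eff = params.p_RS
    resid = core_rhs(point.as_core_state(), p_NSF_eff, p_RS_eff, params)
    if np.max(np.abs(resid)) > 1e-6:
        raise ValueError("point does not satisfy the stationary equations")
    J = core_jacobian(point.as_core_state(), params)
    eig = np.linalg.eigvals(J)
    real = np.real(eig)
    if np.any(np.abs(real) < MARGINAL_TOL):
        raise MarginalStabilityError(
            f"marginal stationary point at RpS={point.RpS:.6g}: "
            f"eigenvalue real parts {real}"
        )
    return Stability.STABLE if np.all(real < 0) else Stability.UNSTABLE


def residual_slope(
    RpS: float,
    params: CoreParameters,
    p_NSF_eff: Optional[float] = None,
    p_RS_eff: Optional[float] = None,
    h: float = 1e-7,
) -> float:
    """Central finite-difference slope of the reduced residual (the 1-D
    stability criterion: negative slope = stable)."""
    if p_NSF_eff is None:
        p_NSF_eff = params.p_NSF
    if p_RS_eff is None:
        p_RS_eff = params.p_RS
    lo, hi = admissible_interval(params, p_NSF_eff, p_RS_eff)
    a = max(RpS - h, lo)
    b = min(RpS + h, hi)
    fa = stationary_residual(a, params, p_NSF_eff, p_RS_eff)
    fb = stationary_residual(b, params, p_NSF_eff, p_RS_eff)
    return (fb - fa) / (b - a)


def pnsf_sweep(
    p_NSF_range: tuple[float, float],
    n_steps: int,
    params: CoreParameters,
    grid_resolution: int = 2000,
) -> BifurcationTable:
    """Stationary points as the NSF production rate is swept.

    Along increasing p_NSF the regime sequence is monostable-LTD →
    tristable → monostable-LTP, with two fold transitions where a
    stable/unstable pair is created or annihilated.
    """
    lo, hi = p_NSF_range
    grid = np.linspace(lo, hi, n_steps)
    points_per_p: list[list[StationaryPoint]] = []
    n_stable: list[int] = []
    labels_per_p: list[set] = []
    for p in grid:
        pts = find_stationary_points(
            params, float(p), params.p_RS, grid_resolution=grid_resolution
        )
        points_per_p.append(pts)
        stable = [q for q in pts if q.stability is Stability.STABLE]
        n_stable.append(len(stable))
        labels_per_p.append({q.label for q in stable})

    # Narrow bistable shoulders flank the tristable window (one of the three
    # branches is born/annihilated slightly before the other); the 3-value
    # regime classification folds them into the neighboring regime so the
    # sequence along p_NSF is monostable_LTD -> tristable -> monostable_LTP.
    tri = [i for i, n in enumerate(n_stable) if n >= 3]
    regimes: list[Regime] = []
    for i, n in enumerate(n_stable):
        if n >= 3:
            regimes.append(Regime.TRISTABLE)
        elif tri and i < tri[0]:
            regimes.append(Regime.MONOSTABLE_LTD)
        elif tri and i > tri[-1]:
            regimes.append(Regime.MONOSTABLE_LTP)
        elif StateLabel.LTP in labels_per_p[i] and StateLabel.LTD not in labels_per_p[i]:
            regimes.append(Regime.MONOSTABLE_LTP)
        else:
            regimes.append(Regime.MONOSTABLE_LTD)
    return BifurcationTable(grid, points_per_p, regimes)


def stable_points(points: Sequence[StationaryPoint]) -> list[StationaryPoint]:
    return [p for p in points if p.stability is Stability.STABLE]


def point_by_label(
    points: Sequence[StationaryPoint], label: StateLabel
) -> StationaryPoint:
    for p in points:
        if p.label is StateLabel(label):
            return p
    raise KeyError(f"no stationary point labeled {label}")
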