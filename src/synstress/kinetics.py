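"""Core AMPA-subunit activation kinetics.

The cytosolic pool of a glutamatergic postsynapse is reduced to three
species: NSF (the ATPase that activates short-tailed AMPA subunits),
nonactivated short-tailed subunits ``RS`` ([R_S], GluA2/3) and activated
subunits ``RpS`` ([R'_S]).  Activation follows

    R_S + NSF  <-- k0, k4 -->  R'_S

with *state-dependent* rate "constants": k0 grows with [R'_S] (activated
homomers R'_S R'_S promote further activation) and k4 grows with [R_S]
(nonactivated heteromers R_S R_L promote deactivation).  This double
positive feedback is what makes the system multistable; both nonlinear
kinetics are S-shaped and are represented here by :class:`SCurve`.

Dimerization (2 R'_S <-> R'_S R'_S and R_S + R_L <-> R_S R_L) is treated in
quasi-steady state: its feedback on activation lives entirely inside the
S-curves, while the algebraic pools computed by :func:`dimer_pools` feed the
membrane-trafficking layer.  Concentrations are normalized; time is in
hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "SCurveShape",
    "SCurve",
    "CoreParameters",
    "CoreState",
    "k0_rate",
    "k4_rate",
    "dimer_pools",
    "core_rhs",
    "core_jacobian",
]

ArrayLike = Union[float, np.ndarray]


class SCurveShape(str, Enum):
    """Functional form of an S-shaped rate law."""

    PIECEWISE_LINEAR = "piecewise_linear"
    SMOOTH_SIGMOID = "smooth_sigmoid"


# Logistic gain so the smooth variant sits within 1% of each plateau at the
# ends of the ramp (matches the piecewise-linear plateaus there).
_SIGMOID_SPAN = 2.0 * np.log(99.0)


@dataclass(frozen=True)
class SCurve:
    """S-shaped rate law: a low plateau, a monotone ramp, a high plateau.

    ``low_rate`` is the value for arguments below ``rise_start`` and
    ``high_rate`` the value above ``rise_end``.  The default constructor
    builds a nondecreasing curve (``high_rate >= low_rate``); use
    :meth:`mirrored` for the nonincreasing view (useful when reading the
    deactivation kinetics k4, which increase in [R_S], as a function of
    [R'_S]).

    The ``piecewise_linear`` shape is the kinked schematic form (kinks make
    the stationary-point geometry easy to see); ``smooth_sigmoid`` is a
    logistic ramp matched to the plateaus at the ramp ends, for which the
    qualitative behavior is unchanged.
    """

    low_rate: float
    high_rate: float
    rise_start: float
    rise_end: float
    shape: SCurveShape = SCurveShape.PIECEWISE_LINEAR
    _allow_decreasing: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.low_rate < 0 or self.high_rate < 0:
            raise ValueError("SCurve plateau rates must be nonnegative")
        if not self.rise_start < self.rise_end:
            raise ValueError("SCurve requires rise_start < rise_end")
        if not self._allow_decreasing and self.high_rate < self.low_rate:
            raise ValueError(
                "SCurve is nondecreasing; use SCurve.mirrored for a "
                "nonincreasing curve"
            )
        object.__setattr__(self, "shape", SCurveShape(self.shape))

    @classmethod
    def mirrored(
        cls,
        low_rate: float,
        high_rate: float,
        rise_start: float,
        rise_end: float,
        shape: SCurveShape = SCurveShape.PIECEWISE_LINEAR,
    ) -> "SCurve":
        """Nonincreasing curve: value ``low_rate`` left of the ramp is the
        *larger* plateau.  Arguments name the plateaus by position, so here
        ``low_rate >= high_rate`` is required."""
        if high_rate > low_rate:
            raise ValueError("mirrored SCurve requires low_rate >= high_rate")
        return cls(low_rate, high_rate, rise_start, rise_end, shape,
                   _allow_decreasing=True)

    def __call__(self, u: ArrayLike) -> ArrayLike:
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr < 0):
            raise ValueError("S-curve argument is a concentration; must be >= 0")
        if self.shape is SCurveShape.PIECEWISE_LINEAR:
            out = np.interp(
                u_arr,
                [self.rise_start, self.rise_end],
                [self.low_rate, self.high_rate],
            )
        else:
            g = _SIGMOID_SPAN / (self.rise_end - self.rise_start)
            mid = 0.5 * (self.rise_start + self.rise_end)
            z = np.clip(g * (u_arr - mid), -500.0, 500.0)
            out = self.low_rate + (self.high_rate - self.low_rate) / (
                1.0 + np.exp(-z)
            )
        return out if out.ndim else float(out)

    def derivative(self, u: ArrayLike) -> ArrayLike:
        """d(rate)/d(argument).  At the kinks of the piecewise-linear shape
        the one-sided derivatives differ; the ramp-side value is returned."""
        u_arr = np.asarray(u, dtype=float)
        if self.shape is SCurveShape.PIECEWISE_LINEAR:
            slope = (self.high_rate - self.low_rate) / (
                self.rise_end - self.rise_start
            )
            inside = (u_arr >= self.rise_start) & (u_arr <= self.rise_end)
            out = np.where(inside, slope, 0.0)
        else:
            g = _SIGMOID_SPAN / (self.rise_end - self.rise_start)
            mid = 0.5 * (self.rise_start + self.rise_end)
            z = np.clip(g * (u_arr - mid), -500.0, 500.0)
            s = 1.0 / (1.0 + np.exp(-z))
            out = (self.high_rate - self.low_rate) * g * s * (1.0 - s)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CoreParameters:
    """Rate constants of the cytosolic activation system.

    ``p_NSF``/``p_RS`` are baseline ribosomal production rates (the cascade
    modulates them at run time), ``z_*`` linear decay rates, ``k1``/``k2``
    and ``k5``/``k6`` the association/dissociation rates of homomer and
    heteromer formation, and ``R_L_pool`` the free long-tailed subunit pool,
    held constant (no R_L dynamics are modeled).
    """

    p_NSF: float = 1.0
    p_RS: float = 1.0
    z_NSF: float = 1.0
    z_RS: float = 1.0
    z_RpS: float = 1.0
    k0_curve: SCurve = field(default=None)  # type: ignore[assignment]
    k4_curve: SCurve = field(default=None)  # type: ignore[assignment]
    k1: float = 1.0
    k2: float = 1.0
    k5: float = 1.0
    k6: float = 1.0
    R_L_pool: float = 1.0

    def __post_init__(self) -> None:
        if self.k0_curve is None:
            object.__setattr__(self, "k0_curve", default_k0_curve())
        if self.k4_curve is None:
            object.__setattr__(self, "k4_curve", default_k4_curve())
        for name in ("p_NSF", "p_RS", "z_NSF", "z_RS", "z_RpS",
                     "k1", "k2", "k5", "k6", "R_L_pool"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.k2 <= 0 or self.k6 <= 0:
            raise ValueError(
                "k2 and k6 must be positive (quasi-steady-state dimer pools)"
            )

    def with_shape(self, shape: SCurveShape) -> "CoreParameters":
        """Same parameters with both kinetics switched to ``shape``."""
        return replace(
            self,
            k0_curve=replace(self.k0_curve, shape=SCurveShape(shape)),
            k4_curve=replace(self.k4_curve, shape=SCurveShape(shape)),
        )


# Default S-curve breakpoints.  The normalized parameter scale (everything
# normalized to 1) leave the curve plateaus and kinks free; these values were
# calibrated once with the equilibrium module so that the core system has
# five stationary points (LTD / unstable / active / unstable / LTP), the
# lower p_NSF fold lies in (0.8, 1) and the upper fold well below 3x
# baseline, and the LTP/active homomer ratio yields a transmission
# fold-change of about 2.  See docs/methods.md.
_K0_DEFAULT = dict(low_rate=1.3, high_rate=2.8, rise_start=0.42, rise_end=0.46)
_K4_DEFAULT = dict(low_rate=0.2, high_rate=2.5, rise_start=0.66, rise_end=0.74)


def default_k0_curve(shape: SCurveShape = SCurveShape.PIECEWISE_LINEAR) -> SCurve:
    """Calibrated activation kinetics k0([R'_S])."""
    return SCurve(shape=SCurveShape(shape), **_K0_DEFAULT)


def default_k4_curve(shape: SCurveShape = SCurveShape.PIECEWISE_LINEAR) -> SCurve:
    """Calibrated deactivation kinetics k4([R_S]) (increasing in [R_S])."""
    return SCurve(shape=SCurveShape(shape), **_K4_DEFAULT)


@dataclass(frozen=True)
class CoreState:
    """Concentrations of the three cytosolic species (normalized units)."""

    NSF: float
    RS: float
    RpS: float

    def as_array(self) -> np.ndarray:
        return np.array([self.NSF, self.RS, self.RpS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CoreState":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


def k0_rate(RpS: ArrayLike, curve: SCurve) -> ArrayLike:
    """Activation rate k0 as a function of activated subunits [R'_S].

    More [R'_S] means more R'_S R'_S homomers, which promote activation, so
    the curve is nondecreasing.
    """
    return curve(RpS)


def k4_rate(RS: ArrayLike, curve: SCurve) -> ArrayLike:
    """Deactivation rate k4 as a function of nonactivated subunits [R_S].

    More [R_S] means more R_S R_L heteromers, which promote deactivation, so
    the curve is nondecreasing in [R_S].
    """
    return curve(RS)


def dimer_pools(
    RS: ArrayLike, RpS: ArrayLike, params: CoreParameters
) -> tuple[ArrayLike, ArrayLike]:
    """Quasi-steady-state dimer pools.

    Homomers: 2 R'_S <-> R'_S R'_S gives [R'_S R'_S] = (k1/k2) [R'_S]^2.
    Heteromers: R_S + R_L <-> R_S R_L gives [R_S R_L] = (k5/k6) [R_S] [R_L].
    """
    RS = np.asarray(RS, dtype=float)
    RpS = np.asarray(RpS, dtype=float)
    if np.any(RS < 0) or np.any(RpS < 0):
        raise ValueError("concentrations must be nonnegative")
    homomer = (params.k1 / params.k2) * RpS**2
    heteromer = (params.k5 / params.k6) * RS * params.R_L_pool
    if homomer.ndim == 0:
        return float(homomer), float(heteromer)
    return homomer, heteromer


def core_rhs(
    state: CoreState | np.ndarray,
    p_NSF_eff: float,
    p_RS_eff: float,
    params: CoreParameters,
) -> np.ndarray:
    """Time derivatives (d[NSF], d[R_S], d[R'_S])/dt.

    The interaction term I = k0([R'_S]) [R_S][NSF] - k4([R_S]) [R'_S]
    appears with sign -I in the NSF and R_S equations and +I in the R'_S
    equation, so d[NSF]/dt - d[R_S]/dt and d[R_S]/dt + d[R'_S]/dt are purely
    linear in the state (the conservation identities used by the
    stationary-point reduction).
    """
    if isinstance(state, CoreState):
        NSF, RS, RpS = state.NSF, state.RS, state.RpS
    else:
        NSF, RS, RpS = float(state[0]), float(state[1]), float(state[2])
    interaction = (
        k0_rate(max(RpS, 0.0), params.k0_curve) * RS * NSF
        - k4_rate(max(RS, 0.0), params.k4_curve) * RpS
    )
    dNSF = p_NSF_eff - params.z_NSF * NSF - interaction
    dRS = p_RS_eff - params.z_RS * RS - interaction
    dRpS = -params.z_RpS * RpS + interaction
    return np.array([dNSF, dRS, dRpS])


def core_jacobian(
    state: CoreState | np.ndarray,
    params: CoreParameters,
) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`core_rhs` w.r.t. (NSF, RS, RpS).

    Uses the S-curve derivative; at a kink of the piecewise-linear shape the
    ramp-side one-sided derivative is used.
    """
    if isinstance(state, CoreState):
        NSF, RS, RpS = state.NSF, state.RS, state.RpS
    else:
        NSF, RS, RpS = float(state[0]), float(state[1]), float(state[2])
    k0 = k0_rate(RpS, params.k0_curve)
    k4 = k4_rate(RS, params.k4_curve)
    dk0 = params.k0_curve.derivative(RpS)
    dk4 = params.k4_curve.derivative(RS)
    # interaction I = k0(RpS) RS NSF - k4(RS) RpS
    dI_dNSF = k0 * RS
    dI_dRS = k0 * NSF - dk4 * RpS
    dI_dRpS = dk0 * RS * NSF - k4
    return np.array(
        [
            [-params.z_NSF - dI_dNSF, -dI_dRS, -dI_dRpS],
            [-dI_dNSF, -params.z_RS - dI_dRS, -dI_dRpS],
            [dI_dNSF, dI_dRS, -params.z_RpS + dI_dRpS],
        ]
    )
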