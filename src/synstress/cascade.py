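"""Upstream signaling cascade: stimulation + cortisol -> production rates.

This layer sits causally before the core activation system.  It turns the
two experimental inputs — the presynaptic signal s(t) and the cortisol
concentration C — into a modulation of the ribosomal production rates of
NSF and R_S:

* Glutamate release (tracked by s(t)) produces CaMKII, and — only in
  coincidence with postsynaptic depolarization, encoded by the gain σ —
  releases tPA into the cleft (the NMDA-receptor coincidence detector).
* Presynaptic activity releases proBDNF; tPA (via plasmin, collapsed into
  the conversion constant k8) converts proBDNF to mature BDNF, so high
  mBDNF marks highly correlated activity.
* Cortisol occupies the high-affinity MR and low-affinity GR receptors
  (Michaelis–Menten, M_MR << M_GR).  MR drives TrkB expression, GR
  suppresses TrkB and drives p75, which makes steady-state TrkB bell-shaped
  in cortisol: maximal at low-normal C, low both without cortisol and under
  stress.
* mBDNF·TrkB and proBDNF·p75 complexes (activated TrkB / activated p75)
  push the modulation variable ``a`` up and down respectively;
  ``a`` shifts the core production rates via the sensitivities u_NSF, u_RS.

All concentrations normalized, time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "CascadeParameters",
    "CascadeState",
    "receptor_occupancy",
    "receptor_expression_rates",
    "cascade_rhs",
    "effective_production",
    "silent_steady_state",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class CascadeParameters:
    """Cascade rate constants.

    The normalized reaction constants follow the standard set: receptor
    affinities M_MR = 1e-4 << M_GR = 5, NSF-channel sensitivity u_NSF = 3,
    slow decays z_tPA = 0.5 and z_proBDNF = 0.1, fast activated-complex
    decays z_actTrkB = z_actp75 = 2, elevated production gains p_BDNF = 10,
    p_actTrkB = 10, p_tPA = 2, and unity for the remaining reaction rates.

    The receptor-expression and complex-formation constants that the
    reaction scheme leaves free were calibrated once against the scenario
    outcomes (see docs/methods.md): TrkB expression gain
    ``p_TrkB_expr`` = 0.35 (sets the ceiling of TrkB signaling, which under
    conservative binding saturates at the receptor replenishment flux),
    constitutive p75 expression ``p_p75_basal`` = 0.025, p75 association
    rate ``p_actp75`` = 2, and R_S-channel sensitivity ``u_RS`` = 0.3
    (well below u_NSF, so LTD induction does not disarm the heteromer
    deactivation feedback it depends on).

    ``a_sign_convention`` selects which activated complex raises ``a``
    (and with it protein production): ``"trkb_positive"`` (default) has
    TrkB signaling increase production, ``"p75_positive"`` the opposite.
    ``consume_on_binding`` (default True) makes ligand–receptor binding
    conservative mass action — complex formation consumes both partners,
    as for internalized receptor–ligand pairs; False switches to a
    catalytic-sensing approximation in which binding consumes neither.
    """

    b_CaMKII: float = 1.0
    z_CaMKII: float = 1.0
    sigma: float = 1.0
    z_tPA: float = 0.5
    p_tPA: float = 2.0
    k8: float = 1.0
    k9: float = 1.0
    p_BDNF: float = 10.0
    z_proBDNF: float = 0.1
    M_MR: float = 1e-4
    M_GR: float = 5.0
    p_TrkB_expr: float = 0.35
    p_p75_expr: float = 1.0
    p_p75_basal: float = 0.025
    z_TrkB: float = 1.0
    z_p75: float = 1.0
    p_actTrkB: float = 10.0
    p_actp75: float = 2.0
    z_actTrkB: float = 2.0
    z_actp75: float = 2.0
    b_a: float = 1.0
    z_a: float = 1.0
    u_NSF: float = 3.0
    u_RS: float = 0.3
    a_sign_convention: str = "trkb_positive"
    consume_on_binding: bool = True

    def __post_init__(self) -> None:
        for name in (
            "b_CaMKII", "z_CaMKII", "sigma", "z_tPA", "p_tPA", "k8", "k9", "p_BDNF",
            "z_proBDNF", "M_MR", "M_GR", "p_TrkB_expr", "p_p75_expr",
            "p_p75_basal", "z_TrkB", "z_p75", "p_actTrkB", "p_actp75", "z_actTrkB",
            "z_actp75", "b_a", "z_a", "u_NSF", "u_RS",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.M_MR < self.M_GR:
            raise ValueError(
                "M_MR must be smaller than M_GR (MR is the high-affinity "
                "cortisol receptor)"
            )
        if self.a_sign_convention not in ("trkb_positive", "p75_positive"):
            raise ValueError(
                "a_sign_convention must be 'trkb_positive' or 'p75_positive'"
            )


#: order of the cascade species in the packed state vector
CASCADE_SPECIES = (
    "CaMKII", "tPA", "proBDNF", "mBDNF",
    "TrkB", "p75", "actTrkB", "actp75", "a",
)


@dataclass(frozen=True)
class CascadeState:
    """Cascade species concentrations (normalized).  ``actTrkB`` and
    ``actp75`` are the activated mBDNF–TrkB and proBDNF–p75 complexes; ``a``
    is the production-modulation level (may be negative)."""

    CaMKII: float = 0.0
    tPA: float = 0.0
    proBDNF: float = 0.0
    mBDNF: float = 0.0
    TrkB: float = 0.0
    p75: float = 0.0
    actTrkB: float = 0.0
    actp75: float = 0.0
    a: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CASCADE_SPECIES])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CascadeState":
        return cls(**{n: float(v) for n, v in zip(CASCADE_SPECIES, arr)})


def receptor_occupancy(
    C: ArrayLike, params: CascadeParameters
) -> tuple[ArrayLike, ArrayLike]:
    """Fractional MR and GR occupancy at cortisol concentration ``C``.

    [MR] = C/(C + M_MR), [GR] = C/(C + M_GR).  Since M_MR << M_GR, MR
    saturates at very low cortisol while GR only responds to stress-level
    concentrations; MR >= GR for every C > 0.
    """
    C_arr = np.asarray(C, dtype=float)
    if np.any(C_arr < 0):
        raise ValueError("cortisol concentration must be nonnegative")
    MR = C_arr / (C_arr + params.M_MR)
    GR = C_arr / (C_arr + params.M_GR)
    if MR.ndim == 0:
        return float(MR), float(GR)
    return MR, GR


def receptor_expression_rates(
    MR: ArrayLike, GR: ArrayLike, params: CascadeParameters
) -> tuple[ArrayLike, ArrayLike]:
    """Production rates of TrkB and p75 receptors given MR/GR occupancy.

    TrkB production = p_TrkB_expr * MR * (1 - GR): MR promotes, GR
    suppresses (multiplicatively, so full GR occupancy silences TrkB
    expression).  p75 production = p_p75_expr * GR.  The opposed MR/GR
    control is what makes steady-state TrkB bell-shaped in cortisol.
    """
    MR_arr = np.asarray(MR, dtype=float)
    GR_arr = np.asarray(GR, dtype=float)
    trkb = params.p_TrkB_expr * MR_arr * (1.0 - GR_arr)
    p75 = params.p_p75_expr * GR_arr
    if trkb.ndim == 0:
        return float(trkb), float(p75)
    return trkb, p75


def cascade_rhs(
    state: CascadeState | np.ndarray,
    s_t: float,
    C: float,
    params: CascadeParameters,
) -> np.ndarray:
    """Time derivatives of the nine cascade species.

    ``s_t`` is the raw presynaptic signal; the coincidence gain σ is taken
    from ``params.sigma`` (the scenario runner overrides it per protocol
    through :func:`cascade_rhs_sigma`).
    """
    return cascade_rhs_sigma(state, s_t, params.sigma, C, params)


def cascade_rhs_sigma(
    state: CascadeState | np.ndarray,
    s_t: float,
    sigma: float,
    C: float,
    params: CascadeParameters,
) -> np.ndarray:
    """Cascade derivatives with explicit coincidence gain ``sigma``."""
    if isinstance(state, CascadeState):
        arr = state.as_array()
    else:
        arr = np.asarray(state, dtype=float)
    CaMKII, tPA, proBDNF, mBDNF, TrkB, p75, actTrkB, actp75, a = arr

    MR, GR = receptor_occupancy(C, params)
    trkb_prod, p75_prod = receptor_expression_rates(MR, GR, params)

    conversion = params.k8 * max(proBDNF, 0.0) * max(tPA, 0.0)
    backflux = params.k9 * max(mBDNF, 0.0)
    bind_trkb = params.p_actTrkB * max(mBDNF, 0.0) * max(TrkB, 0.0)
    bind_p75 = params.p_actp75 * max(proBDNF, 0.0) * max(p75, 0.0)

    dCaMKII = params.b_CaMKII * s_t - params.z_CaMKII * CaMKII
    dtPA = params.p_tPA * sigma * s_t - params.z_tPA * tPA
    dproBDNF = (
        params.p_BDNF * s_t - params.z_proBDNF * proBDNF
        - conversion + backflux
    )
    dmBDNF = conversion - backflux
    dTrkB = trkb_prod - params.z_TrkB * TrkB
    # p75 has a constitutive (cortisol-independent) expression floor on top
    # of the GR-induced production
    dp75 = params.p_p75_basal + p75_prod - params.z_p75 * p75
    if params.consume_on_binding:
        dmBDNF -= bind_trkb
        dTrkB -= bind_trkb
        dproBDNF -= bind_p75
        dp75 -= bind_p75
    dactTrkB = bind_trkb - params.z_actTrkB * actTrkB
    dactp75 = bind_p75 - params.z_actp75 * actp75

    if params.a_sign_convention == "trkb_positive":
        drive = actTrkB - actp75
    else:
        drive = actp75 - actTrkB
    da = params.b_a * drive - params.z_a * a

    return np.array(
        [dCaMKII, dtPA, dproBDNF, dmBDNF, dTrkB, dp75, dactTrkB, dactp75, da]
    )


def effective_production(
    a: float,
    base_p_NSF: float,
    base_p_RS: float,
    params: CascadeParameters,
) -> tuple[float, float]:
    """Cascade-modulated production rates of NSF and R_S.

    Linear modulation clipped at zero: p_eff = max(0, p_base + u * a).  The
    NSF channel is the more sensitive one (u_NSF = 3 by default), which is
    what lets TrkB/p75 signaling move the system across the p_NSF folds.
    """
    if base_p_NSF < 0 or base_p_RS < 0:
        raise ValueError("base production rates must be nonnegative")
    p_NSF_eff = max(0.0, base_p_NSF + params.u_NSF * a)
    p_RS_eff = max(0.0, base_p_RS + params.u_RS * a)
    return p_NSF_eff, p_RS_eff


def silent_steady_state(C: float, params: CascadeParameters) -> CascadeState:
    """Cascade steady state under silence (s ≡ 0) at cortisol level ``C``.

    With no stimulation every activity-driven species is zero and the
    receptor pools sit at their cortisol-conditioned expression/decay
    balance — the pre-equilibrated initial condition of every scenario.
    """
    MR, GR = receptor_occupancy(C, params)
    trkb_prod, p75_prod = receptor_expression_rates(MR, GR, params)
    return CascadeState(
        TrkB=trkb_prod / params.z_TrkB,
        p75=(params.p_p75_basal + p75_prod) / params.z_p75,
    )
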