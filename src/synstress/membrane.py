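"""Membrane trafficking of AMPA dimers and the transmitted-signal readout.

Heteromers R_S R_L are inserted into the postsynaptic membrane by a
CaMKII-catalyzed reaction (rate k11), removed by a glutamate-catalyzed
decomposition (rate ``k12_removal``; glutamate is identified with the
presynaptic signal s(t)) and exit spontaneously (``k12_vanish``).  The two
removal processes share the printed rate symbol k12; they are kept as
separate parameters with a common default so they can be split in
sensitivity studies.

Activated homomers in the membrane are not given their own dynamics: their
membrane pool is proportional to the cytosolic quasi-steady-state homomer
pool ([R'_S R'_S_mem] ∝ [R'_S R'_S]).

The transmitted signal — the model's stand-in for the excitatory
postsynaptic potential — is

    s_in(t) = 2 ([R'_S R'_S_mem] + [R_S R_L_mem]) s(t),

so synaptic strength is read out by probing with a standard test pulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .kinetics import CoreParameters

__all__ = [
    "MembraneParameters",
    "MembraneState",
    "membrane_rhs",
    "homomer_membrane_pool",
    "transmitted_signal",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class MembraneParameters:
    """Trafficking rates.  ``k11`` defaults to a small value so that the
    CaMKII-catalyzed heteromer pathway contributes only marginally to
    transmission relative to the homomer pool — consistent with the
    experimental dispensability of this pathway that the k11 = 0 knockout
    scenarios probe."""

    k11: float = 0.05
    k12_removal: float = 1.0
    k12_vanish: float = 1.0
    homomer_membrane_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k11", "k12_removal", "k12_vanish",
                     "homomer_membrane_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class MembraneState:
    """Membrane heteromer concentration (the only trafficked pool)."""

    RSRL_mem: float = 0.0


def membrane_rhs(
    RSRL_mem: float,
    heteromer: float,
    CaMKII: float,
    s_t: float,
    params: MembraneParameters,
) -> float:
    """d[R_S R_L_mem]/dt.

    Insertion is catalyzed by CaMKII acting on the cytosolic heteromer
    pool; removal is glutamate-catalyzed (glutamate tracks s(t)) plus a
    spontaneous exit.  Setting k11 = 0 reproduces the C-tail knockout in
    which heteromer insertion is prevented.
    """
    if min(RSRL_mem, heteromer, CaMKII, s_t) < 0:
        raise ValueError("membrane_rhs arguments must be nonnegative")
    return (
        params.k11 * heteromer * CaMKII
        - params.k12_removal * RSRL_mem * s_t
        - params.k12_vanish * RSRL_mem
    )


def homomer_membrane_pool(
    RpS: ArrayLike, core_params: CoreParameters, params: MembraneParameters
) -> ArrayLike:
    """Membrane homomer pool, proportional to the cytosolic QSS pool:
    homomer_membrane_fraction * (k1/k2) * [R'_S]^2."""
    RpS_arr = np.asarray(RpS, dtype=float)
    pool = (
        params.homomer_membrane_fraction
        * (core_params.k1 / core_params.k2)
        * RpS_arr**2
    )
    return pool if pool.ndim else float(pool)


def transmitted_signal(
    homomer_mem: ArrayLike, RSRL_mem: ArrayLike, s_t: ArrayLike
) -> ArrayLike:
    """s_in(t) = 2 ([R'_S R'_S_mem] + [R_S R_L_mem]) s(t).

    Linear in the pooled membrane concentration and in the probing signal;
    the factor 2 counts the two subunits each dimer contributes.
    """
    h = np.asarray(homomer_mem, dtype=float)
    m = np.asarray(RSRL_mem, dtype=float)
    s = np.asarray(s_t, dtype=float)
    if np.any(h < 0) or np.any(m < 0) or np.any(s < 0):
        raise ValueError("transmitted_signal arguments must be nonnegative")
    out = 2.0 * (h + m) * s
    return out if out.ndim else float(out)
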