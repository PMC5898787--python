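"""Stimulation protocols, full-system integration and named experiments.

The full synaptic state couples the three layers (13 species):

==========  ================================================
indices     species
==========  ================================================
0–2         NSF, R_S, R'_S                      (core)
3–11        CaMKII, tPA, proBDNF, mBDNF, TrkB,
            p75, actTrkB, actp75, a             (cascade)
12          R_S R_L membrane heteromers         (membrane)
==========  ================================================

A :class:`Protocol` supplies the time-dependent inputs — presynaptic signal
s(t), coincidence gain σ, cortisol C(t), an optional multiplicative
schedule on the NSF production rate (experimental interventions), and a
set of knockouts (parameters forced to zero).  Every scenario starts from a
pre-equilibrated synapse: the core at its "active" stationary point and the
cascade at its cortisol-conditioned silent steady state.

Synaptic strength is read out by probing the transmitted signal
s_in = 2(homomers_mem + heteromers_mem)·s with a standard unit test pulse
before stimulation and at the hour-5 outcome point; the fold change of the
probe is the model's EPSP ratio.  The terminal state is classified LTD /
active / LTP by basin membership: the core is relaxed under baseline
production rates and matched to the nearest stable stationary point.

The registry names the built-in experiments: six cortisol × coincidence
combinations (``fig4a``–``fig4c`` correlated, ``fig5a``–``fig5c``
noncorrelated, with descriptive aliases such as
``correlated_low_cortisol``), the same six with heteromer membrane
insertion knocked out (``fig6_*``, ``fig7_*``), and the two NSF
intervention protocols (``fig8_left`` strong reduction, ``fig8_right``
small reduction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cascade import (
    CASCADE_SPECIES,
    CascadeParameters,
    CascadeState,
    cascade_rhs_sigma,
    effective_production,
    silent_steady_state,
)
from .config import ModelConfig, ScenarioConditions, config_hash
from .equilibrium import (
    StateLabel,
    find_stationary_points,
    point_by_label,
    stable_points,
)
from .kinetics import CoreParameters, core_rhs, dimer_pools
from .membrane import (
    MembraneParameters,
    homomer_membrane_pool,
    membrane_rhs,
    transmitted_signal,
)

__all__ = [
    "Waveform",
    "boxcar",
    "constant",
    "Protocol",
    "Trajectory",
    "ScenarioResult",
    "SynapticState",
    "IntegrationError",
    "equilibrated_initial_state",
    "integrate",
    "probe_transmission",
    "classify_terminal",
    "run_scenario",
    "intervention_window_scan",
    "scenario_names",
    "SCENARIO_ALIASES",
]

STATE_NAMES = ("NSF", "RS", "RpS") + CASCADE_SPECIES + ("RSRL_mem",)
N_STATE = len(STATE_NAMES)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the failing time in ``.time``."""

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class Waveform:
    """Piecewise-constant, nonnegative time course.

    ``baseline`` holds outside all segments; later segments override
    earlier ones on overlap.  Segment values hold on [start, end).
    """

    baseline: float = 0.0
    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("waveform baseline must be nonnegative")
        for t0, t1, v in self.segments:
            if t1 <= t0:
                raise ValueError("waveform segment must have start < end")
            if v < 0:
                raise ValueError("waveform values must be nonnegative")

    def __call__(self, t: float) -> float:
        value = self.baseline
        for t0, t1, v in self.segments:
            if t0 <= t < t1:
                value = v
        return value

    def breakpoints(self) -> list[float]:
        pts = set()
        for t0, t1, _ in self.segments:
            pts.update((t0, t1))
        return sorted(pts)


def boxcar(amplitude: float, start: float, end: float,
           baseline: float = 0.0) -> Waveform:
    return Waveform(baseline=baseline, segments=((start, end, amplitude),))


def constant(value: float) -> Waveform:
    return Waveform(baseline=value)


@dataclass(frozen=True)
class Protocol:
    """Time-dependent inputs of one simulated experiment."""

    horizon: float
    signal: Waveform = field(default_factory=lambda: constant(0.0))
    sigma: float = 1.0
    cortisol: Waveform = field(default_factory=lambda: constant(0.0))
    pnsf_schedule: Optional[Waveform] = None
    knockouts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("protocol horizon must be positive")
        if self.sigma < 0:
            raise ValueError("coincidence gain sigma must be nonnegative")
        object.__setattr__(self, "knockouts", frozenset(self.knockouts))

    def breakpoints(self) -> list[float]:
        pts = {0.0, self.horizon}
        for wf in (self.signal, self.cortisol, self.pnsf_schedule):
            if wf is not None:
                pts.update(b for b in wf.breakpoints() if 0 < b < self.horizon)
        return sorted(pts)


@dataclass(frozen=True)
class SynapticState:
    """Full 13-species state (see module docstring for the packing)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_STATE,):
            raise ValueError(f"state must have {N_STATE} components")
        object.__setattr__(self, "values", arr)

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[STATE_NAMES.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    def core(self) -> np.ndarray:
        return self.values[:3]

    def cascade(self) -> CascadeState:
        return CascadeState.from_array(self.values[3:12])


def _apply_knockouts(
    knockouts: frozenset[str],
    core: CoreParameters,
    cascade: CascadeParameters,
    membrane: MembraneParameters,
):
    for name in knockouts:
        applied = False
        if hasattr(core, name):
            core = replace(core, **{name: 0.0})
            applied = True
        elif hasattr(cascade, name):
            cascade = replace(cascade, **{name: 0.0})
            applied = True
        elif hasattr(membrane, name):
            membrane = replace(membrane, **{name: 0.0})
            applied = True
        if not applied:
            raise KeyError(f"unknown knockout parameter: {name}")
    return core, cascade, membrane


def _full_rhs_factory(
    protocol: Protocol,
    core: CoreParameters,
    cascade: CascadeParameters,
    membrane: MembraneParameters,
) -> Callable[[float, np.ndarray], np.ndarray]:
    sigma = protocol.sigma

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        s_t = protocol.signal(t)
        C_t = protocol.cortisol(t)
        mult = protocol.pnsf_schedule(t) if protocol.pnsf_schedule else 1.0
        a = y[11]
        p_NSF_eff, p_RS_eff = effective_production(
            a, mult * core.p_NSF, core.p_RS, cascade
        )
        dcore = core_rhs(y[:3], p_NSF_eff, p_RS_eff, core)
        dcasc = cascade_rhs_sigma(y[3:12], s_t, sigma, C_t, cascade)
        _, heteromer = dimer_pools(max(y[1], 0.0), max(y[2], 0.0), core)
        dmem = membrane_rhs(
            max(y[12], 0.0), heteromer, max(y[3], 0.0), s_t, membrane
        )
        return np.concatenate([dcore, dcasc, [dmem]])

    return rhs


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course on a dense output grid.

    ``states`` has shape (len(times), 13) in STATE_NAMES order; ``s_in`` is
    the transmitted signal under the protocol's own s(t) (zero whenever the
    synapse is silent).  ``state_at`` interpolates the continuous solution.
    """

    times: np.ndarray
    states: np.ndarray
    s_in: np.ndarray
    protocol: Protocol

    def state_at(self, t: float) -> SynapticState:
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError("time outside trajectory range")
        vals = np.array(
            [np.interp(t, self.times, self.states[:, i]) for i in range(N_STATE)]
        )
        return SynapticState(vals)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format (time, variable, value), s_in included."""
        frames = []
        for i, name in enumerate(STATE_NAMES):
            frames.append(pd.DataFrame(
                {"time": self.times, "variable": name,
                 "value": self.states[:, i]}
            ))
        frames.append(pd.DataFrame(
            {"time": self.times, "variable": "s_in", "value": self.s_in}
        ))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def equilibrated_initial_state(
    config: ModelConfig,
    cortisol: float,
    start_label: StateLabel = StateLabel.ACTIVE,
) -> SynapticState:
    """Pre-equilibrated synapse: core at the requested stable stationary
    point, cascade at its silent steady state for the given cortisol level,
    membrane heteromer pool at its silent steady state (zero, since CaMKII
    is absent without stimulation).

    The closed-form steady state is refined by integrating a silent period
    (``conditions.pre_equilibration`` hours), which also guards against a
    mis-specified steady state for nondefault parameter choices.
    """
    pts = find_stationary_points(config.core)
    start = point_by_label(pts, start_label)
    casc = silent_steady_state(cortisol, config.cascade)
    y0 = np.concatenate([
        start.as_core_state().as_array(), casc.as_array(), [0.0]
    ])
    pre = Protocol(
        horizon=max(config.conditions.pre_equilibration, 1e-3),
        signal=constant(0.0),
        sigma=0.0,
        cortisol=constant(cortisol),
    )
    traj = integrate(pre, config, y0=SynapticState(y0))
    return SynapticState(traj.states[-1])


def integrate(
    protocol: Protocol,
    config: ModelConfig,
    y0: Optional[SynapticState] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dt_out: float = 0.01,
) -> Trajectory:
    """Solve the coupled 13-species system over the protocol horizon.

    The integration is split at every waveform discontinuity so the
    stiff-capable adaptive solver (LSODA) never steps across a jump in the
    inputs; within each segment the inputs are constant or smooth.  The
    output grid has spacing ``dt_out`` plus the exact breakpoints.
    """
    core, cascade, membrane = _apply_knockouts(
        protocol.knockouts, config.core, config.cascade, config.membrane
    )
    rhs = _full_rhs_factory(protocol, core, cascade, membrane)
    if y0 is None:
        y0 = equilibrated_initial_state(
            config, protocol.cortisol(0.0)
        )
    y = y0.values.copy()

    breaks = protocol.breakpoints()
    all_times: list[np.ndarray] = []
    all_states: list[np.ndarray] = []
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        n_pts = max(2, int(np.ceil((t1 - t0) / dt_out)) + 1)
        t_eval = np.linspace(t0, t1, n_pts)
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA",
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else t0}: "
                f"{sol.message}", float(sol.t[-1] if len(sol.t) else t0),
            )
        all_times.append(sol.t if not all_times else sol.t[1:])
        all_states.append(sol.y.T if not all_states else sol.y.T[1:])
        y = sol.y[:, -1].copy()

    times = np.concatenate(all_times)
    states = np.concatenate(all_states)

    s_vals = np.array([protocol.signal(t) for t in times])
    hom_mem = homomer_membrane_pool(
        np.clip(states[:, 2], 0.0, None), core, membrane
    )
    s_in = transmitted_signal(hom_mem, np.clip(states[:, 12], 0.0, None), s_vals)
    return Trajectory(times=times, states=states, s_in=np.asarray(s_in),
                      protocol=protocol)


def probe_transmission(
    trajectory: Trajectory,
    config: ModelConfig,
    probe_times: Optional[tuple[float, float]] = None,
    probe_amplitude: Optional[float] = None,
) -> tuple[float, float, float]:
    """Baseline and outcome transmission, probed with a standard test pulse.

    The transmitted signal is zero whenever the synapse is silent, so
    synaptic strength is measured by evaluating s_in with a test pulse of
    ``probe_amplitude`` against the membrane pools at each probe time.
    Returns (baseline, final, fold_change); the fold change is independent
    of the probe amplitude because s_in is linear in s.
    """
    cond = config.conditions
    if probe_times is None:
        probe_times = (cond.probe_baseline, cond.probe_final)
    if probe_amplitude is None:
        probe_amplitude = cond.probe_amplitude
    t_base, t_final = probe_times
    if not trajectory.times[0] <= t_base < t_final <= trajectory.times[-1]:
        raise ValueError("probe times must lie ordered within the horizon")

    core, _, membrane = _apply_knockouts(
        trajectory.protocol.knockouts, config.core, config.cascade,
        config.membrane,
    )

    def probe(t: float) -> float:
        st = trajectory.state_at(t)
        hom = homomer_membrane_pool(max(st.RpS, 0.0), core, membrane)
        return transmitted_signal(hom, max(st.RSRL_mem, 0.0), probe_amplitude)

    baseline = probe(t_base)
    final = probe(t_final)
    if baseline <= 0:
        raise ValueError(
            "baseline transmission is zero: synapse not initialized"
        )
    return baseline, final, final / baseline


def classify_terminal(
    trajectory: Trajectory,
    config: ModelConfig,
    relax_horizon: float = 200.0,
) -> StateLabel:
    """LTD / active / LTP label of the terminal state, by basin membership.

    The core subsystem is relaxed from the terminal concentrations under
    baseline production rates (the cascade modulation has decayed by then)
    and the settled state is matched to the nearest stable stationary
    point.
    """
    core, _, _ = _apply_knockouts(
        trajectory.protocol.knockouts, config.core, config.cascade,
        config.membrane,
    )
    y_end = np.clip(trajectory.states[-1, :3], 0.0, None)
    sol = solve_ivp(
        lambda t, y: core_rhs(y, core.p_NSF, core.p_RS, core),
        (0.0, relax_horizon), y_end, method="LSODA",
        rtol=1e-9, atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError("relaxation failed: " + sol.message, sol.t[-1])
    x_final = sol.y[2, -1]
    stable = stable_points(find_stationary_points(core))
    nearest = min(stable, key=lambda p: abs(p.RpS - x_final))
    return nearest.label


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one named experiment."""

    name: str
    trajectory: Trajectory
    baseline_transmission: float
    final_transmission: float
    fold_change: float
    classification: StateLabel

    def summary(self, config: Optional[ModelConfig] = None) -> dict:
        out = {
            "name": self.name,
            "baseline_transmission": self.baseline_transmission,
            "final_transmission": self.final_transmission,
            "fold_change": self.fold_change,
            "classification": self.classification.value,
        }
        if config is not None:
            out["config_hash"] = config_hash(config)
        return out

    def to_json(self, path: Union[str, Path],
                config: Optional[ModelConfig] = None) -> None:
        Path(path).write_text(json.dumps(self.summary(config), indent=2))


# --- scenario registry ------------------------------------------------------

def _stim_protocol(cond: ScenarioConditions, sigma: float, cortisol: float,
                   knockouts: frozenset[str] = frozenset(),
                   correlated: bool = True) -> Protocol:
    # correlated runs emulate a brief strong tetanus, noncorrelated runs a
    # prolonged weak (low-frequency-like) drive
    if correlated:
        signal = boxcar(cond.stimulus_amplitude, cond.stimulus_start,
                        cond.stimulus_end)
    else:
        signal = boxcar(cond.noncorr_amplitude, cond.stimulus_start,
                        cond.noncorr_end)
    return Protocol(
        horizon=cond.horizon,
        signal=signal,
        sigma=sigma,
        cortisol=constant(cortisol),
        knockouts=knockouts,
    )


def _fig8_protocol(cond: ScenarioConditions, reduction: float,
                   window: Optional[float] = None) -> Protocol:
    if window is None:
        window = cond.fig8_window
    segments = [(0.0, cond.elevation_end, cond.elevation_factor)]
    if window > 0:
        segments.append(
            (cond.reduction_start, cond.reduction_start + window, reduction)
        )
    return Protocol(
        horizon=cond.fig8_horizon,
        signal=constant(0.0),
        sigma=0.0,
        cortisol=constant(cond.cortisol_low),
        pnsf_schedule=Waveform(baseline=1.0, segments=tuple(segments)),
    )


def _registry(cond: ScenarioConditions) -> dict[str, Protocol]:
    ko = frozenset({"k11"})
    s_c, s_n = cond.sigma_correlated, cond.sigma_noncorrelated
    c_lo, c_hi, c_vl = (cond.cortisol_low, cond.cortisol_high,
                        cond.cortisol_verylow)
    return {
        "fig4a": _stim_protocol(cond, s_c, c_lo),
        "fig4b": _stim_protocol(cond, s_c, c_hi),
        "fig4c": _stim_protocol(cond, s_c, c_vl),
        "fig5a": _stim_protocol(cond, s_n, c_lo, correlated=False),
        "fig5b": _stim_protocol(cond, s_n, c_hi, correlated=False),
        "fig5c": _stim_protocol(cond, s_n, c_vl, correlated=False),
        "fig6_low": _stim_protocol(cond, s_c, c_lo, ko),
        "fig6_high": _stim_protocol(cond, s_c, c_hi, ko),
        "fig6_zero": _stim_protocol(cond, s_c, c_vl, ko),
        "fig7_low": _stim_protocol(cond, s_n, c_lo, ko, correlated=False),
        "fig7_high": _stim_protocol(cond, s_n, c_hi, ko, correlated=False),
        "fig7_zero": _stim_protocol(cond, s_n, c_vl, ko, correlated=False),
        "fig8_left": _fig8_protocol(cond, cond.reduction_strong),
        "fig8_right": _fig8_protocol(cond, cond.reduction_small),
    }


#: descriptive aliases for the registry ids
SCENARIO_ALIASES = {
    "correlated_low_cortisol": "fig4a",
    "correlated_high_cortisol": "fig4b",
    "correlated_no_cortisol": "fig4c",
    "noncorrelated_low_cortisol": "fig5a",
    "noncorrelated_high_cortisol": "fig5b",
    "noncorrelated_no_cortisol": "fig5c",
    "intervention_strong_reduction": "fig8_left",
    "intervention_small_reduction": "fig8_right",
}


def scenario_names(config: Optional[ModelConfig] = None) -> list[str]:
    """The registered scenario ids (aliases not included)."""
    cond = (config or ModelConfig()).conditions
    return sorted(_registry(cond))


def run_scenario(
    name: str,
    config: Optional[ModelConfig] = None,
    overrides: Optional[Mapping] = None,
) -> ScenarioResult:
    """Run one named experiment and measure its plasticity outcome.

    ``overrides`` is an optional config patch in the flat file schema
    (mapping of section name -> {key: value}) applied over ``config``.
    """
    if config is None:
        config = ModelConfig()
    if overrides:
        import configparser
        import io as _io

        from .config import dump_config, load_config

        cp = configparser.ConfigParser()
        cp.optionxform = str
        cp.read_string(dump_config(config))
        for sec, kv in overrides.items():
            if not cp.has_section(sec):
                cp.add_section(sec)
            for k, v in kv.items():
                cp[sec][k] = str(v)
        buf = _io.StringIO()
        cp.write(buf)
        config = load_config(buf.getvalue())
    registry = _registry(config.conditions)
    key = SCENARIO_ALIASES.get(name, name)
    if key not in registry:
        raise KeyError(
            f"unknown scenario {name!r}; registered: "
            + ", ".join(sorted(registry))
        )
    protocol = registry[key]
    y0 = equilibrated_initial_state(config, protocol.cortisol(0.0))
    traj = integrate(protocol, config, y0=y0)
    if key.startswith("fig8"):
        # intervention protocols: strength is probed before the elevation
        # cannot exist (t=0) — use the pre-stimulus active state directly
        hom0 = homomer_membrane_pool(y0.RpS, config.core, config.membrane)
        baseline = transmitted_signal(
            hom0, y0.RSRL_mem, config.conditions.probe_amplitude
        )
        st = traj.state_at(traj.times[-1])
        core, _, membrane = _apply_knockouts(
            protocol.knockouts, config.core, config.cascade, config.membrane
        )
        hom = homomer_membrane_pool(max(st.RpS, 0.0), core, membrane)
        final = transmitted_signal(
            hom, max(st.RSRL_mem, 0.0), config.conditions.probe_amplitude
        )
        fold = final / baseline
    else:
        baseline, final, fold = probe_transmission(traj, config)
    label = classify_terminal(traj, config)
    return ScenarioResult(
        name=key,
        trajectory=traj,
        baseline_transmission=baseline,
        final_transmission=final,
        fold_change=fold,
        classification=label,
    )


def intervention_window_scan(
    decrease_magnitude: float,
    window_lengths: Sequence[float],
    config: Optional[ModelConfig] = None,
) -> dict[float, StateLabel]:
    """Terminal classification as a function of the reduction window length.

    The synapse is first driven into LTP by the initial production
    elevation; from ``reduction_start`` the NSF production is multiplied by
    ``decrease_magnitude`` for each window length in turn, and the terminal
    state is classified.  A strong reduction converts LTP to LTD for all
    but under-proportionally short windows; a small reduction leaves a much
    larger range of window lengths that do not end in LTD.
    """
    if config is None:
        config = ModelConfig()
    cond = config.conditions
    y0 = equilibrated_initial_state(config, cond.cortisol_low)
    out: dict[float, StateLabel] = {}
    for w in window_lengths:
        protocol = _fig8_protocol(cond, decrease_magnitude, window=float(w))
        traj = integrate(protocol, config, y0=y0, dt_out=0.05)
        out[float(w)] = classify_terminal(traj, config)
    return out
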