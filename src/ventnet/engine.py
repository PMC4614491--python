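"""Coupled network ventilation engine.

Air is delivered at constant flow ``Q_subtree`` (one generation-11 subtree's
share of the tidal volume) into the connected air phase, which has a single
gauge pressure ``P`` (air treated as inviscid and incompressible).  At every
instant ``P`` is the unique root of the volume-conservation equation: the air
in opened airway segments (which equilibrate instantaneously to the tube law),
in open acini, and in the proximal compliance compartment (generations 0-10,
assumed open throughout, one subtree's share) must equal the delivered
volume.  Tips advance by the peeling law wherever ``P`` exceeds the local
yield pressure; an airway that completes (``s = 1``) unlocks its two
children; recruitment halts in any airway whenever ``P`` falls below its
yield and resumes when it rises above it again.  Menisci never retract
(``s`` is nondecreasing) and opened acini follow their pressure-volume law
non-hysteretically within the inflation.

`simulate` drives the compiled kernel in :mod:`ventnet._core`; the
pure-python `subtree_air_volume` / `solve_pressure` / `advance` operations
mirror its semantics step for step and serve as the readable reference path
(and test oracle) at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _core
from .errors import DomainError, NumericsError
from .network import N_AIRWAYS, Network, acinar_volume
from .reopening import (
    FluidParams,
    constant_speed_pressure,
    reference_collapsed_radius,
    velocity_coefficient,
)
from .tube_law import (
    CM_H2O,
    AirwayElastica,
    area_from_pressure,
    lambert_reference,
    transmural_pressure,
)


@dataclass(frozen=True)
class VentilatorProtocol:
    """Prescribed-tidal-volume ventilation protocol.

    ``v_t_per_kg`` (ml/kg) and ``body_mass`` (kg) set the absolute tidal
    volume, delivered at constant flow over ``t_q`` seconds and shared
    equally among ``subtree_count`` generation-11 subtrees (2^11 for the
    whole lung).  ``peep`` (cm H2O), when set, is the initial airway
    pressure; otherwise the initial pressure is the constant-speed
    recruitment pressure of the homogeneous reference network at
    ``reference_c``.
    """

    v_t_per_kg: float = 10.0
    body_mass: float = 70.0
    t_q: float = 2.5
    peep: float | None = None
    subtree_count: int = 2048
    reference_c: float = 0.2

    def __post_init__(self) -> None:
        if self.v_t_per_kg < 0 or self.body_mass <= 0 or self.t_q <= 0:
            raise DomainError("tidal volume, body mass and T_Q must be positive")
        if self.subtree_count < 1:
            raise DomainError("subtree_count must be at least 1")
        if not (0.0 < self.reference_c <= 1.0):
            raise DomainError("reference_c must lie in (0, 1]")
        if self.v_t_per_kg == 0 and self.peep is None:
            raise DomainError("zero tidal volume requires an explicit PEEP")

    @property
    def q_subtree(self) -> float:
        """Subtree inflow, cm^3/s."""
        return (self.v_t_per_kg * self.body_mass / self.subtree_count) / self.t_q


@dataclass(frozen=True)
class Numerics:
    """Time-step controller and solver settings.

    ``dt_scale`` scales every step-size cap together (halve it to halve the
    step); ``ds_cap`` limits the recruited-fraction advance per step,
    ``dp_cap_cmh2o`` the pressure change per step.  ``vol_tol`` is the
    volume-conservation residual tolerance (cm^3).
    """

    dt_scale: float = 1.0
    ds_cap: float = 0.1
    dp_cap_cmh2o: float = 0.05
    dt_max: float = 0.02
    dt_init: float = 1e-6
    dt_floor: float = 1e-11
    vol_tol: float = 1e-11
    max_steps: int = 200_000

    def scaled(self) -> "Numerics":
        f = self.dt_scale
        return replace(
            self,
            dt_scale=1.0,
            ds_cap=self.ds_cap * f,
            dp_cap_cmh2o=self.dp_cap_cmh2o * f,
            dt_max=self.dt_max * f,
            dt_init=self.dt_init * f,
        )


_TERMINATIONS = {
    _core.TERM_OK: "completed_inflation",
    _core.TERM_MAX_STEPS: "max_steps_exceeded",
    _core.TERM_SOLVER: "pressure_solver_failure",
}


@dataclass
class EngineArrays:
    """Flat per-airway / proximal / acinar arrays consumed by the kernel."""

    aw: dict[str, np.ndarray]
    px: dict[str, np.ndarray]
    ac_PA: float
    ac_K: float
    ac_VA: float


def _build_arrays(
    net: Network, fluid: FluidParams, protocol: VentilatorProtocol
) -> EngineArrays:
    n = len(net.airways)
    aw = {
        k: np.empty(n)
        for k in (
            "alpha0", "n1", "n2", "P1", "P2", "Amax", "L", "Pc", "kU",
            "Goff", "Gden",
        )
    }
    for i, airway in enumerate(net.airways):
        el = airway.elastica
        p = el.params
        aw["alpha0"][i] = p.alpha0
        aw["n1"][i] = p.n1
        aw["n2"][i] = p.n2
        aw["P1"][i] = p.P1
        aw["P2"][i] = p.P2
        aw["Amax"][i] = el.A_max
        aw["L"][i] = airway.length
        aw["Pc"][i] = airway.reopening.P_yield
        aw["kU"][i] = velocity_coefficient(el, fluid)
        a_init = airway.reopening.a_init
        r_c = reference_collapsed_radius(el, airway.reopening.collapse_C)
        # tip-gradient numerator offset: G = (P - Goff) / Gden
        aw["Goff"][i] = (
            transmural_pressure(a_init, el) - 2.0 * fluid.gamma / r_c
        )
        aw["Gden"][i] = fluid.tip_width_factor * r_c * 1.0e4
    m = 11
    px = {k: np.empty(m) for k in ("alpha0", "n1", "n2", "P1", "P2", "Amax", "wl")}
    for j in range(m):
        p = lambert_reference(j)
        px["alpha0"][j] = p.alpha0
        px["n1"][j] = p.n1
        px["n2"][j] = p.n2
        px["P1"][j] = p.P1
        px["P2"][j] = p.P2
        px["Amax"][j] = p.A_max_ref
        px["wl"][j] = p.length * 2.0**j / protocol.subtree_count
    ac = net.acini[0]
    return EngineArrays(
        aw=aw,
        px=px,
        ac_PA=ac.P_A * CM_H2O,
        ac_K=ac.K_A / CM_H2O,
        ac_VA=ac.V_A,
    )


def initial_pressure(protocol: VentilatorProtocol, fluid: FluidParams) -> float:
    """Initial airway pressure (dyn cm^-2): PEEP if set, otherwise the
    constant-speed recruitment pressure of the homogeneous reference network."""
    if protocol.peep is not None:
        return protocol.peep * CM_H2O
    return constant_speed_pressure(
        protocol.q_subtree, fluid, reference_C=protocol.reference_c
    )


# ---------------------------------------------------------------------------
# Reference (pure-python) state and operations.


@dataclass
class SimState:
    """Instantaneous engine state for the reference path."""

    t: float
    P: float  # dyn cm^-2
    network: Network
    arrays: EngineArrays
    protocol: VentilatorProtocol
    fluid: FluidParams
    P_ref: float  # pressure defining the volume reference (initial pressure)
    s: np.ndarray = field(default=None)  # type: ignore[assignment]
    state_code: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.s is None:
            self.s = np.zeros(N_AIRWAYS)
        if self.state_code is None:
            self.state_code = np.zeros(N_AIRWAYS, dtype=np.int8)
            self.state_code[0] = 1

    @property
    def delivered_volume(self) -> float:
        return self.protocol.q_subtree * self.t


def make_state(
    net: Network,
    protocol: VentilatorProtocol,
    fluid: FluidParams | None = None,
) -> SimState:
    fluid = fluid or FluidParams()
    p0 = initial_pressure(protocol, fluid)
    return SimState(
        t=0.0,
        P=p0,
        network=net,
        arrays=_build_arrays(net, fluid, protocol),
        protocol=protocol,
        fluid=fluid,
        P_ref=p0,
    )


def _absolute_volume(P: float, state: SimState, s: np.ndarray) -> float:
    """Air volume at pressure P for given recruited fractions (cm^3)."""
    a = state.arrays
    net = state.network
    V = 0.0
    for i, airway in enumerate(net.airways):
        if s[i] > 0.0:
            V += s[i] * airway.length * area_from_pressure(P, airway.elastica)
    for j in range(len(a.px["wl"])):
        p = lambert_reference(j)
        V += a.px["wl"][j] * area_from_pressure(P, AirwayElastica(p, 1.0))
    for k, ac in enumerate(net.acini):
        if state.state_code[31 + k] == 2:
            V += acinar_volume(P, ac)
    return V


def subtree_air_volume(P: float, state: SimState) -> float:
    """Subtree air volume relative to the initial reference (cm^3).

    Sum of opened airway-segment volumes at the tube-law area, open-acinus
    volumes, and the change in the proximal compartment volume since the
    initial pressure; strictly increasing in ``P``.
    """
    zero = np.zeros(N_AIRWAYS)
    return _absolute_volume(P, state, state.s) - _absolute_volume(
        state.P_ref, replace_state_zero(state), zero
    )


def replace_state_zero(state: SimState) -> SimState:
    """State with no recruitment and no open acini, for the volume reference."""
    ref = SimState(
        t=0.0,
        P=state.P_ref,
        network=state.network,
        arrays=state.arrays,
        protocol=state.protocol,
        fluid=state.fluid,
        P_ref=state.P_ref,
    )
    return ref


def solve_pressure(V_target: float, state: SimState, tol: float = 1e-11) -> float:
    """The unique pressure with ``subtree_air_volume(P) = V_target`` (bracketed)."""
    if V_target < 0:
        raise DomainError("target volume must be nonnegative")

    def f(P: float) -> float:
        return subtree_air_volume(P, state) - V_target

    lo, hi = state.P - 50.0, state.P + 50.0
    step = 100.0
    for _ in range(120):
        if f(lo) < 0.0:
            break
        lo -= step
        step *= 2.0
    else:
        raise NumericsError(f"no lower bracket for V_target={V_target}")
    step = 100.0
    for _ in range(120):
        if f(hi) > 0.0:
            break
        hi += step
        step *= 2.0
    else:
        raise NumericsError(f"no upper bracket for V_target={V_target}")
    root = brentq(f, lo, hi, xtol=1e-9, rtol=8.9e-16, maxiter=300)
    if abs(f(root)) > max(tol, 1e-9):
        raise NumericsError(
            f"pressure solve residual {f(root):.3e} cm^3 exceeds tolerance at "
            f"P={root / CM_H2O:.4f} cm H2O, t={state.t:.6f} s"
        )
    return float(root)


def advance(state: SimState, dt: float) -> SimState:
    """One implicit step of the reference path (mirrors the kernel).

    Trial recruited fractions at the new pressure follow the peeling law;
    the new pressure solves volume conservation at ``t + dt``; completions
    unlock children; acini switch on when their parent is recruited and the
    pressure is above the acinar opening pressure.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    a = state.arrays
    t_new = state.t + dt
    V_target = state.protocol.q_subtree * t_new

    def trial_s(P: float) -> np.ndarray:
        u = np.where(
            state.state_code == 1,
            np.maximum(0.0, a.aw["kU"] * (P - a.aw["Pc"])),
            0.0,
        )
        s = np.where(
            state.state_code == 2,
            1.0,
            np.minimum(1.0, state.s + dt * u / a.aw["L"]),
        )
        return np.where(state.state_code == 0, 0.0, s)

    zero = np.zeros(N_AIRWAYS)
    v_ref = _absolute_volume(state.P_ref, replace_state_zero(state), zero)

    def f(P: float) -> float:
        return _absolute_volume(P, state, trial_s(P)) - v_ref - V_target

    lo, hi = state.P - 50.0, state.P + 50.0
    step = 100.0
    while f(lo) > 0.0:
        lo -= step
        step *= 2.0
    step = 100.0
    while f(hi) < 0.0:
        hi += step
        step *= 2.0
    P_new = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16, maxiter=300)

    new = SimState(
        t=t_new,
        P=float(P_new),
        network=state.network,
        arrays=a,
        protocol=state.protocol,
        fluid=state.fluid,
        P_ref=state.P_ref,
        s=trial_s(P_new).copy(),
        state_code=state.state_code.copy(),
    )
    for i in range(N_AIRWAYS):
        if new.state_code[i] == 1 and new.s[i] >= 1.0 - 1e-9:
            new.s[i] = 1.0
            new.state_code[i] = 2
            if i < 31:
                new.state_code[2 * i + 1] = max(new.state_code[2 * i + 1], 1)
                new.state_code[2 * i + 2] = max(new.state_code[2 * i + 2], 1)
    return new


# ---------------------------------------------------------------------------
# Simulation driver (compiled kernel).


@dataclass
class SimResult:
    """Output of one ventilation simulation.

    ``trace`` columns: ``t_s``, ``P_cmH2O``, ``V_subtree_cm3`` (delivered),
    ``V_lung_ml`` (whole-lung extrapolation), ``n_recruited``,
    ``n_acini_open``, ``n_peeling``, ``residual_cm3``.  ``airways`` holds one
    row per airway with recruitment times and the maximal tip pressure
    gradient ``G_max`` (dyn cm^-2 um^-1).
    """

    trace: pd.DataFrame
    airways: pd.DataFrame
    acini: pd.DataFrame
    t_first_passage: float | None
    t_recruit_all: float | None
    termination: str
    P_init: float  # dyn cm^-2
    V_ref: float  # cm^3, absolute subtree air volume at t = 0
    seed: int | None
    residual_max: float

    @property
    def complete(self) -> bool:
        return self.t_recruit_all is not None


def simulate(
    net: Network,
    protocol: VentilatorProtocol | None = None,
    fluid: FluidParams | None = None,
    numerics: Numerics | None = None,
) -> SimResult:
    """Run one fixed-tidal-volume inflation of a (possibly partly) collapsed
    network and return traces, event times and per-airway stress maxima."""
    protocol = protocol or VentilatorProtocol()
    fluid = fluid or FluidParams()
    numerics = (numerics or Numerics()).scaled()
    arrays = _build_arrays(net, fluid, protocol)
    p0 = initial_pressure(protocol, fluid)

    aw, px = arrays.aw, arrays.px
    out = _core.run_kernel(
        aw["alpha0"], aw["n1"], aw["n2"], aw["P1"], aw["P2"], aw["Amax"],
        aw["L"], aw["Pc"], aw["kU"], aw["Goff"], aw["Gden"],
        px["alpha0"], px["n1"], px["n2"], px["P1"], px["P2"], px["Amax"],
        px["wl"],
        arrays.ac_PA, arrays.ac_K, arrays.ac_VA,
        protocol.q_subtree, protocol.t_q, p0,
        numerics.ds_cap, numerics.dp_cap_cmh2o * CM_H2O, numerics.dt_max,
        numerics.dt_init, numerics.dt_floor, numerics.vol_tol,
        numerics.max_steps,
    )
    (tr_t, tr_P, tr_nrec, tr_nac, tr_npeel, tr_resid,
     s, state, t_start, t_complete, g_max, ac_time, v_ref, term) = out

    if term == _core.TERM_SOLVER:
        raise NumericsError(
            f"pressure solver failed at t={tr_t[-1]:.6g} s "
            f"(P={tr_P[-1] / CM_H2O:.4g} cm H2O, {int(tr_nrec[-1])} recruited)"
        )

    delivered = protocol.q_subtree * tr_t
    trace = pd.DataFrame(
        {
            "t_s": tr_t,
            "P_cmH2O": tr_P / CM_H2O,
            "V_subtree_cm3": delivered,
            "V_lung_ml": (v_ref + delivered) * protocol.subtree_count,
            "n_recruited": tr_nrec,
            "n_acini_open": tr_nac,
            "n_peeling": tr_npeel,
            "residual_cm3": tr_resid,
        }
    )
    gens = np.array([a.generation for a in net.airways])
    airways = pd.DataFrame(
        {
            "id": np.arange(len(net.airways)),
            "generation": gens,
            "lam": net.lambdas,
            "length_cm": [a.length for a in net.airways],
            "a_eq_cm2": [a.elastica.a_eq for a in net.airways],
            "P_yield_cmH2O": aw["Pc"] / CM_H2O,
            "s_final": s,
            "recruited": state == 2,
            "t_start_s": np.where(t_start >= 0, t_start, np.nan),
            "t_complete_s": np.where(t_complete >= 0, t_complete, np.nan),
            "G_max": g_max,
        }
    )
    acini = pd.DataFrame(
        {
            "parent_airway_id": np.arange(31, 63),
            "opened": ac_time >= 0,
            "open_time_s": np.where(ac_time >= 0, ac_time, np.nan),
        }
    )
    terminal_done = t_complete[31:]
    t_fp = float(terminal_done[terminal_done >= 0].min()) if np.any(
        terminal_done >= 0
    ) else None
    t_all = float(t_complete.max()) if np.all(t_complete >= 0) else None
    termination = _TERMINATIONS[term]
    if termination == "completed_inflation" and t_all is None:
        termination = "incomplete_recruitment"
    return SimResult(
        trace=trace,
        airways=airways,
        acini=acini,
        t_first_passage=t_fp,
        t_recruit_all=t_all,
        termination=termination,
        P_init=p0,
        V_ref=v_ref,
        seed=net.seed,
        residual_max=float(tr_resid.max()),
    )
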