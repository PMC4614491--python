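"""Single-airway recruitment mechanics.

A flooded, collapsed airway reopens by "peeling": an air finger advances at a
speed that rises with the airway pressure once that pressure exceeds a
threshold (yield) pressure specific to the airway.  The laws here are
reduced-order: each is a scalar closed form in the airway's elastica, its
initial collapse fraction ``C`` and the liquid properties, chosen so that the
full set of qualitative orderings of the underlying single-airway physics
holds simultaneously:

* yield pressure strictly decreasing along generations 11 -> 16 of a
  homogeneous network;
* yield pressure strictly increasing in ``C`` (a more strongly collapsed
  airway stores more elastic energy and yields at lower pressure);
* yield pressure strictly decreasing, and peeling speed increasing, in the
  scale parameter ``lambda`` (wider, more compliant airways open at lower
  pressure; stiffer airways open faster once yielded);
* tip pressure gradient strictly increasing in the excess pressure, with a
  finite capillary floor at yield, and largest in the narrowest airways.

Default law ("default" variant):

* ``P_yield = beta * F(a_init) + c_y * P1 * lambda**-0.5``, where
  ``F(a_init)`` is the (negative) elastic recoil of the wall at the collapsed
  area ``a_init = C * a_eq``, ``beta`` the fraction of that stored recoil
  available to drive the tip, ``P1`` the collapsed-branch pressure scale of
  the tube law, and ``c_y`` a dimensionless adhesion coefficient calibrated
  once against the constant-speed recruitment worked example (generation 11,
  C = 0.2, 10 ml/kg over 2.5 s -> 0.822 cm H2O).  An optional longitudinal
  tension correction ``c_T * T / l_T**2`` is provided as a hook (default
  coefficient 0).
* ``U = (m0 / mu) * r_eq * (P - P_yield) * lambda**-q`` for ``P > P_yield``,
  else 0; linear in the excess pressure as in channel peeling models.
* ``G = (P - F(a_init) + 2 gamma / r_c) / (w * r_c)``, reported per
  micrometre, with ``r_c`` the generation's reference collapsed radius
  (``lambda = 1``): the jump from the air pressure to the static liquid
  pressure ahead of the tip — including the capillary jump across the
  meniscus, which dominates in the narrowest airways — across a tip region a
  fraction ``w`` of that radius.  Using the generation-reference radius
  keeps within-generation damage variation governed by the pressure history
  (avalanche timing) rather than tied deterministically to the airway's own
  scale parameter.

All quantities CGS unless noted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NumericsError
from .tube_law import (
    CM_H2O,
    AirwayElastica,
    lambert_reference,
    area_from_pressure,
    transmural_pressure,
)


@dataclass(frozen=True)
class FluidParams:
    """Liquid and reopening-law parameters (CGS).

    ``gamma`` surface tension (dyn/cm), ``mu`` viscosity (dyn s/cm^2) and
    ``tension_T`` longitudinal wall tension (dyn/cm) carry the lining-fluid
    physics; the remaining dimensionless constants shape the reduced laws.
    ``adhesion_coeff`` (c_y) and ``elastic_release_beta`` (beta) are fixed by
    the ordering constraints and the constant-speed worked example; see the
    module docstring and docs/methods.md.
    """

    gamma: float = 30.0
    mu: float = 0.01
    tension_T: float = 3000.0
    mobility_m0: float = 1.0
    stiffness_exponent_q: float = 1.0
    tip_width_factor: float = 0.3
    adhesion_coeff: float = 2.124
    elastic_release_beta: float = 0.2
    tension_coeff: float = 0.0
    tension_length: float = 1.0  # cm
    law_variant: str = "default"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.mu <= 0:
            raise DomainError("gamma and mu must be positive")
        if self.tension_T < 0:
            raise DomainError("tension_T must be nonnegative")
        if self.mobility_m0 <= 0 or self.tip_width_factor <= 0:
            raise DomainError("mobility_m0 and tip_width_factor must be positive")
        if self.stiffness_exponent_q < 0:
            raise DomainError("stiffness_exponent_q must be nonnegative")
        if self.law_variant not in _LAW_VARIANTS:
            raise DomainError(
                f"unknown reopening law variant {self.law_variant!r}; "
                f"available: {sorted(_LAW_VARIANTS)}"
            )


class Status(str, enum.Enum):
    BLOCKED = "blocked"
    READY = "ready"
    PEELING = "peeling"
    STALLED = "stalled"
    RECRUITED = "recruited"


@dataclass
class ReopeningState:
    """Recruitment state of one airway."""

    elastica: AirwayElastica
    collapse_C: float
    a_init: float
    P_yield: float  # dyn cm^-2
    s: float = 0.0  # recruited fraction of length
    status: Status = Status.BLOCKED
    G_max: float = 0.0  # dyn cm^-2 um^-1

    @classmethod
    def create(
        cls, elastica: AirwayElastica, collapse_C: float, fluid: FluidParams
    ) -> "ReopeningState":
        a_init = collapse_C * elastica.a_eq
        return cls(
            elastica=elastica,
            collapse_C=collapse_C,
            a_init=a_init,
            P_yield=yield_pressure(elastica, collapse_C, fluid),
        )


def _check_collapse(collapse_C: float) -> None:
    if not (0.0 < collapse_C <= 1.0):
        raise DomainError(f"collapse fraction must lie in (0, 1], got {collapse_C}")


def yield_pressure(
    el: AirwayElastica, collapse_C: float, fluid: FluidParams
) -> float:
    """Threshold (yield) opening pressure of an airway, dyn cm^-2."""
    _check_collapse(collapse_C)
    return _LAW_VARIANTS[fluid.law_variant]["yield"](el, collapse_C, fluid)


def _yield_default(el: AirwayElastica, C: float, fluid: FluidParams) -> float:
    f_init = transmural_pressure(C * el.a_eq, el)
    adhesion = fluid.adhesion_coeff * el.params.P1 * el.lam**-0.5
    tension = fluid.tension_coeff * fluid.tension_T / fluid.tension_length**2
    return fluid.elastic_release_beta * f_init + adhesion + tension


def reference_collapsed_radius(el: AirwayElastica, collapse_C: float) -> float:
    """Collapsed equivalent radius of the generation's reference airway
    (``lambda = 1``): ``sqrt(C * alpha0 * A_max_ref / pi)`` (cm)."""
    _check_collapse(collapse_C)
    return float(
        np.sqrt(collapse_C * el.params.alpha0 * el.params.A_max_ref / np.pi)
    )


def velocity_coefficient(el: AirwayElastica, fluid: FluidParams) -> float:
    """dU/dP above yield: ``m0 * r_eq / (mu * lambda**q)`` (cm s^-1 per dyn cm^-2)."""
    return (
        fluid.mobility_m0
        * el.r_eq
        / (fluid.mu * el.lam**fluid.stiffness_exponent_q)
    )


def peeling_velocity(P: float, state: ReopeningState, fluid: FluidParams) -> float:
    """Tip advance speed (cm/s): zero at/below yield, linear in excess pressure."""
    excess = P - state.P_yield
    if excess <= 0.0:
        return 0.0
    return velocity_coefficient(state.elastica, fluid) * excess


def tip_pressure_gradient(
    P: float, state: ReopeningState, fluid: FluidParams
) -> float:
    """Liquid pressure gradient across the advancing tip, dyn cm^-2 um^-1.

    The normal-stress jump from the air to the static liquid ahead of the
    tip — air pressure ``P``, minus the liquid pressure ``F(a_init)`` set by
    the collapsed flooded wall, plus the capillary jump across the meniscus —
    acting over a tip length a fraction ``w`` of the generation's reference
    collapsed radius.  Frozen at the initial collapsed geometry, the gradient
    is strictly increasing in ``P`` and largest in the most collapsed, most
    peripheral airways, where the capillary jump dominates.
    """
    r_c = reference_collapsed_radius(state.elastica, state.collapse_C)
    f_init = transmural_pressure(state.a_init, state.elastica)
    length_um = fluid.tip_width_factor * r_c * 1.0e4
    return (P - f_init + 2.0 * fluid.gamma / r_c) / length_um


def constant_speed_pressure(
    q_subtree: float,
    fluid: FluidParams,
    reference_C: float = 0.2,
    generation: int = 11,
) -> float:
    """Airway pressure at which a homogeneous root airway recruits at constant
    speed: the root of ``Q_subtree = a(P) * U(P)`` (dyn cm^-2).

    This is the pressure at which the air-finger volume gain in the root
    airway exactly absorbs the prescribed inflow; used as the initial airway
    pressure when no PEEP is applied.
    """
    if q_subtree <= 0:
        raise DomainError("subtree flow must be positive")
    _check_collapse(reference_C)
    el = AirwayElastica(lambert_reference(generation), 1.0)
    p_c = yield_pressure(el, reference_C, fluid)
    k_u = velocity_coefficient(el, fluid)

    def shortfall(P: float) -> float:
        return area_from_pressure(P, el) * k_u * max(0.0, P - p_c) - q_subtree

    lo = p_c
    hi = p_c + CM_H2O
    for _ in range(60):
        if shortfall(hi) > 0.0:
            break
        hi += CM_H2O * 2.0 ** max(0, _ - 10)
    else:
        raise NumericsError(
            f"no constant-speed root in [{lo / CM_H2O:.3f}, {hi / CM_H2O:.3f}] cm H2O "
            f"for Q_subtree = {q_subtree:.4g} cm^3/s"
        )
    return float(brentq(shortfall, lo, hi, xtol=1e-10, rtol=1e-14))


_LAW_VARIANTS: dict[str, dict] = {
    "default": {"yield": _yield_default},
}
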