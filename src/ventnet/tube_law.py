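"""Elastic pressure--area mechanics of individual airways.

Each airway obeys a two-branch "tube law" relating transmural pressure
(internal minus external) to cross-sectional area, in the Lambert
parametrisation.  With ``alpha = a / A_max`` the normalised area,

* collapsed branch (``P <= 0``):  ``alpha = alpha0 * (1 - P/P1)**(-n1)``
* distended branch (``P > 0``):   ``alpha = 1 - (1 - alpha0) * (1 - P/P2)**(-n2)``

where ``P1 = alpha0 * n1 / alpha0'`` and ``P2 = -(1 - alpha0) * n2 / alpha0'``
are fixed by continuity of value and slope at zero transmural pressure,
``alpha0`` being the normalised area there and ``alpha0'`` the slope.  The law
is strictly increasing, maps all real pressures onto ``(0, A_max)``, and is
analytically invertible on both branches.

Heterogeneity enters through a single dimensionless scale parameter
``lambda`` which multiplies the reference maximal area of the generation:
``F(a; lambda) = F(a / lambda; 1)``.  One parameter therefore simultaneously
sets the maximal extension, the equilibrium (zero transmural pressure) area
``a_eq = alpha0 * lambda * A_max_ref`` and the wall stiffness
``Gamma = dF/da``, which scales as ``1 / lambda`` at fixed ``a / A_max``.

Internal unit system is CGS (dyn, cm, s); tabulated compliances are per
cm H2O and are converted on load.  Pressures are reported to users in
cm H2O through :data:`CM_H2O`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .errors import DomainError

#: dyn cm^-2 per cm H2O; the single unit-conversion constant of the package.
CM_H2O = 980.665

_TABLE_RESOURCE = "lambert1982.json"


@dataclass(frozen=True)
class TubeLawParams:
    """Per-generation elastic and geometric constants of the tube law.

    ``alpha0_prime`` is stored as tabulated (per cm H2O); the derived pressure
    scales ``P1`` (collapsed branch, positive) and ``P2`` (distended branch,
    negative) are in CGS.
    """

    generation: int
    A_max_ref: float  # cm^2, per airway
    alpha0: float
    alpha0_prime: float  # (cm H2O)^-1
    n1: float
    n2: float
    length: float  # cm

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha0 < 1.0):
            raise DomainError(f"alpha0 must lie in (0, 1), got {self.alpha0}")
        if self.alpha0_prime <= 0 or self.n1 <= 0 or self.n2 <= 0:
            raise DomainError("alpha0_prime, n1 and n2 must be positive")
        if self.A_max_ref <= 0 or self.length <= 0:
            raise DomainError("A_max_ref and length must be positive")

    @property
    def alpha0_prime_cgs(self) -> float:
        """Slope of alpha(P) at P = 0 in (dyn cm^-2)^-1."""
        return self.alpha0_prime / CM_H2O

    @property
    def P1(self) -> float:
        """Collapsed-branch pressure scale (dyn cm^-2, > 0)."""
        return self.alpha0 * self.n1 / self.alpha0_prime_cgs

    @property
    def P2(self) -> float:
        """Distended-branch pressure scale (dyn cm^-2, < 0)."""
        return -(1.0 - self.alpha0) * self.n2 / self.alpha0_prime_cgs


@dataclass(frozen=True)
class AirwayElastica:
    """A tube law instantiated for one airway: generation constants plus the
    airway's scale parameter ``lam`` (> 0), which rescales the maximal area."""

    params: TubeLawParams
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DomainError(f"lambda must be positive, got {self.lam}")

    @property
    def A_max(self) -> float:
        return self.lam * self.params.A_max_ref

    @property
    def a_eq(self) -> float:
        """Equilibrium area, where transmural pressure vanishes (cm^2)."""
        return self.params.alpha0 * self.A_max

    @property
    def r_eq(self) -> float:
        """Equivalent circular radius at equilibrium (cm)."""
        return float(np.sqrt(self.a_eq / np.pi))


@lru_cache(maxsize=1)
def _load_table() -> dict[int, TubeLawParams]:
    raw = json.loads(
        (resources.files("ventnet") / "data" / _TABLE_RESOURCE).read_text()
    )
    table = {}
    for row in raw["generations"]:
        g = row["generation"]
        table[g] = TubeLawParams(
            generation=g,
            A_max_ref=row["area_total"] / 2.0**g,
            alpha0=row["alpha0"],
            alpha0_prime=row["alpha0_prime"],
            n1=row["n1"],
            n2=row["n2"],
            length=row["length"],
        )
    return table


def lambert_reference(generation: int) -> TubeLawParams:
    """Return the embedded constants-table entry for a generation (0-16)."""
    table = _load_table()
    if generation not in table:
        raise DomainError(
            f"generation {generation} outside the tabulated range 0-16"
        )
    return table[generation]


def _alpha_of_pressure(P, p: TubeLawParams):
    """Normalised area alpha(P); accepts scalars or arrays, defined for all P."""
    P = np.asarray(P, dtype=float)
    collapsed = p.alpha0 * (1.0 - np.minimum(P, 0.0) / p.P1) ** (-p.n1)
    distended = 1.0 - (1.0 - p.alpha0) * (1.0 - np.maximum(P, 0.0) / p.P2) ** (
        -p.n2
    )
    return np.where(P <= 0.0, collapsed, distended)


def transmural_pressure(a, el: AirwayElastica):
    """Transmural pressure F(a) in dyn cm^-2 for area(s) ``a`` in (0, A_max)."""
    p = el.params
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= el.A_max):
        raise DomainError(
            f"area must lie strictly inside (0, {el.A_max:.6g}) cm^2"
        )
    alpha = a / el.A_max
    low = p.P1 * (1.0 - (p.alpha0 / np.minimum(alpha, p.alpha0)) ** (1.0 / p.n1))
    high = p.P2 * (
        1.0 - ((1.0 - p.alpha0) / (1.0 - np.maximum(alpha, p.alpha0))) ** (1.0 / p.n2)
    )
    out = np.where(alpha <= p.alpha0, low, high)
    return out if out.ndim else float(out)


def area_from_pressure(P, el: AirwayElastica):
    """Inverse tube law: the unique area with ``transmural_pressure(a) = P``.

    Closed form on both branches; defined for every real pressure (the law
    maps all of R onto ``(0, A_max)``).
    """
    out = _alpha_of_pressure(P, el.params) * el.A_max
    return out if np.ndim(out) else float(out)


def stiffness(a, el: AirwayElastica):
    """Wall stiffness Gamma(a) = dF/da in dyn cm^-4 (analytic derivative)."""
    p = el.params
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0.0) or np.any(a >= el.A_max):
        raise DomainError(
            f"area must lie strictly inside (0, {el.A_max:.6g}) cm^2"
        )
    alpha = a / el.A_max
    al = np.minimum(alpha, p.alpha0)
    low = (p.P1 / p.n1) * p.alpha0 ** (1.0 / p.n1) * al ** (-1.0 / p.n1 - 1.0)
    ah = np.maximum(alpha, p.alpha0)
    high = (
        (-p.P2 / p.n2)
        * (1.0 - p.alpha0) ** (1.0 / p.n2)
        * (1.0 - ah) ** (-1.0 / p.n2 - 1.0)
    )
    out = np.where(alpha <= p.alpha0, low, high) / el.A_max
    return out if out.ndim else float(out)
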