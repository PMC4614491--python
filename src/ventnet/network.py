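"""Stochastic six-generation bifurcating airway tree with terminal acini.

The modelled domain is one generation-11 subtree of the adult lung: 63
airways over generations 11-16 (2^(j-11) airways in generation j, dichotomous
branching) with one compliant acinus downstream of each of the 32 terminal
generation-16 airways.  Heterogeneity enters through the per-airway scale
parameter ``lambda``, drawn independently from a unit-mean normal with
standard deviation ``d``, redrawn while at or below a small positive floor so
the distribution stays positive without an atom at the boundary.  Every
airway starts uniformly collapsed to ``C`` times its equilibrium area.

Airways are indexed breadth-first: airway 0 is the generation-11 root and the
children of airway ``i`` are ``2 i + 1`` and ``2 i + 2``; airways 31-62 are
generation 16 and carry acini.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, SchemaError
from .reopening import FluidParams, ReopeningState, Status
from .tube_law import CM_H2O, AirwayElastica, lambert_reference

GENERATIONS = range(11, 17)
N_AIRWAYS = 63
N_ACINI = 32
NETWORK_SCHEMA_VERSION = "1"

#: Table-1 acinus defaults: maximal volume (cm^3), compliance (cm H2O^-1),
#: acinar opening pressure (cm H2O).
V_A_DEFAULT = 0.0778
K_A_DEFAULT = 0.14
P_A_DEFAULT = 2.0

LAMBDA_FLOOR_DEFAULT = 0.05


@dataclass
class Airway:
    id: int
    generation: int
    parent_id: int | None
    child_ids: tuple[int, int] | tuple[()]
    elastica: AirwayElastica
    reopening: ReopeningState
    length: float  # cm

    @property
    def lam(self) -> float:
        return self.elastica.lam


@dataclass
class Acinus:
    """Terminal compliant compartment: modified Salazar-Knowles law
    ``V(P) = V_A (1 - exp(-K_A (P - P_A)))`` above the opening pressure."""

    parent_airway_id: int
    V_A: float = V_A_DEFAULT
    K_A: float = K_A_DEFAULT  # (cm H2O)^-1
    P_A: float = P_A_DEFAULT  # cm H2O
    opened: bool = False
    open_time: float | None = None


@dataclass
class Network:
    airways: list[Airway]
    acini: list[Acinus]
    heterogeneity_d: float
    collapse_C: float
    seed: int
    lambda_floor: float = LAMBDA_FLOOR_DEFAULT

    def airway_generation(self, i: int) -> int:
        return self.airways[i].generation

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([a.lam for a in self.airways])


def generation_of_index(i: int) -> int:
    """Generation (11-16) of breadth-first airway index ``i`` (0-62)."""
    return 11 + int(np.log2(i + 1))


def sample_lambda(
    d: float, rng: np.random.Generator, floor: float = LAMBDA_FLOOR_DEFAULT
) -> float:
    """One draw of the scale parameter: Normal(1, d^2) truncated by redraw.

    Redrawing (rather than clipping) below the floor keeps the distribution
    atom-free; at the heterogeneity levels studied (d <= 0.5) the truncated
    mass is negligible.
    """
    if d < 0:
        raise DomainError(f"heterogeneity s.d. must be nonnegative, got {d}")
    if d == 0:
        return 1.0
    while True:
        lam = rng.normal(1.0, d)
        if lam > floor:
            return float(lam)


def build_network(
    d: float,
    C: float,
    seed: int,
    fluid: FluidParams | None = None,
    lambda_floor: float = LAMBDA_FLOOR_DEFAULT,
) -> Network:
    """Sample a 63-airway tree (generations 11-16) with 32 acini.

    Deterministic given ``seed``: lambdas are drawn in breadth-first airway
    order from ``numpy.random.default_rng(seed)``.
    """
    if not (0.0 < C <= 1.0):
        raise DomainError(f"collapse fraction must lie in (0, 1], got {C}")
    if d < 0:
        raise DomainError(f"heterogeneity s.d. must be nonnegative, got {d}")
    fluid = fluid or FluidParams()
    rng = np.random.default_rng(seed)
    airways: list[Airway] = []
    for i in range(N_AIRWAYS):
        gen = generation_of_index(i)
        params = lambert_reference(gen)
        lam = sample_lambda(d, rng, lambda_floor)
        el = AirwayElastica(params, lam)
        state = ReopeningState.create(el, C, fluid)
        if i == 0:
            state.status = Status.READY
        children: tuple[int, int] | tuple[()] = (
            (2 * i + 1, 2 * i + 2) if gen < 16 else ()
        )
        airways.append(
            Airway(
                id=i,
                generation=gen,
                parent_id=None if i == 0 else (i - 1) // 2,
                child_ids=children,
                elastica=el,
                reopening=state,
                length=params.length,
            )
        )
    acini = [Acinus(parent_airway_id=i) for i in range(31, 63)]
    return Network(
        airways=airways,
        acini=acini,
        heterogeneity_d=d,
        collapse_C=C,
        seed=seed,
        lambda_floor=lambda_floor,
    )


def acinar_volume(P: float, ac: Acinus) -> float:
    """Acinar air volume (cm^3) at airway pressure ``P`` (dyn cm^-2).

    Zero at or below the acinar opening pressure; saturates at ``V_A``.
    """
    p_a = ac.P_A * CM_H2O
    if P <= p_a:
        return 0.0
    k = ac.K_A / CM_H2O
    return ac.V_A * (1.0 - np.exp(-k * (P - p_a)))


# ---------------------------------------------------------------------------
# Serialization: lossless JSON round trip (write -> read -> write identical).


def network_to_dict(net: Network) -> dict:
    return {
        "schema_version": NETWORK_SCHEMA_VERSION,
        "seed": net.seed,
        "heterogeneity_d": net.heterogeneity_d,
        "collapse_C": net.collapse_C,
        "lambda_floor": net.lambda_floor,
        "lambdas": [a.lam for a in net.airways],
        "acini": [
            {"parent_airway_id": ac.parent_airway_id, "V_A": ac.V_A,
             "K_A": ac.K_A, "P_A": ac.P_A}
            for ac in net.acini
        ],
    }


def save_network(net: Network, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(net), indent=1, sort_keys=True) + "\n"
    )


def network_from_dict(data: dict, fluid: FluidParams | None = None) -> Network:
    version = data.get("schema_version")
    if version != NETWORK_SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported network schema version {version!r}; "
            f"this package reads version {NETWORK_SCHEMA_VERSION!r}"
        )
    fluid = fluid or FluidParams()
    lambdas = data["lambdas"]
    if len(lambdas) != N_AIRWAYS:
        raise SchemaError(f"expected {N_AIRWAYS} lambdas, got {len(lambdas)}")
    C = data["collapse_C"]
    airways: list[Airway] = []
    for i, lam in enumerate(lambdas):
        gen = generation_of_index(i)
        params = lambert_reference(gen)
        el = AirwayElastica(params, lam)
        state = ReopeningState.create(el, C, fluid)
        if i == 0:
            state.status = Status.READY
        airways.append(
            Airway(
                id=i,
                generation=gen,
                parent_id=None if i == 0 else (i - 1) // 2,
                child_ids=(2 * i + 1, 2 * i + 2) if gen < 16 else (),
                elastica=el,
                reopening=state,
                length=params.length,
            )
        )
    acini = [
        Acinus(
            parent_airway_id=row["parent_airway_id"],
            V_A=row["V_A"],
            K_A=row["K_A"],
            P_A=row["P_A"],
        )
        for row in data["acini"]
    ]
    if len(acini) != N_ACINI:
        raise SchemaError(f"expected {N_ACINI} acini, got {len(acini)}")
    return Network(
        airways=airways,
        acini=acini,
        heterogeneity_d=data["heterogeneity_d"],
        collapse_C=C,
        seed=data["seed"],
        lambda_floor=data.get("lambda_floor", LAMBDA_FLOOR_DEFAULT),
    )


def load_network(path: str | Path, fluid: FluidParams | None = None) -> Network:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(
            f"cannot parse network file {path}: line {exc.lineno}, col {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    return network_from_dict(data, fluid)
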