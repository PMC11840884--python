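"""Dispersal energy budget: costs over distance and maximum dispersal distance.

The transfer phase is modelled as straight-line travel at the sustained
speed v, drawing power FMRdis. Over a distance D this takes t1 = D/v and
costs Ec = FMRdis·t1, leaving Er = E0 − Ec of the initial storage. A
residual fraction λ of E0 must survive the journey, so only
Eα = (1−λ)·E0 is spendable; depleting it bounds the distance at

    Dmax = v · Eα / FMRdis.

With a fraction β of the time budget spent resting (burning BMR, covering
no ground), depletion takes t3 = Eα / ((1−β)·FMRdis + β·BMR) and the
bound becomes Dmaxβ = (1−β)·v·t3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .allometry import basal_metabolic_rate, energy_storage, field_metabolic_rate, travel_speed
from .animals import AnimalProfile
from .params import DEFAULT_PARAMETERS, ModelParameters

__all__ = [
    "EnergyBudget",
    "DispersalOutcome",
    "MaxDispersalResult",
    "energy_budget",
    "energy_cost",
    "cost_per_metre",
    "relative_depletion",
    "max_dispersal_distance",
    "max_dispersal_distance_resting",
    "lambda_sweep",
    "DEFAULT_LAMBDA",
]

#: Default residual-energy fraction: 10% of storage must remain on arrival.
DEFAULT_LAMBDA = 0.1


@dataclass(frozen=True)
class EnergyBudget:
    """Energy storage split into a spendable and a reserved part.

    Attributes: ``e0`` total storage [J]; ``lam`` residual fraction λ;
    ``e_available`` = (1−λ)·E0 [J], the part spendable on dispersal.
    """

    e0: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam!r}")

    @property
    def e_available(self) -> float:
        return (1.0 - self.lam) * self.e0


@dataclass(frozen=True)
class DispersalOutcome:
    """Book-keeping of one dispersal bout of a fixed distance.

    ``feasible`` is False when the cost exceeds total storage
    (``energy_remaining`` < 0); the raw negative value is kept because the
    network layer clamps it itself.
    """

    distance: float        #: D [m]
    travel_time: float     #: t1 = D/v [s]
    energy_cost: float     #: Ec = FMRdis·t1 [J]
    energy_remaining: float  #: Er = E0 − Ec [J]

    @property
    def feasible(self) -> bool:
        return self.energy_remaining >= 0.0


@dataclass(frozen=True)
class MaxDispersalResult:
    """Physiological maximum dispersal distance and its components."""

    d_max: float            #: [m]
    depletion_time: float   #: t2 (β = 0) or t3 (β > 0) [s]
    speed: float            #: sustained travel speed v [m/s]
    e_available: float      #: Eα = (1−λ)·E0 [J]
    resting_fraction: float = 0.0  #: β

    @property
    def d_max_km(self) -> float:
        return self.d_max / 1000.0


def energy_budget(
    animal: AnimalProfile,
    lam: float = DEFAULT_LAMBDA,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> EnergyBudget:
    """Energy budget of ``animal`` with residual fraction ``lam``."""
    return EnergyBudget(energy_storage(animal, params), lam)


def energy_cost(
    animal: AnimalProfile,
    distance: float,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> DispersalOutcome:
    """Cost of travelling ``distance`` metres in a straight line.

    Linear in distance; never raises for distances beyond the maximum —
    the outcome simply reports negative remaining energy.
    """
    if distance < 0:
        raise ValueError(f"distance must be >= 0, got {distance!r}")
    v = travel_speed(animal, params)
    t1 = distance / v
    ec = field_metabolic_rate(animal, params) * t1
    return DispersalOutcome(
        distance=distance,
        travel_time=t1,
        energy_cost=ec,
        energy_remaining=energy_storage(animal, params) - ec,
    )


def cost_per_metre(
    animal: AnimalProfile, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Absolute cost of dispersal per metre travelled, FMRdis/v [J/m]."""
    return field_metabolic_rate(animal, params) / travel_speed(animal, params)


def relative_depletion(
    animal: AnimalProfile,
    distance: float,
    lam: float = DEFAULT_LAMBDA,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> float:
    """Fraction of the *available* energy Eα spent travelling ``distance``.

    Reaches exactly 1 at D = Dmax. Raises for λ = 1 (no spendable energy).
    """
    budget = energy_budget(animal, lam, params)
    if budget.e_available == 0.0:
        raise ValueError("lambda = 1 leaves no available energy; relative depletion undefined")
    return energy_cost(animal, distance, params).energy_cost / budget.e_available


def max_dispersal_distance(
    animal: AnimalProfile,
    lam: float = DEFAULT_LAMBDA,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> MaxDispersalResult:
    """Physiological maximum dispersal distance Dmax = v·(1−λ)·E0/FMRdis."""
    budget = energy_budget(animal, lam, params)
    v = travel_speed(animal, params)
    t2 = budget.e_available / field_metabolic_rate(animal, params)
    return MaxDispersalResult(d_max=v * t2, depletion_time=t2, speed=v,
                              e_available=budget.e_available)


def max_dispersal_distance_resting(
    animal: AnimalProfile,
    lam: float = DEFAULT_LAMBDA,
    beta: float = 0.0,
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> MaxDispersalResult:
    """Maximum distance when a fraction β of the time budget is spent resting.

    Dmaxβ = (1−β)·v·t3 with t3 = Eα / ((1−β)·FMRdis + β·BMR). Reduces
    exactly to :func:`max_dispersal_distance` at β = 0 and to 0 at β = 1;
    strictly decreasing in β (resting burns BMR without covering ground).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta!r}")
    budget = energy_budget(animal, lam, params)
    v = travel_speed(animal, params)
    denom = (1.0 - beta) * field_metabolic_rate(animal, params) + beta * basal_metabolic_rate(
        animal, params
    )
    t3 = budget.e_available / denom
    return MaxDispersalResult(
        d_max=(1.0 - beta) * v * t3,
        depletion_time=t3,
        speed=v,
        e_available=budget.e_available,
        resting_fraction=beta,
    )


def lambda_sweep(
    animal: AnimalProfile,
    lambda_grid: Iterable[float],
    params: ModelParameters = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Sensitivity of Dmax to the residual fraction λ over a grid.

    Returns a DataFrame with columns ``lambda``, ``d_max_m``, ``d_max_km``.
    Dmax(λ) = (1−λ)·Dmax(0): exactly linear in 1−λ.
    """
    grid = [float(g) for g in lambda_grid]
    if not grid:
        raise ValueError("lambda grid is empty")
    if any(not 0.0 <= g <= 1.0 for g in grid):
        raise ValueError("lambda grid values must lie in [0, 1]")
    rows = [(g, max_dispersal_distance(animal, g, params).d_max) for g in grid]
    return pd.DataFrame(
        {"lambda": [r[0] for r in rows],
         "d_max_m": [r[1] for r in rows],
         "d_max_km": [r[1] / 1000.0 for r in rows]}
    )
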