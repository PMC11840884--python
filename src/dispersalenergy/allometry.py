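"""Allometric building blocks: energy storage, BMR, travel speed, locomotion cost.

All quantities are power laws (or simple combinations of power laws) of body
mass M in kg, parameterized per taxonomic group / locomotion mode. At
M = 1 kg each pure power law evaluates exactly to its table coefficient.
"""

from __future__ import annotations

import math

from .animals import AnimalProfile
from .params import DEFAULT_PARAMETERS, ModelParameters

__all__ = [
    "energy_storage",
    "basal_metabolic_rate",
    "travel_speed",
    "locomotion_cost",
    "field_metabolic_rate",
]


def energy_storage(animal: AnimalProfile, params: ModelParameters = DEFAULT_PARAMETERS) -> float:
    """Total energy storage E0 [J]: the fat reserve fuelling dispersal.

    E0 = a·M^b with group-specific (a, b); strictly increasing in mass.
    """
    a, b = {
        "bird": (params.a1, params.b1),
        "mammal": (params.a2, params.b2),
        "fish": (params.a3, params.b3),
    }[animal.group]
    return a * animal.body_mass**b


def basal_metabolic_rate(animal: AnimalProfile, params: ModelParameters = DEFAULT_PARAMETERS) -> float:
    """Basal metabolic rate BMR [J/s]: maintenance power at rest."""
    a, b = {
        "bird": (params.a4, params.b4),
        "mammal": (params.a5, params.b5),
        "fish": (params.a6, params.b6),
    }[animal.group]
    return a * animal.body_mass**b


def travel_speed(animal: AnimalProfile, params: ModelParameters = DEFAULT_PARAMETERS) -> float:
    """Sustained travel speed v [m/s] during dispersal.

    v = v0·M^c / (1 + v0·k·M^(c+d))

    The numerator is the metabolic (power-law) speed capacity; the
    denominator caps it by the animal's heat-dissipation capacity, which
    erodes sustained speed in large animals. Speed is therefore hump-shaped
    over mass: rising ~M^c for small animals, declining ~M^−d for very
    large ones. The exact algebraic reading is configurable through
    ``params.parse`` (see :class:`dispersalenergy.params.ParseOptions`).
    """
    v0 = {"flying": params.v0_fly, "running": params.v0_run, "swimming": params.v0_swim}[
        animal.mode
    ]
    m = animal.body_mass
    delta = params.c + params.d if params.parse.speed_heat_exponent == "c+d" else params.d
    heat = params.k * m**delta
    if params.parse.speed_v0_in_heat:
        heat *= v0
    return v0 * m**params.c / (1.0 + heat)


def locomotion_cost(
    animal: AnimalProfile, v: float, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Locomotion cost LCOT [J/s]: power needed to move at speed v [m/s].

    Mode specific:

    * flying:   a7·M^b7·v^b8 + a8·M^b7·v^b9 + a9·M^b10·v^b9 — U-shaped in v
      (induced-power term ∝ 1/v plus parasite/profile terms ∝ v^2.5);
    * running:  a10·M^b11·v — linear in v;
    * swimming: a11·M^p·exp(a12·M^b12·v) — exponential in v, with M^b12·v a
      length-normalized speed (p = ``params.parse.swim_mass_exponent``).
    """
    if not v > 0:
        raise ValueError(f"speed must be > 0, got {v!r}")
    m = animal.body_mass
    if animal.mode == "flying":
        return (
            params.a7 * m**params.b7 * v**params.b8
            + params.a8 * m**params.b7 * v**params.b9
            + params.a9 * m**params.b10 * v**params.b9
        )
    if animal.mode == "running":
        return params.a10 * m**params.b11 * v
    # swimming
    p = params.parse.swim_mass_exponent
    return params.a11 * m**p * math.exp(params.a12 * m**params.b12 * v)


def field_metabolic_rate(
    animal: AnimalProfile, params: ModelParameters = DEFAULT_PARAMETERS
) -> float:
    """Field metabolic rate during dispersal FMRdis [J/s].

    FMRdis = postural·BMR + LCOT(v), with v the sustained travel speed.
    The postural multiplier (a13 flying, a14 running, 1 swimming) accounts
    for the extra maintenance cost of the locomotor posture; buoyancy spares
    swimmers that surcharge.
    """
    postural = {"flying": params.a13, "running": params.a14, "swimming": 1.0}[animal.mode]
    v = travel_speed(animal, params)
    return postural * basal_metabolic_rate(animal, params) + locomotion_cost(animal, v, params)
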