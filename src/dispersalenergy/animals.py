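"""Animal profiles: the trait key into every allometry of the model.

The model is parameterized for three (taxonomic group, locomotion mode)
pairings — flying birds, running mammals and swimming fishes. A profile
carries body mass in kilograms plus the pairing; everything else (energy
storage, metabolic rates, travel speed) is derived from it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AnimalProfile",
    "UnsupportedTaxonError",
    "GROUP_FOR_MODE",
    "MODE_FOR_GROUP",
]

#: The three parameterized pairings. Other combinations (swimming mammals,
#: running birds, ...) are rejected: no coefficients exist for them.
MODE_FOR_GROUP = {"bird": "flying", "mammal": "running", "fish": "swimming"}
GROUP_FOR_MODE = {v: k for k, v in MODE_FOR_GROUP.items()}

#: Masses outside this range (kg) trigger a warning: the underlying
#: allometries were fitted well inside it and anything beyond is a wild
#: extrapolation (though formally still defined).
_MASS_WARN_RANGE = (1e-6, 1e6)


class UnsupportedTaxonError(ValueError):
    """Raised for a (group, mode) pairing the model has no coefficients for."""


@dataclass(frozen=True)
class AnimalProfile:
    """A dispersing animal: body mass [kg], taxonomic group, locomotion mode.

    Either ``group`` or ``mode`` may be omitted; the other is inferred from
    the pairing (bird/flying, mammal/running, fish/swimming).

    Examples
    --------
    >>> AnimalProfile(4.5, group="mammal").mode
    'running'
    >>> AnimalProfile.mammal(4.5) == AnimalProfile(4.5, "mammal", "running")
    True
    """

    body_mass: float
    group: str = None  # type: ignore[assignment]
    mode: str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = float(self.body_mass)
        if not math.isfinite(m) or m <= 0.0:
            raise ValueError(f"body_mass must be positive and finite, got {self.body_mass!r}")
        object.__setattr__(self, "body_mass", m)

        group, mode = self.group, self.mode
        if group is None and mode is None:
            raise UnsupportedTaxonError("need at least one of group or mode")
        if group is None:
            group = GROUP_FOR_MODE.get(mode)
        if mode is None:
            mode = MODE_FOR_GROUP.get(group)
        if MODE_FOR_GROUP.get(group) != mode or mode is None:
            raise UnsupportedTaxonError(
                f"unparameterized pairing (group={self.group!r}, mode={self.mode!r}); "
                f"supported: bird/flying, mammal/running, fish/swimming"
            )
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "mode", mode)

        if not _MASS_WARN_RANGE[0] <= m <= _MASS_WARN_RANGE[1]:
            warnings.warn(
                f"body mass {m:g} kg lies outside [{_MASS_WARN_RANGE[0]:g}, "
                f"{_MASS_WARN_RANGE[1]:g}] kg; allometric predictions are an "
                "extreme extrapolation",
                stacklevel=3,
            )

    # convenience constructors ------------------------------------------------
    @classmethod
    def bird(cls, body_mass: float) -> "AnimalProfile":
        """A flying bird of ``body_mass`` kg."""
        return cls(body_mass, "bird", "flying")

    @classmethod
    def mammal(cls, body_mass: float) -> "AnimalProfile":
        """A running mammal of ``body_mass`` kg."""
        return cls(body_mass, "mammal", "running")

    @classmethod
    def fish(cls, body_mass: float) -> "AnimalProfile":
        """A swimming fish of ``body_mass`` kg."""
        return cls(body_mass, "fish", "swimming")
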