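"""Model parameterization: coefficients, exponents, and equation-parse options.

The defaults reproduce the published coefficient table for flying birds,
running mammals and swimming fishes (all SI: J, J/s, m/s, kg):

* energy storage          E0   = a·M^b         (a1–a3, b1–b3, per group)
* basal metabolic rate    BMR  = a·M^b         (a4–a6, b4–b6, per group)
* travel speed            v    = v0·M^c / (1 + v0·k·M^(c+d))   (v0 per mode)
* locomotion cost (power) LCOT — mode specific (a7–a12, b7–b12)
* field metabolic rate    FMRdis = postural·BMR + LCOT(v)      (a13, a14)

The speed and swimming-cost equations admit several algebraic readings in
secondary sources; :class:`ParseOptions` makes the reading explicit and
:func:`dispersalenergy.reference.resolve_parse` selects the default by
minimizing discrepancy against the published worked results.

Every number is overridable (for sensitivity analysis) via
:meth:`ModelParameters.replace`, and the whole set round-trips through a
flat ``name = value`` text file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from dataclasses import dataclass
from typing import Mapping, TextIO, Union

__all__ = ["ParseOptions", "ModelParameters", "DEFAULT_PARAMETERS", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Invalid parameter value or unresolvable parse configuration."""


@dataclass(frozen=True)
class ParseOptions:
    """Explicit algebraic reading of the ambiguous model equations.

    Parameters
    ----------
    speed_heat_exponent:
        Mass exponent of the heat-dissipation term in the travel-speed
        denominator: ``"c+d"`` (default) or ``"d"``.
    speed_v0_in_heat:
        Whether the mode-specific speed coefficient v0 multiplies the heat
        term, i.e. v = v0·M^c / (1 + v0·k·M^δ) (default) versus
        v = v0·M^c / (1 + k·M^δ).
    swim_mass_exponent:
        Exponent p of the mass prefactor in the swimming cost
        LCOT = a11·M^p·exp(a12·M^b12·v). Default 1: a mass-specific
        exponential cost scaled up by body mass, with M^b12·v a
        length-normalized swimming speed (b12 ≈ −1/3).
    """

    speed_heat_exponent: str = "c+d"
    speed_v0_in_heat: bool = True
    swim_mass_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_heat_exponent not in ("c+d", "d"):
            raise ConfigurationError(
                f"speed_heat_exponent must be 'c+d' or 'd', got {self.speed_heat_exponent!r}"
            )


#: Names of the numeric parameters, in canonical (config-file) order.
PARAMETER_NAMES = (
    # energy storage E0 = a·M^b  [J]
    "a1", "b1",      # birds
    "a2", "b2",      # mammals
    "a3", "b3",      # fish
    # basal metabolic rate BMR = a·M^b  [J/s]
    "a4", "b4",      # birds
    "a5", "b5",      # mammals
    "a6", "b6",      # fish
    # travel speed  [m/s]
    "v0_fly", "v0_run", "v0_swim", "c", "k", "d",
    # locomotion cost, flying: a7·M^b7·v^b8 + a8·M^b7·v^b9 + a9·M^b10·v^b9  [J/s]
    "a7", "a8", "a9", "b7", "b8", "b9", "b10",
    # locomotion cost, running: a10·M^b11·v  [J/s]
    "a10", "b11",
    # locomotion cost, swimming: a11·M^p·exp(a12·M^b12·v)  [J/s]
    "a11", "a12", "b12",
    # postural multipliers on BMR during dispersal
    "a13",           # flying
    "a14",           # running (swimming has none)
)

# Parameters that must be strictly positive (exponents may be any sign).
_POSITIVE = frozenset(
    n for n in PARAMETER_NAMES if n.startswith(("a", "v0", "k"))
)


@dataclass(frozen=True)
class ModelParameters:
    """Full coefficient/exponent set of the bioenergetic dispersal model.

    Field names follow the published parameter table; units are SI
    throughout (see module docstring). Instances are immutable; use
    :meth:`replace` for overrides.
    """

    # energy storage [J]
    a1: float = 2.5e6
    b1: float = 0.98
    a2: float = 2.00e6
    b2: float = 1.00
    a3: float = 4.78e6
    b3: float = 1.02
    # basal metabolic rate [J/s]
    a4: float = 3.63
    b4: float = 0.65
    a5: float = 2.89
    b5: float = 0.74
    a6: float = 0.29
    b6: float = 0.95
    # travel speed [m/s]
    v0_fly: float = 30.54
    v0_run: float = 0.28
    v0_swim: float = 0.39
    c: float = 0.27
    k: float = 0.03
    d: float = 0.24
    # locomotion cost, flying [J/s]
    a7: float = 32.00
    a8: float = 3.3e-3
    a9: float = 5.8e-3
    b7: float = 0.66
    b8: float = -1.00
    b9: float = 2.50
    b10: float = 0.49
    # locomotion cost, running [J/s]
    a10: float = 11.30
    b11: float = 0.72
    # locomotion cost, swimming [J/s]
    a11: float = 0.12
    a12: float = 1.88
    b12: float = -0.36
    # postural multipliers
    a13: float = 1.10
    a14: float = 1.20
    # algebraic reading of the ambiguous equations
    parse: ParseOptions = ParseOptions()

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"parameter {name} must be > 0, got {getattr(self, name)!r}")

    # --- overrides ---------------------------------------------------------
    def replace(self, **overrides: Union[float, ParseOptions]) -> "ModelParameters":
        """Return a copy with the given parameters overridden."""
        return dataclasses.replace(self, **overrides)

    # --- flat config round trip -------------------------------------------
    def to_config(self, stream: Union[str, TextIO, None] = None) -> str:
        """Serialize to flat ``name = value`` text (one parameter per line).

        ``stream`` may be a path or writable file object; the text is
        returned either way. Parse options are not part of the numeric
        config; they are code-level choices.
        """
        lines = [f"{n} = {getattr(self, n)!r}" for n in PARAMETER_NAMES]
        text = "\n".join(lines) + "\n"
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        elif stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_config(cls, source: Union[str, TextIO, Mapping[str, float]]) -> "ModelParameters":
        """Load from flat config text, a path, a file object, or a mapping.

        Lines are ``name = value``; blank lines and ``#`` comments ignored.
        Unknown names are rejected; absent names keep their defaults.
        """
        if isinstance(source, Mapping):
            values = dict(source)
        else:
            if isinstance(source, str):
                text = open(source).read() if "\n" not in source and "=" not in source else source
            else:
                text = source.read()
            values = {}
            for lineno, raw in enumerate(io.StringIO(text), start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"line {lineno}: expected 'name = value', got {raw!r}")
                name, _, val = line.partition("=")
                values[name.strip()] = float(val)
        unknown = set(values) - set(PARAMETER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**values)

    def digest(self) -> str:
        """Short stable hash of the numeric parameter set (for run logs)."""
        return hashlib.sha256(self.to_config().encode()).hexdigest()[:12]


#: The shipped default parameterization (published table values, resolved parse).
DEFAULT_PARAMETERS = ModelParameters()
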