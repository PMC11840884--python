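"""Run configuration: parameter overrides, λ, β, seed, units, output paths.

A :class:`RunConfig` captures everything that varies between runs of the
command-line tool (and of scripted analyses) and round-trips losslessly
through the same flat ``name = value`` text format used for parameters;
run-level settings are namespaced with a ``run.`` prefix so the two can
share a file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Dict, TextIO, Union

from .energetics import DEFAULT_LAMBDA
from .params import DEFAULT_PARAMETERS, PARAMETER_NAMES, ConfigurationError, ModelParameters

__all__ = ["RunConfig"]

_RUN_FIELDS = ("lam", "beta", "seed", "rel_tol")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one reproducible run.

    ``overrides`` maps parameter names (a1…a14, b1…b12, c, d, k, v0_*) to
    replacement values; unlisted parameters keep their defaults.
    ``distance_unit`` controls CLI reporting ("m" or "km"; computations are
    always SI internally).
    """

    overrides: Dict[str, float] = field(default_factory=dict)
    lam: float = DEFAULT_LAMBDA
    beta: float = 0.0
    seed: int = 0
    rel_tol: float = 1e-2
    distance_unit: str = "km"
    out_dir: str = "."

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(PARAMETER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter override(s): {sorted(unknown)}")
        if self.distance_unit not in ("m", "km"):
            raise ConfigurationError(f"distance_unit must be 'm' or 'km', got {self.distance_unit!r}")

    def parameters(self) -> ModelParameters:
        """Model parameters with this config's overrides applied."""
        return DEFAULT_PARAMETERS.replace(**self.overrides)

    def with_overrides(self, **overrides: float) -> "RunConfig":
        return replace(self, overrides={**self.overrides, **overrides})

    # --- flat-file round trip ----------------------------------------------
    def to_config(self, stream: Union[str, TextIO, None] = None) -> str:
        lines = [f"run.{name} = {getattr(self, name)!r}" for name in _RUN_FIELDS]
        lines.append(f"run.distance_unit = {self.distance_unit}")
        lines.append(f"run.out_dir = {self.out_dir}")
        lines += [f"{k} = {v!r}" for k, v in sorted(self.overrides.items())]
        text = "\n".join(lines) + "\n"
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        elif stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_config(cls, source: Union[str, TextIO]) -> "RunConfig":
        if isinstance(source, str):
            text = open(source).read() if "\n" not in source and "=" not in source else source
        else:
            text = source.read()
        kwargs: Dict[str, object] = {}
        overrides: Dict[str, float] = {}
        for lineno, raw in enumerate(io.StringIO(text), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected 'name = value', got {raw!r}")
            name, _, val = line.partition("=")
            name, val = name.strip(), val.strip()
            if name.startswith("run."):
                key = name[4:]
                if key in ("distance_unit", "out_dir"):
                    kwargs[key] = val.strip("'\"")
                elif key == "seed":
                    kwargs[key] = int(val)
                elif key in _RUN_FIELDS:
                    kwargs[key] = float(val)
                else:
                    raise ConfigurationError(f"unknown run setting {name!r}")
            else:
                overrides[name] = float(val)
        return cls(overrides=overrides, **kwargs)  # type: ignore[arg-type]
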