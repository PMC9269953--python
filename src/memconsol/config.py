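"""Run configuration: flat key=value files plus command-line overrides.

A config file holds one ``key = value`` pair per line (``#`` comments).
Parameter overrides accept absolute values (``k_basalp_creb = 4.8e-6``) or
relative scalings (``k_basalp_creb = x1.5``), matching how the protocols are
phrased ("at 150% of the standard value").  Variant flags are booleans
(``block_cebp_loop = true``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model import ModelVariant
from .params import ParameterSet

__all__ = ["RunConfig", "load_config", "parse_override"]

_FLAG_NAMES = ("block_camkii_loop", "block_cebp_loop", "block_w_loop",
               "no_mecp2_effects")
_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


@dataclass
class RunConfig:
    """Validated run description: parameter overrides + variant + protocol."""

    overrides: dict[str, float] = field(default_factory=dict)   # absolute
    scalings: dict[str, float] = field(default_factory=dict)    # x-factors
    variant: ModelVariant = ModelVariant()
    protocol_args: dict[str, str] = field(default_factory=dict)

    def parameters(self) -> ParameterSet:
        base = ParameterSet().replace(**self.overrides)
        return base.scaled(**self.scalings) if self.scalings else base


def parse_override(key: str, raw: str) -> tuple[str, float, bool]:
    """Parse one override value; returns (name, value, is_relative)."""
    if key not in ParameterSet.names():
        raise KeyError(f"unknown parameter {key!r}")
    raw = raw.strip()
    relative = raw[:1] in ("x", "X")
    try:
        value = float(raw[1:] if relative else raw)
    except ValueError:
        raise ValueError(f"non-numeric value {raw!r} for parameter {key!r}") from None
    if relative and value <= 0:
        raise ValueError(f"relative scaling for {key!r} must be > 0, got {value}")
    return key, value, relative


def _parse_bool(key: str, raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"expected a boolean for {key!r}, got {raw!r}")


def load_config(path: str | Path | None = None,
                pairs: dict[str, str] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a key=value file and/or explicit pairs.

    ``pairs`` (e.g. from CLI ``--set`` flags) override file values.  Unknown
    keys, non-numeric values, and duplicate keys within the file are hard
    errors.
    """
    entries: dict[str, str] = {}
    if path is not None:
        text = Path(path).read_text()
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key in entries:
                raise ValueError(f"{path}:{ln}: duplicate key {key!r}")
            entries[key] = raw
    if pairs:
        entries.update(pairs)

    cfg = RunConfig()
    flags: dict[str, bool] = {}
    for key, raw in entries.items():
        if key in _FLAG_NAMES:
            flags[key] = _parse_bool(key, raw)
        elif key in ParameterSet.names():
            name, value, relative = parse_override(key, raw)
            (cfg.scalings if relative else cfg.overrides)[name] = value
        elif key.startswith("protocol."):
            cfg.protocol_args[key[len("protocol."):]] = raw
        else:
            raise KeyError(f"unknown config key {key!r}")
    cfg.variant = ModelVariant(**flags)
    cfg.parameters()  # validate now, not at use time
    return cfg
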