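"""Result serialization: CSV tables plus a JSON reproducibility manifest.

Trajectories are written as CSV with a ``time_s`` column followed by the 17
state names in canonical order; resistance curves as (onset_h,
reduction_day2_pct, reduction_day7_pct); scan grids long-form.  Every result
file is accompanied by a manifest holding the fully resolved parameter set,
variant flags, protocol description, integration step, and package version —
enough to reproduce the file bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .integrator import Trajectory
from .model import ModelVariant
from .params import ParameterSet
from .protocols import ResistanceCurve, ScanGrid

__all__ = ["write_results", "write_manifest"]

# full double precision so CSV -> load -> rerun round-trips exactly
_FLOAT_FMT = "%.17e"


def write_manifest(out_dir: Path, name: str, params: ParameterSet,
                   variant: ModelVariant, protocol: str,
                   extra: dict | None = None, step: float = 3.0) -> Path:
    from . import __version__

    manifest = {
        "result": name,
        "protocol": protocol,
        "parameters": params.as_dict(),
        "variant": dataclasses.asdict(variant),
        "integration_step_s": step,
        "package": "memconsol",
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"{name}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_results(result, out_dir: str | Path, name: str,
                  params: ParameterSet, variant: ModelVariant = ModelVariant(),
                  protocol: str = "", extra: dict | None = None) -> list[Path]:
    """Write a Trajectory / ResistanceCurve / ScanGrid plus its manifest.

    Returns the written paths (data file first).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"

    if isinstance(result, Trajectory):
        frame = result.to_frame().reset_index()
        step = result.step
    elif isinstance(result, ResistanceCurve):
        frame = result.to_frame()
        step = 3.0
    elif isinstance(result, ScanGrid):
        frame = result.to_frame()
        step = 3.0
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")

    frame.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    man_path = write_manifest(out_dir, name, params, variant, protocol,
                              extra=extra, step=step)
    return [csv_path, man_path]
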