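"""Run configuration, validation and output writing.

A run config is a YAML (or JSON) mapping with exactly one active command
section — ``scenario``, ``sweep`` or ``sensitivity`` — plus optional
``output`` settings. Parameter values outside the documented simulation
ranges are allowed only when ``allow_extrapolation`` is set, and unknown
keys are rejected so typos fail loudly. Every output file is accompanied
by a run-manifest JSON recording the parameters, seed and package version
that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .biomass import ScenarioParams
from .engine import PRESETS, TABLE1_LEVELS
from .sensitivity import MC_LEVELS, SensitivitySpec

__all__ = ["RunConfig", "load_config", "parse_config", "write_outputs", "write_field_csv"]

#: Documented simulation ranges; values outside these are flagged as
#: extrapolation unless explicitly allowed.
_RANGES = {
    "d_h": (min(TABLE1_LEVELS["d_h"]), max(TABLE1_LEVELS["d_h"])),
    "q": (min(TABLE1_LEVELS["q"]), max(TABLE1_LEVELS["q"])),
    "d_50": (min(MC_LEVELS["d_50"]), max(TABLE1_LEVELS["d_50"]) * 2),
    "p": (min(TABLE1_LEVELS["p"]), max(TABLE1_LEVELS["p"])),
}

_SCENARIO_KEYS = {
    "d_h", "q", "d_50", "d_99", "d_r_step", "s_r", "p", "group", "q_nr",
    "overlap_rule", "n_side", "cell_size",
}
_SWEEP_KEYS = {"preset", "axis1", "axis2", "base"}
_SENS_KEYS = {"group", "n_iterations", "strata_steps", "levels", "seed", "catch_model", "q_nr"}
_TOP_KEYS = {"scenario", "sweep", "sensitivity", "catch_model", "threshold_level",
             "seed", "output", "allow_extrapolation"}


class ConfigError(ValueError):
    """Configuration file is missing, malformed or out of range."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with exactly one active command."""

    command: str
    scenario: ScenarioParams | None = None
    sweep: dict | None = None
    sensitivity: SensitivitySpec | None = None
    catch_model: str = "linear"
    threshold_level: float = 0.70
    seed: int = 0
    output_dir: Path = Path(".")
    allow_extrapolation: bool = False

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "catch_model": self.catch_model,
            "threshold_level": self.threshold_level,
            "seed": self.seed,
            "output": {"dir": str(self.output_dir)},
            "allow_extrapolation": self.allow_extrapolation,
        }
        if self.command == "scenario":
            out["scenario"] = dataclasses.asdict(self.scenario)
        elif self.command == "sweep":
            out["sweep"] = self.sweep
        elif self.command == "sensitivity":
            d = dataclasses.asdict(self.sensitivity)
            d["levels"] = {k: list(v) for k, v in d["levels"].items()}
            d["strata_steps"] = list(d["strata_steps"])
            out["sensitivity"] = d
        return out


def _reject_unknown(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _check_ranges(params: Mapping, allow_extrapolation: bool) -> None:
    for name, (lo, hi) in _RANGES.items():
        if name in params and params[name] is not None:
            v = params[name]
            if not lo <= v <= hi and not allow_extrapolation:
                raise ConfigError(
                    f"parameter {name}={v} outside documented range [{lo}, {hi}]; "
                    "set allow_extrapolation: true to override"
                )


def parse_config(obj: Mapping) -> RunConfig:
    """Validate a raw config mapping into a :class:`RunConfig`."""
    if not isinstance(obj, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(obj).__name__}")
    _reject_unknown(obj, _TOP_KEYS, "config root")
    commands = [k for k in ("scenario", "sweep", "sensitivity") if k in obj]
    if len(commands) != 1:
        raise ConfigError(
            f"exactly one of scenario/sweep/sensitivity must be present, found {commands}"
        )
    command = commands[0]
    allow_x = bool(obj.get("allow_extrapolation", False))
    catch_model = obj.get("catch_model", "linear")
    if catch_model not in ("linear", "threshold"):
        raise ConfigError(f"catch_model must be 'linear' or 'threshold', got {catch_model!r}")

    kwargs: dict[str, Any] = dict(
        command=command,
        catch_model=catch_model,
        threshold_level=float(obj.get("threshold_level", 0.70)),
        seed=int(obj.get("seed", 0)),
        output_dir=Path(obj.get("output", {}).get("dir", ".")),
        allow_extrapolation=allow_x,
    )

    try:
        if command == "scenario":
            sec = obj["scenario"] or {}
            _reject_unknown(sec, _SCENARIO_KEYS, "scenario")
            _check_ranges(sec, allow_x)
            kwargs["scenario"] = ScenarioParams(**sec)
        elif command == "sweep":
            sec = obj["sweep"] or {}
            _reject_unknown(sec, _SWEEP_KEYS, "sweep")
            if "preset" in sec:
                if sec["preset"] not in PRESETS:
                    raise ConfigError(
                        f"unknown preset {sec['preset']!r}; available: {sorted(PRESETS)}"
                    )
            elif "axis1" not in sec or "base" not in sec:
                raise ConfigError("sweep needs either a preset or base + axis1")
            base = sec.get("base", {})
            _reject_unknown(base, _SCENARIO_KEYS, "sweep.base")
            _check_ranges(base, allow_x)
            kwargs["sweep"] = dict(sec)
        else:
            sec = obj["sensitivity"] or {}
            _reject_unknown(sec, _SENS_KEYS, "sensitivity")
            sec = dict(sec)
            if "levels" in sec:
                sec["levels"] = {k: tuple(v) for k, v in sec["levels"].items()}
            if "strata_steps" in sec:
                sec["strata_steps"] = tuple(sec["strata_steps"])
            sec.setdefault("seed", kwargs["seed"])
            kwargs["sensitivity"] = SensitivitySpec(**sec)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {command} section: {exc}") from exc
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    return parse_config(obj or {})


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    config: RunConfig | Mapping,
    out_dir: str | Path,
    stem: str = "run",
) -> list[Path]:
    """Write result tables as CSV plus a run-manifest JSON, atomically.

    Returns the list of files written. The manifest records the full
    configuration, package version and a UTC timestamp, so any output is
    reproducible from its manifest alone.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in tables.items():
        path = out_dir / f"{stem}_{name}.csv"
        _atomic_write(path, df.to_csv(index=False))
        written.append(path)
    manifest = {
        "config": config.to_dict() if isinstance(config, RunConfig) else dict(config),
        "outputs": [p.name for p in written],
        "reefsim_version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    mpath = out_dir / f"{stem}_manifest.json"
    _atomic_write(mpath, json.dumps(manifest, indent=2, default=str))
    written.append(mpath)
    return written


def write_field_csv(
    field, grid, path: str | Path, fmt: str = "matrix"
) -> Path:
    """Export a biomass/distance field as CSV.

    ``fmt="matrix"``: dense row-major matrix with a metadata header comment.
    ``fmt="long"``: one row per cell with row, col, x_m, y_m, value.
    """
    import numpy as np

    path = Path(path)
    field = np.asarray(field)
    if fmt == "matrix":
        header = f"# n_side={grid.n_side} cell_size={grid.cell_size}\n"
        body = "\n".join(",".join(f"{v:.12g}" for v in row) for row in field)
        _atomic_write(path, header + body + "\n")
    elif fmt == "long":
        rows, cols = np.indices(field.shape)
        df = pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "x_m": cols.ravel() * grid.cell_size,
                "y_m": rows.ravel() * grid.cell_size,
                "value": field.ravel(),
            }
        )
        _atomic_write(path, df.to_csv(index=False))
    else:
        raise ValueError(f"fmt must be 'matrix' or 'long', got {fmt!r}")
    return path
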