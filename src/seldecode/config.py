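"""YAML configuration: designs, decoder settings, pipeline wiring.

Configs are deliberately flat and strict: unknown keys are rejected (typos
in a tolerance name must not silently fall back to a default) and *all*
schema violations are collected before raising, so one validation pass
reports every problem.  A config-free invocation reproduces the published
decoder defaults (5 ppm MS1/MS2, 1 of 5 matching peaks, 1 hydrogen shift,
10 s / 3-fold background subtraction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .annotate import CometConfig
from .formula import ElementalFormula, FormulaError
from .library import (
    BuildingBlock,
    LibraryConfigError,
    ScaffoldDesign,
    read_bb_table,
)
from .simulate import SimulationConfig

__all__ = [
    "ConfigError",
    "load_design",
    "comet_config_from_dict",
    "PipelineConfig",
    "validate_config",
]


class ConfigError(ValueError):
    """One or more configuration problems; ``errors`` lists them all."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _check_unknown(d: dict, allowed: set[str], where: str, errors: list[str]):
    for key in d:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r}")


def load_design(
    path: str | Path,
) -> tuple[ScaffoldDesign, list[list[BuildingBlock]]]:
    """Load a design YAML and its referenced building-block CSVs.

    Schema::

        design_id: SEL1-like
        positions: [bb1.csv, bb2.csv, bb3.csv]   # one BB table per position
        scaffold_offset_formula: NH3             # may be empty
        fragment_types: "S[0;1], S[1;2],0,2"
        adduct: "[M+H]+"

    A BB CSV may hold several positions; each ``positions`` entry selects
    the rows of its own position index from its file.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: design config must be a mapping"])
    _check_unknown(
        raw,
        {"design_id", "positions", "scaffold_offset_formula", "fragment_types",
         "adduct"},
        str(path),
        errors,
    )
    positions = raw.get("positions")
    if not isinstance(positions, list) or not positions:
        errors.append(f"{path}: 'positions' must be a non-empty list of BB CSVs")
        raise ConfigError(errors)
    offset_text = raw.get("scaffold_offset_formula") or ""
    try:
        offset = ElementalFormula.parse(str(offset_text))
    except FormulaError as exc:
        errors.append(f"{path}: scaffold_offset_formula: {exc}")
        raise ConfigError(errors)
    design = ScaffoldDesign(
        design_id=str(raw.get("design_id", path.stem)),
        n_positions=len(positions),
        scaffold_offset=offset,
        fragment_types=str(raw.get("fragment_types", "")),
        adduct=str(raw.get("adduct", "[M+H]+")),
    )
    bb_sets: list[list[BuildingBlock]] = []
    for p, ref in enumerate(positions):
        bb_path = (path.parent / ref).resolve() if not Path(ref).is_absolute() \
            else Path(ref)
        if not bb_path.exists():
            errors.append(f"{path}: BB table {ref!r} does not exist")
            continue
        try:
            table = read_bb_table(bb_path)
        except LibraryConfigError as exc:
            errors.append(str(exc))
            continue
        if p not in table:
            errors.append(
                f"{bb_path}: no building blocks for position {p}"
            )
            continue
        bb_sets.append(table[p])
    if errors:
        raise ConfigError(errors)
    return design, bb_sets


_COMET_KEYS = {f.name for f in dataclasses.fields(CometConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def comet_config_from_dict(d: dict | None, where: str = "comet") -> CometConfig:
    """Build a :class:`CometConfig` from a mapping, filling defaults."""
    d = d or {}
    errors: list[str] = []
    _check_unknown(d, _COMET_KEYS, where, errors)
    if errors:
        raise ConfigError(errors)
    try:
        return CometConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError([f"{where}: {exc}"]) from exc


def _sim_config_from_dict(d: dict | None, where: str) -> SimulationConfig:
    d = dict(d or {})
    errors: list[str] = []
    _check_unknown(d, _SIM_KEYS, where, errors)
    if errors:
        raise ConfigError(errors)
    if "background_ratio_range" in d:
        d["background_ratio_range"] = tuple(d["background_ratio_range"])
    if "emission_probabilities" in d and d["emission_probabilities"] is not None:
        d["emission_probabilities"] = {
            str(k): float(v) for k, v in d["emission_probabilities"].items()
        }
    try:
        return SimulationConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError([f"{where}: {exc}"]) from exc


@dataclass
class PipelineConfig:
    """Everything one end-to-end pipeline invocation needs."""

    design_path: Path
    output_dir: Path
    sample_paths: list[Path] = field(default_factory=list)
    control_paths: list[Path] = field(default_factory=list)
    comet: CometConfig = field(default_factory=CometConfig)
    simulation: SimulationConfig | None = None
    merge_mode: str = "union"
    alpha: float = 0.05
    seed: int = 0

    def normalized(self) -> dict:
        """Round-trippable plain-dict form (normalize is idempotent)."""
        d: dict[str, Any] = {
            "design": str(self.design_path),
            "output_dir": str(self.output_dir),
            "samples": [str(p) for p in self.sample_paths],
            "controls": [str(p) for p in self.control_paths],
            "comet": dataclasses.asdict(self.comet),
            "merge_mode": self.merge_mode,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["background_ratio_range"] = list(
                self.simulation.background_ratio_range
            )
            d["simulation"] = sim
        return d


_PIPELINE_KEYS = {
    "design", "output_dir", "samples", "controls", "comet", "simulation",
    "merge_mode", "alpha", "seed",
}


def validate_config(path: str | Path) -> PipelineConfig:
    """Load + validate a pipeline YAML; every violation is reported at once.

    Referenced files must exist at validation time (except outputs).  The
    returned config has all defaults filled; ``normalized()`` of a config
    built from its own ``normalized()`` dict is identical.
    """
    path = Path(path)
    errors: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file {path} does not exist"])
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raise ConfigError([f"{path}: empty config"])
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: config must be a mapping"])
    _check_unknown(raw, _PIPELINE_KEYS, str(path), errors)

    design = raw.get("design")
    if not design:
        errors.append(f"{path}: 'design' is required")
        design_path = Path("missing")
    else:
        design_path = (path.parent / design) if not Path(design).is_absolute() \
            else Path(design)
        if not design_path.exists():
            errors.append(f"{path}: design file {design!r} does not exist")

    def resolve_list(key: str) -> list[Path]:
        out = []
        for ref in raw.get(key) or []:
            p = (path.parent / ref) if not Path(ref).is_absolute() else Path(ref)
            if not p.exists():
                errors.append(f"{path}: {key} file {ref!r} does not exist")
            out.append(p)
        return out

    samples = resolve_list("samples")
    controls = resolve_list("controls")

    comet = CometConfig()
    try:
        comet = comet_config_from_dict(raw.get("comet"), f"{path}:comet")
    except ConfigError as exc:
        errors.extend(exc.errors)

    simulation = None
    if raw.get("simulation") is not None:
        try:
            simulation = _sim_config_from_dict(
                raw["simulation"], f"{path}:simulation"
            )
        except ConfigError as exc:
            errors.extend(exc.errors)

    merge_mode = str(raw.get("merge_mode", "union"))
    if merge_mode not in ("union", "intersection"):
        errors.append(f"{path}: merge_mode must be 'union' or 'intersection'")
    try:
        alpha = float(raw.get("alpha", 0.05))
        if not 0 < alpha < 1:
            errors.append(f"{path}: alpha must be in (0, 1)")
    except (TypeError, ValueError):
        errors.append(f"{path}: alpha must be a number")
        alpha = 0.05

    if not samples and simulation is None:
        errors.append(
            f"{path}: provide 'samples' (mzML) or a 'simulation' section"
        )

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        design_path=design_path,
        output_dir=(path.parent / raw.get("output_dir", "out")).resolve()
        if not Path(str(raw.get("output_dir", "out"))).is_absolute()
        else Path(raw["output_dir"]),
        sample_paths=samples,
        control_paths=controls,
        comet=comet,
        simulation=simulation,
        merge_mode=merge_mode,
        alpha=alpha,
        seed=int(raw.get("seed", 0)),
    )
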