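"""Structured run configuration (YAML) shared by the CLI and pipeline.

One file describes all stages; per-stage blocks mirror the module
parameters (``pack``, ``dynamics``, ``piston``, ``detect``, ``screen``,
``refine``) with a global ``seed`` and ``output_dir``.  Parameter bounds
are enforced at load time by the underlying dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import IntegratorConfig
from .packing import PackSpec
from .piston import PistonSchedule
from .system import AtomicSystem, read_xyz


class ConfigError(ValueError):
    """Invalid or missing configuration."""


@dataclass
class DetectConfig:
    persistence_frames: int = 25
    form_factor: float = 1.3
    break_factor: float = 1.3

    def __post_init__(self) -> None:
        if self.persistence_frames < 1:
            raise ConfigError("persistence_frames must be >= 1")
        if not (1.0 <= self.form_factor <= self.break_factor):
            raise ConfigError("require 1.0 <= form_factor <= break_factor")


@dataclass
class RefineConfig:
    n_images: int = 11
    spring_k: float = 1.0
    grad_tol: float = 1e-5
    neb_tol: float = 1e-3
    max_step: float = 0.015
    neb_max_iter: int = 5000


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    pack: PackSpec
    integrator: IntegratorConfig
    piston: PistonSchedule
    detect: DetectConfig = field(default_factory=DetectConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    provider: str = "morse"       # "morse" | "leps"
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provider not in ("morse", "leps"):
            raise ConfigError(f"unknown provider {self.provider!r}")


def _template_from_entry(entry: dict, base_dir: Path) -> tuple[AtomicSystem, int]:
    count = int(entry.get("count", 1))
    if "xyz" in entry:
        path = base_dir / entry["xyz"]
        if not path.exists():
            raise ConfigError(f"template file does not exist: {path}")
        traj = read_xyz(path)
        return traj.system_at(0, label=str(entry["xyz"])), count
    try:
        elements = entry["elements"]
        positions = np.asarray(entry["positions"], dtype=float)
    except KeyError as exc:
        raise ConfigError(f"template entry needs 'elements'/'positions' or 'xyz': {exc}")
    return AtomicSystem.from_elements(elements, positions,
                                      label=entry.get("label", "")), count


def load_config_dict(data: dict, base_dir: Path = Path(".")) -> RunConfig:
    try:
        seed = int(data.get("seed", 0))
        pack_d = data["pack"]
        dyn_d = data["dynamics"]
        pist_d = data["piston"]
    except KeyError as exc:
        raise ConfigError(f"missing config block: {exc}")
    templates = [_template_from_entry(e, base_dir) for e in pack_d["templates"]]
    try:
        pack = PackSpec(templates=templates,
                        sphere_radius=float(pack_d["sphere_radius"]),
                        min_separation=float(pack_d.get("min_separation", 2.0)),
                        seed=seed)
        integ = IntegratorConfig(
            n_steps=int(dyn_d["n_steps"]),
            dt=float(dyn_d.get("dt", 0.5)),
            thermostat=dyn_d.get("thermostat", "langevin"),
            temperature=float(dyn_d.get("temperature", 1000.0)),
            damping_time=float(dyn_d.get("damping_time", 300.0)),
            seed=seed,
            snapshot_stride=int(dyn_d.get("snapshot_stride", 1)),
        )
        schedule = PistonSchedule(
            R1=float(pist_d["r1"]), R2=float(pist_d["r2"]),
            t1=float(pist_d["t1"]), t2=float(pist_d["t2"]),
            k1=float(pist_d["k1"]), k2=float(pist_d["k2"]),
            center=np.asarray(pist_d.get("center", [0.0, 0.0, 0.0]), dtype=float),
        )
        det = DetectConfig(**data.get("detect", {}))
        ref = RefineConfig(**data.get("refine", {}))
    except (ValueError, TypeError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(seed=seed,
                     output_dir=Path(data.get("output_dir", "nanoreactor_out")),
                     pack=pack, integrator=integ, piston=schedule,
                     detect=det, refine=ref,
                     provider=dyn_d.get("provider", "morse"),
                     raw=data)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file does not exist: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return load_config_dict(data, base_dir=path.parent)


def toy_exchange_config(seed: int = 7) -> RunConfig:
    """The bundled A + BC exchange study: one C–N molecule plus a free H
    atom and helium in a contracting sphere, on the LEPS toy surface."""
    text = resources.files("nanoreactor.data").joinpath("toy_abc.yaml").read_text()
    data = yaml.safe_load(text)
    data["seed"] = seed
    return load_config_dict(data)
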