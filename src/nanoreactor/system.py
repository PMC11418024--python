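"""Molecular state, kinetic quantities, and (extended-)XYZ trajectory I/O.

All quantities are carried in the internal unit system: amu, Å, fs
(energies amu·Å²·fs⁻²).  The XYZ dialect is: atom-count line, comment line
holding optional whitespace-separated ``key=value`` metadata, then one
``element x y z [vx vy vz]`` line per atom; multi-frame files concatenate
blocks.  Recognized comment keys are ``time`` (fs), ``energy`` (kJ/mol),
``boundary_radius`` (Å) and ``boundary_k`` (fs⁻²); unknown ``key=value``
pairs are preserved verbatim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import units


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


def _load_json_data(name: str) -> dict:
    text = resources.files("nanoreactor.data").joinpath(name).read_text()
    data = json.loads(text)
    data.pop("_comment", None)
    return data


#: isotope-averaged atomic masses, amu
ATOMIC_MASSES: dict[str, float] = _load_json_data("atomic_masses.json")


def normalize_element(symbol: str) -> str:
    """Normalize an element symbol to standard capitalization (``he`` → ``He``)."""
    return symbol.strip().capitalize()


def mass_of(symbol: str) -> float:
    sym = normalize_element(symbol)
    try:
        return ATOMIC_MASSES[sym]
    except KeyError:
        raise KeyError(f"unknown element symbol {symbol!r}") from None


@dataclass
class AtomicSystem:
    """A point-mass molecular system: elements, masses, positions, velocities.

    Parameters
    ----------
    elements : sequence of str
        Element symbols, standard capitalization.
    masses : array, shape (n,)
        Per-atom masses in amu, strictly positive.
    positions : array, shape (n, 3)
        Cartesian coordinates in Å.
    velocities : array, shape (n, 3), optional
        Cartesian velocities in Å/fs.  ``None`` means "no velocities";
        a zero array is a valid (cold) velocity state.
    """

    elements: tuple[str, ...]
    masses: np.ndarray
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.elements = tuple(normalize_element(e) for e in self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(len(self.elements), -1)
        n = len(self.elements)
        if n < 1:
            raise ValueError("AtomicSystem requires at least one atom")
        if self.masses.shape != (n,):
            raise ValueError(f"masses shape {self.masses.shape} != ({n},)")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.positions.shape[0] != n or not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite with one row per atom")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")

    @classmethod
    def from_elements(
        cls,
        elements: Sequence[str],
        positions,
        velocities=None,
        label: str = "",
    ) -> "AtomicSystem":
        """Build a system looking masses up in the bundled isotope-averaged table."""
        elements = tuple(normalize_element(e) for e in elements)
        masses = np.array([mass_of(e) for e in elements])
        return cls(elements, masses, np.asarray(positions, dtype=float), velocities, label)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            self.elements,
            self.masses.copy(),
            self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
            self.label,
        )


@dataclass
class Frame:
    """One trajectory snapshot (times in fs, coordinates in Å, energy kJ/mol)."""

    time: float
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    potential_energy: Optional[float] = None
    boundary_radius: Optional[float] = None
    boundary_k: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("frame time must be >= 0")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)


@dataclass
class Trajectory:
    elements: tuple[str, ...]
    masses: np.ndarray
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.elements = tuple(normalize_element(e) for e in self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        for k, f in enumerate(self.frames):
            if f.positions.shape != (len(self.elements), 3):
                raise ValueError(f"frame {k}: positions shape mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def system_at(self, index: int, label: str = "") -> AtomicSystem:
        f = self.frames[index]
        return AtomicSystem(self.elements, self.masses, f.positions.copy(),
                            None if f.velocities is None else f.velocities.copy(), label)


_KNOWN_KEYS = ("time", "energy", "boundary_radius", "boundary_k")


def _parse_comment(comment: str) -> dict:
    out: dict = {"extra": {}}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, val = token.partition("=")
        if key in _KNOWN_KEYS:
            try:
                out[key] = float(val)
            except ValueError:
                raise XYZParseError(f"non-numeric value for key {key!r}: {val!r}")
        else:
            out["extra"][key] = val
    return out


def read_xyz(path) -> Trajectory:
    """Read a (multi-frame, extended) XYZ file into a :class:`Trajectory`.

    Frames lacking a ``time`` key are assigned their frame index (in fs) so
    that plain XYZ remains readable.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    elements: Optional[tuple[str, ...]] = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}")
        if natoms < 1:
            raise XYZParseError(f"line {i + 1}: atom count must be >= 1")
        if i + 1 + natoms >= len(lines) + 1 and i + 1 >= len(lines):
            raise XYZParseError(f"line {i + 1}: truncated frame {frame_no}")
        meta = _parse_comment(lines[i + 1] if i + 1 < len(lines) else "")
        syms: list[str] = []
        pos = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        have_vel = None
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise XYZParseError(f"line {ln + 1}: truncated frame {frame_no}")
            parts = lines[ln].split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"line {ln + 1}: expected 'element x y z [vx vy vz]', got {lines[ln]!r}")
            sym = normalize_element(parts[0])
            if sym not in ATOMIC_MASSES:
                raise XYZParseError(f"line {ln + 1}: unknown element symbol {parts[0]!r}")
            syms.append(sym)
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError:
                raise XYZParseError(f"line {ln + 1}: non-numeric coordinate")
            pos[a] = vals[:3]
            row_has_vel = len(vals) == 6
            if have_vel is None:
                have_vel = row_has_vel
            elif have_vel != row_has_vel:
                raise XYZParseError(
                    f"line {ln + 1}: inconsistent velocity columns within frame {frame_no}")
            if row_has_vel:
                vel[a] = vals[3:]
        if elements is None:
            elements = tuple(syms)
        elif tuple(syms) != elements:
            raise XYZParseError(
                f"line {i + 1}: frame {frame_no} has different atoms than frame 1")
        frames.append(Frame(
            time=meta.get("time", float(len(frames))),
            positions=pos,
            velocities=vel.copy() if have_vel else None,
            potential_energy=meta.get("energy"),
            boundary_radius=meta.get("boundary_radius"),
            boundary_k=meta.get("boundary_k"),
            extra=meta["extra"],
        ))
        i += 2 + natoms
    if elements is None:
        raise XYZParseError("empty XYZ file: no frames found")
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    return Trajectory(elements, masses, frames)


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write a trajectory as extended XYZ (zero frames → zero-byte file)."""
    path = Path(path)
    chunks: list[str] = []
    for f in trajectory.frames:
        meta = [f"time={f.time:.6f}"]
        if f.potential_energy is not None:
            meta.append(f"energy={f.potential_energy:.12g}")
        if f.boundary_radius is not None:
            meta.append(f"boundary_radius={f.boundary_radius:.6f}")
        if f.boundary_k is not None:
            meta.append(f"boundary_k={f.boundary_k:.9g}")
        meta.extend(f"{k}={v}" for k, v in f.extra.items())
        chunks.append(str(trajectory.n_atoms))
        chunks.append(" ".join(meta))
        for a in range(trajectory.n_atoms):
            row = f.positions[a]
            line = f"{trajectory.elements[a]:2s} {row[0]:16.8f} {row[1]:16.8f} {row[2]:16.8f}"
            if f.velocities is not None:
                v = f.velocities[a]
                line += f" {v[0]:16.8f} {v[1]:16.8f} {v[2]:16.8f}"
            chunks.append(line)
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""))


def write_systems_xyz(systems: Sequence[AtomicSystem], path) -> None:
    """Write a sequence of single geometries as a multi-frame XYZ (times = index)."""
    if not systems:
        Path(path).write_text("")
        return
    ref = systems[0]
    frames = [Frame(time=float(k), positions=s.positions, velocities=s.velocities)
              for k, s in enumerate(systems)]
    write_xyz(Trajectory(ref.elements, ref.masses, frames), path)


def kinetic_energy(system: AtomicSystem) -> float:
    """Total kinetic energy Σ ½ m|v|², internal units (amu·Å²·fs⁻²)."""
    if system.velocities is None:
        raise ValueError("system has no velocities")
    return 0.5 * float(np.sum(system.masses[:, None] * system.velocities**2))


def kinetic_temperature(system: AtomicSystem) -> float:
    """Instantaneous kinetic temperature T = 2·KE / (3·N·kB), in kelvin."""
    ke = kinetic_energy(system)
    return 2.0 * ke / (3.0 * system.n_atoms * units.KB)
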