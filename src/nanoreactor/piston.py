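"""Time-dependent spherical "piston" boundary potential.

The nanoreactor's defining feature: a potential that is zero inside a
sphere of radius R(t) and harmonic outside with force constant m_i·k(t),
so every atom outside the boundary feels the same inward *acceleration*
regardless of its mass.  R(t) and k(t) follow a rectangular wave: the
expanded phase (R1, k1) for t1 fs, then the compression stroke (R2, k2)
for t2 fs, repeating with period t1 + t2.

Per-atom energy outside the sphere (d = distance from the center):

    U_i = ½ m_i k(t) (d_i − R(t))²        for d_i > R(t), else 0
    F_i = −m_i k(t) (d_i − R(t)) r̂_i     (central restoring force)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PistonSchedule", "schedule_at", "boundary_energy_forces"]


@dataclass
class PistonSchedule:
    """Rectangular-wave boundary program (R1, k1) ↔ (R2, k2).

    Units: radii Å, periods fs, stiffnesses fs⁻² (force constant of the
    harmonic wall is m_i·k, i.e. k carries units of inverse time squared
    in the amu/Å/fs system).
    """

    R1: float
    R2: float
    t1: float
    t2: float
    k1: float
    k2: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not self.R2 < self.R1:
            raise ValueError(f"require R2 < R1, got R1={self.R1}, R2={self.R2}")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("phase durations t1, t2 must be positive")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("stiffnesses k1, k2 must be >= 0")
        self.center = np.asarray(self.center, dtype=float).reshape(-1)

    @property
    def period(self) -> float:
        return self.t1 + self.t2


def schedule_at(schedule: PistonSchedule, t: float) -> tuple[float, float]:
    """Boundary state (R, k) at time t (fs).

    The cycle starts expanded: (R1, k1) on [n·T, n·T + t1), then (R2, k2)
    on the following t2 interval; switch instants belong to the interval
    they begin (left-closed / right-open).
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    phase = t % schedule.period
    if phase < schedule.t1:
        return schedule.R1, schedule.k1
    return schedule.R2, schedule.k2


def boundary_energy_forces(system, schedule: PistonSchedule, t: float):
    """Boundary energy and per-atom forces for a system at time t.

    Returns ``(U, F)`` with U in internal units (amu·Å²·fs⁻²) and F of
    shape (n, 3).  Atoms inside R(t) contribute nothing; an atom exactly
    at the center is inside (force zero by definition).
    """
    R, k = schedule_at(schedule, t)
    return _energy_forces(system.positions, system.masses, R, k, schedule.center)


def _energy_forces(positions: np.ndarray, masses: np.ndarray,
                   R: float, k: float, center: np.ndarray):
    rel = positions - center
    d = np.linalg.norm(rel, axis=1)
    excess = d - R
    outside = excess > 0
    energy = 0.5 * k * float(np.sum(masses[outside] * excess[outside] ** 2))
    forces = np.zeros_like(positions)
    if np.any(outside):
        unit = rel[outside] / d[outside, None]
        forces[outside] = -(masses[outside] * k * excess[outside])[:, None] * unit
    return energy, forces
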