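"""Time integration: velocity-Verlet (NVE) and BAOAB Langevin dynamics,
with the optional piston boundary for nanoreactor runs.

The BAOAB splitting is used for the Langevin thermostat because it gives
accurate configurational sampling at the large (0.5 fs) time steps this
workflow runs at; the friction is γ = 1/damping_time applied per degree
of freedom, and the same seeded noise stream makes trajectories exactly
reproducible.  As γ → 0 the O-step becomes the identity and the scheme
reduces to velocity-Verlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import units
from .forcefields import ForceProvider
from .piston import PistonSchedule, schedule_at, _energy_forces
from .system import AtomicSystem, Frame, Trajectory


class IntegrationError(RuntimeError):
    """Non-finite energy or force encountered during a run."""


@dataclass
class IntegratorConfig:
    n_steps: int
    dt: float = 0.5                  # fs
    thermostat: str = "none"         # "none" | "langevin"
    temperature: float = 300.0       # K (langevin target)
    damping_time: float = 300.0      # fs
    seed: int = 0
    snapshot_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.thermostat not in ("none", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat == "langevin" and self.damping_time <= 0:
            raise ValueError("damping_time must be > 0 for the Langevin thermostat")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw velocities (Å/fs) from the Maxwell–Boltzmann distribution."""
    sigma = np.sqrt(units.KB * temperature / np.asarray(masses, dtype=float))
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def _check_finite(energy: float, forces: np.ndarray, step: int) -> None:
    if not np.isfinite(energy):
        raise IntegrationError(f"non-finite energy at step {step}")
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.all(np.isfinite(forces), axis=1))[0, 0])
        raise IntegrationError(f"non-finite force at step {step}, atom {bad}")


def integrate(system: AtomicSystem, provider: ForceProvider,
              config: IntegratorConfig,
              schedule: Optional[PistonSchedule] = None) -> Trajectory:
    """Integrate the equations of motion and return the snapshot trajectory.

    Snapshots are taken at step 0, every ``snapshot_stride`` steps, and at
    the final step; each records the potential energy (kJ/mol) and, when a
    piston schedule is active, the boundary radius and stiffness at that
    time.  Velocities default to a Maxwell–Boltzmann draw at the target
    temperature when the system carries none and the thermostat is on;
    otherwise absent velocities start at zero.
    """
    n = system.n_atoms
    x = system.positions.copy()
    masses = system.masses
    rng = np.random.default_rng(config.seed)
    if system.velocities is not None:
        v = system.velocities.copy()
    elif config.thermostat == "langevin":
        v = maxwell_boltzmann_velocities(masses, config.temperature, rng)
    else:
        v = np.zeros_like(x)

    langevin = config.thermostat == "langevin"
    dt = config.dt
    if langevin:
        gamma = 1.0 / config.damping_time
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        sigma_v = np.sqrt(units.KB * config.temperature / masses)[:, None]

    def eval_forces(pos, t, step):
        e, f = provider.evaluate(pos, system.elements)
        if schedule is not None:
            eb, fb = _energy_forces(pos, masses, *schedule_at(schedule, t),
                                    schedule.center)
            e += eb
            f = f + fb
        _check_finite(e, f, step)
        return e, f

    frames: list[Frame] = []

    def snapshot(step, t, pos, vel, epot):
        kwargs = {}
        if schedule is not None:
            R, k = schedule_at(schedule, t)
            kwargs = {"boundary_radius": R, "boundary_k": k}
        frames.append(Frame(time=t, positions=pos.copy(), velocities=vel.copy(),
                            potential_energy=epot * units.EU_TO_KJ_PER_MOL,
                            **kwargs))

    epot, forces = eval_forces(x, 0.0, 0)
    snapshot(0, 0.0, x, v, epot)
    inv_m = (1.0 / masses)[:, None]
    for step in range(1, config.n_steps + 1):
        t_new = step * dt
        # B: half kick
        v = v + 0.5 * dt * forces * inv_m
        if langevin:
            # A-O-A
            x = x + 0.5 * dt * v
            v = c1 * v + c2 * sigma_v * rng.normal(size=v.shape)
            x = x + 0.5 * dt * v
        else:
            x = x + dt * v
        epot, forces = eval_forces(x, t_new, step)
        v = v + 0.5 * dt * forces * inv_m
        if step % config.snapshot_stride == 0 or step == config.n_steps:
            snapshot(step, t_new, x, v, epot)

    return Trajectory(system.elements, masses.copy(), frames)


def run_nanoreactor(packed_system: AtomicSystem, provider: ForceProvider,
                    schedule: PistonSchedule,
                    config: IntegratorConfig) -> Trajectory:
    """Discovery-stage run: dynamics under the physical provider plus the
    piston boundary; snapshots carry the boundary state at their time."""
    return integrate(packed_system, provider, config, schedule=schedule)
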