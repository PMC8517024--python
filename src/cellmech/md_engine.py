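"""Time integration of the bead system.

The integrator is velocity Verlet with a BAOAB-style Langevin splitting:
with ``damping = 0`` and ``temperature = 0`` the O-step is the identity and
the scheme reduces to plain (symplectic) velocity Verlet, used for
energy-conservation checks; with friction and temperature it samples the
canonical ensemble, used for production runs of the overdamped cellular
regime.  All beads have unit mass in reduced units.

External drivers (the virtual AFM tip anchor, substrate tethers, pulling
springs) plug in through the :class:`ExternalForce` protocol; they add
forces and report their own potential energy so total-energy bookkeeping
stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .model_builder import BeadConfiguration, InteractionTable
from .potentials import OverextensionError, PackedInteractions

__all__ = [
    "SimulationConfig", "Trajectory", "SimulationUnstableError",
    "ExternalForce", "HarmonicTethers", "step", "run", "write_xyz",
]


class SimulationUnstableError(RuntimeError):
    """Integration produced an overextended bond or non-finite coordinates."""

    def __init__(self, step_index: int, reason: str):
        self.step_index = step_index
        super().__init__(f"simulation unstable at step {step_index}: {reason}")


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.005
    n_steps: int = 1000
    damping: float = 1.0
    temperature: float = 0.0
    seed: int = 0
    neighbor_skin: float = 0.4
    record_every: int = 100

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.damping < 0 or self.temperature < 0:
            raise ValueError("damping and temperature must be >= 0")
        if self.n_steps < 1 or self.record_every < 1:
            raise ValueError("n_steps and record_every must be >= 1")


class ExternalForce(Protocol):  # pragma: no cover - interface only
    def add_forces(self, t: float, pos: np.ndarray, forces: np.ndarray) -> float:
        """Accumulate forces in place; return this term's potential energy."""
        ...


@dataclass
class HarmonicTethers:
    """Harmonic restraints pinning selected beads to fixed anchor points."""

    indices: np.ndarray
    anchors: np.ndarray
    k: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(-1, 2)

    def add_forces(self, t, pos, forces):
        d = self.anchors - pos[self.indices]
        forces[self.indices] += self.k * d
        return 0.5 * self.k * float(np.sum(d * d))


@dataclass
class Trajectory:
    """Recorded frames plus per-frame energies and run provenance."""

    times: list = field(default_factory=list)
    frames: list = field(default_factory=list)        # BeadConfiguration snapshots
    kinetic: list = field(default_factory=list)
    potential: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def record(self, t, state: BeadConfiguration, ke, pe):
        if self.times and t <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        if not (np.isfinite(ke) and np.isfinite(pe)):
            raise ValueError("energies must be finite")
        self.times.append(t)
        self.frames.append(state.copy())
        self.kinetic.append(ke)
        self.potential.append(pe)

    @property
    def energies(self) -> pd.DataFrame:
        ke = np.asarray(self.kinetic)
        pe = np.asarray(self.potential)
        return pd.DataFrame({"time": self.times, "kinetic": ke,
                             "potential": pe, "total": ke + pe})

    @property
    def final(self) -> BeadConfiguration:
        return self.frames[-1]


class _Integrator:
    """Holds packed interactions, the neighbor list and integrator state."""

    def __init__(self, state: BeadConfiguration, table: InteractionTable,
                 sim: SimulationConfig,
                 external: Sequence[ExternalForce] = (),
                 per_bead_damping: np.ndarray | None = None,
                 thermostat_mask: np.ndarray | None = None):
        table.validate_indices(state.n_beads)
        self.state = state.copy()
        self.sim = sim
        self.external = list(external)
        self.packed = PackedInteractions.from_table(table, state.n_beads)
        self.rng = np.random.default_rng(sim.seed)
        n = state.n_beads
        gamma = np.full(n, sim.damping) if per_bead_damping is None \
            else np.asarray(per_bead_damping, dtype=float)
        dt = sim.dt
        self._c1 = np.exp(-gamma * dt)[:, None]
        self._c2 = np.sqrt(np.maximum(0.0, 1.0 - np.exp(-2 * gamma * dt))
                           * sim.temperature)[:, None]
        if thermostat_mask is not None:
            # damped but athermal beads (e.g. the macroscopic tip apparatus)
            self._c2 = self._c2 * np.asarray(thermostat_mask, float)[:, None]
        self._stochastic = sim.temperature > 0 and np.any(gamma > 0)
        self.t = 0.0
        self._rebuild_neighbors()
        self.forces = np.zeros_like(self.state.positions)
        self.potential = self._compute_forces(step_index=0)

    def _rebuild_neighbors(self):
        self._pair_arrays = self.packed.candidate_pairs(
            self.state.positions, self.state.type_label,
            extra=self.sim.neighbor_skin)
        self._pos_at_build = self.state.positions.copy()

    def _maybe_rebuild(self):
        disp = self.state.positions - self._pos_at_build
        if np.max(np.abs(disp)) * 2.0 > self.sim.neighbor_skin:
            self._rebuild_neighbors()

    def _compute_forces(self, step_index: int) -> float:
        self._maybe_rebuild()
        self.forces[:] = 0.0
        try:
            pe = self.packed.evaluate(self.state.positions, self._pair_arrays,
                                      self.forces)
        except OverextensionError as err:
            raise SimulationUnstableError(
                step_index, f"FENE bond {err.bond_index} overextended") from err
        for ext in self.external:
            pe += ext.add_forces(self.t, self.state.positions, self.forces)
        return pe

    def advance(self, step_index: int):
        dt = self.sim.dt
        pos, vel = self.state.positions, self.state.velocities
        vel += 0.5 * dt * self.forces                      # B
        pos += 0.5 * dt * vel                              # A
        if self._stochastic:                               # O
            noise = self.rng.standard_normal(pos.shape)
            vel *= self._c1
            vel += self._c2 * noise
        elif self.sim.damping > 0:
            vel *= self._c1
        pos += 0.5 * dt * vel                              # A
        self.t += dt
        pe = self._compute_forces(step_index)
        vel += 0.5 * dt * self.forces                      # B
        if not np.all(np.isfinite(pos)):
            raise SimulationUnstableError(step_index, "non-finite position")
        self.potential = pe

    @property
    def kinetic(self) -> float:
        v = self.state.velocities
        return 0.5 * float(np.sum(v * v))


def step(state: BeadConfiguration, table: InteractionTable,
         sim: SimulationConfig,
         external: Sequence[ExternalForce] = ()) -> BeadConfiguration:
    """One integrator update; returns the new configuration.

    Convenience wrapper: for long runs use :func:`run`, which keeps the
    packed system and neighbor list alive between steps.
    """
    integ = _Integrator(state, table, sim, external)
    integ.advance(step_index=1)
    return integ.state


def run(state: BeadConfiguration, table: InteractionTable,
        sim: SimulationConfig,
        external: Sequence[ExternalForce] = (),
        per_bead_damping: np.ndarray | None = None,
        thermostat_mask: np.ndarray | None = None,
        on_record: Callable[[int, "_Integrator"], None] | None = None,
        until: Callable[[int, "_Integrator"], bool] | None = None) -> Trajectory:
    """Integrate ``sim.n_steps`` steps, recording every ``record_every``.

    ``on_record(step_index, integrator)`` lets callers sample observables
    (e.g. tip spring deformation) on the recording grid; ``until`` is
    checked on the same grid and stops the run early when it returns True.
    """
    integ = _Integrator(state, table, sim, external, per_bead_damping,
                        thermostat_mask)
    traj = Trajectory(metadata={"sim": sim, "seed": sim.seed})
    traj.record(0.0, integ.state, integ.kinetic, integ.potential)
    if on_record is not None:
        on_record(0, integ)
    for s in range(1, sim.n_steps + 1):
        integ.advance(s)
        if s % sim.record_every == 0 or s == sim.n_steps:
            traj.record(integ.t, integ.state, integ.kinetic, integ.potential)
            if on_record is not None:
                on_record(s, integ)
            if until is not None and until(s, integ):
                break
    return traj


def write_xyz(trajectory: Trajectory, path, energy_csv=None) -> None:
    """Write frames as extended-XYZ text (type, x, y) and optionally the
    per-frame energy log as CSV."""
    path = Path(path)
    with path.open("w") as fh:
        for t, frame in zip(trajectory.times, trajectory.frames):
            fh.write(f"{frame.n_beads}\n")
            fh.write(f'Properties=species:I:1:pos:R:2 Time={t!r}\n')
            for ty, (x, y) in zip(frame.type_label, frame.positions):
                fh.write(f"{ty} {x!r} {y!r}\n")
    if energy_csv is not None:
        trajectory.energies.to_csv(energy_csv, index=False)
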