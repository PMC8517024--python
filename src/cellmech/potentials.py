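"""Interaction potentials of the coarse-grained cell model.

Four energy terms define the mechanics:

* a Lennard-Jones pair potential written with its minimum at the
  equilibrium distance sigma, ``U(r) = eps[(sigma/r)^12 - 2 (sigma/r)^6]``,
  used for the two tunable attractions of the model (membrane-membrane
  adhesion ``eps00`` and filament-head-to-membrane contractility ``eps03``);
* its purely repulsive WCA truncation, used for excluded volume between all
  other bead-type pairs;
* a FENE bond potential with a finite extension/compression window
  ``|r - r0| < drmax`` for every spring (membrane rings, nuclear ring,
  filament backbones);
* a cosine-form bend potential ``kB/2 (cos(theta) - cos(theta0))^2`` on
  consecutive bead triples, which confers ring and filament rigidity.

Scalar kernels accept numpy arrays and follow the equations exactly;
``total_forces``/``total_energy`` assemble the full system via compiled
loops and are the single force implementation used by the MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from ._kernels import KIND_LJ, KIND_NONE, KIND_WCA

if TYPE_CHECKING:  # pragma: no cover
    from .model_builder import BeadConfiguration, InteractionTable

__all__ = [
    "PairPotentialParams", "FeneParams", "BendParams",
    "lj_energy", "wca_energy", "fene_energy", "bend_energy",
    "total_energy", "total_forces", "OverextensionError",
]


class OverextensionError(ValueError):
    """A FENE bond left its admissible window |r - r0| < drmax."""

    def __init__(self, bond_index: int, message: str | None = None):
        self.bond_index = bond_index
        super().__init__(message or f"FENE bond {bond_index} overextended")


@dataclass(frozen=True)
class PairPotentialParams:
    """Non-bonded pair rule: kind 'lj' or 'wca', well depth, equilibrium
    distance and cutoff.  For WCA the cutoff is pinned to sigma; for LJ the
    default cutoff is 2.5 sigma with the energy shifted to zero there.  A
    cutoff of ``inf`` gives the untruncated form."""

    epsilon: float
    sigma: float
    cutoff: float | None = None
    kind: str = "lj"

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kind not in ("lj", "wca"):
            raise ValueError(f"unknown pair kind {self.kind!r}")
        if self.kind == "wca":
            object.__setattr__(self, "cutoff", self.sigma)
        elif self.cutoff is None:
            object.__setattr__(self, "cutoff", math.inf)
        elif self.cutoff < self.sigma:
            raise ValueError("LJ cutoff must be >= sigma")

    @property
    def shift(self) -> float:
        """Energy at the cutoff, subtracted inside it for continuity."""
        if self.kind == "wca" or math.isinf(self.cutoff):
            return 0.0
        s6 = (self.sigma / self.cutoff) ** 6
        return self.epsilon * (s6 * s6 - 2.0 * s6)


@dataclass(frozen=True)
class FeneParams:
    """Finitely extensible bond: stiffness kF, rest length r0, window drmax."""

    kF: float
    r0: float
    drmax: float

    def __post_init__(self):
        if self.drmax <= 0:
            raise ValueError("drmax must be > 0")
        if self.r0 <= 0:
            raise ValueError("r0 must be > 0")


@dataclass(frozen=True)
class BendParams:
    """Cosine bend term: stiffness kB and equilibrium angle theta0."""

    kB: float
    theta0: float

    def __post_init__(self):
        if self.kB < 0:
            raise ValueError("kB must be >= 0")
        if not (0.0 < self.theta0 <= math.pi):
            raise ValueError("theta0 must lie in (0, pi]")


def lj_energy(r, p: PairPotentialParams):
    """Lennard-Jones energy with minimum -epsilon at r = sigma.

    Zero at and beyond the cutoff, with the inside branch shifted so the
    potential is continuous there.  Raises for non-positive separations.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be > 0")
    s6 = (p.sigma / r) ** 6
    u = p.epsilon * (s6 * s6 - 2.0 * s6) - p.shift
    return np.where(r < p.cutoff, u, 0.0)[()]


def wca_energy(r, p: PairPotentialParams):
    """WCA (repulsive-only) energy: LJ + epsilon below sigma, zero above."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be > 0")
    s6 = (p.sigma / r) ** 6
    u = p.epsilon * (s6 * s6 - 2.0 * s6) + p.epsilon
    return np.where(r < p.sigma, u, 0.0)[()]


def fene_energy(r, p: FeneParams):
    """FENE energy, zero at r0 and divergent as |r - r0| -> drmax."""
    r = np.asarray(r, dtype=float)
    x = (r - p.r0) / p.drmax
    if np.any(np.abs(x) >= 1.0):
        raise OverextensionError(-1, "separation outside FENE window")
    return (-0.5 * p.kF * p.drmax ** 2 * np.log(1.0 - x * x))[()]


def bend_energy(theta, p: BendParams):
    """Bend energy kB/2 (cos(theta) - cos(theta0))^2."""
    c = np.clip(np.cos(np.asarray(theta, dtype=float)), -1.0, 1.0)
    return (0.5 * p.kB * (c - math.cos(p.theta0)) ** 2)[()]


# ---------------------------------------------------------------------------
# System assembly

_MAX_TYPE = 8  # type labels are small integers (0, 1, 3, 7)


@dataclass
class PackedInteractions:
    """Flat-array view of an InteractionTable for the compiled kernels."""

    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_kf: np.ndarray
    bond_r0: np.ndarray
    bond_dr: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_kb: np.ndarray
    ang_cos0: np.ndarray
    kind_m: np.ndarray   # (_MAX_TYPE, _MAX_TYPE) int
    eps_m: np.ndarray
    sigma_m: np.ndarray
    cutoff_m: np.ndarray
    shift_m: np.ndarray
    excluded: np.ndarray  # sorted encoded i*N+j (i<j) bonded pairs
    n_beads: int
    rmax: float = field(default=0.0)

    @classmethod
    def from_table(cls, table: "InteractionTable", n_beads: int) -> "PackedInteractions":
        bonds = np.asarray(table.bonds, dtype=np.int64).reshape(-1, 2)
        angles = np.asarray(table.angles, dtype=np.int64).reshape(-1, 3)
        kind_m = np.zeros((_MAX_TYPE, _MAX_TYPE), dtype=np.int64)
        eps_m = np.zeros((_MAX_TYPE, _MAX_TYPE))
        sigma_m = np.ones((_MAX_TYPE, _MAX_TYPE))
        cutoff_m = np.zeros((_MAX_TYPE, _MAX_TYPE))
        shift_m = np.zeros((_MAX_TYPE, _MAX_TYPE))
        rmax = 0.0
        for (ti, tj), p in table.pair_rules.items():
            k = KIND_LJ if p.kind == "lj" else KIND_WCA
            for a, b in ((ti, tj), (tj, ti)):
                kind_m[a, b] = k
                eps_m[a, b] = p.epsilon
                sigma_m[a, b] = p.sigma
                cutoff_m[a, b] = p.cutoff
                shift_m[a, b] = p.shift
            if np.isfinite(p.cutoff):
                rmax = max(rmax, p.cutoff)
            else:
                raise ValueError("system assembly requires finite pair cutoffs")
        if bonds.size:
            lo = np.minimum(bonds[:, 0], bonds[:, 1])
            hi = np.maximum(bonds[:, 0], bonds[:, 1])
            excluded = np.unique(lo.astype(np.int64) * n_beads + hi)
        else:
            excluded = np.empty(0, dtype=np.int64)
        return cls(
            bond_i=np.ascontiguousarray(bonds[:, 0]),
            bond_j=np.ascontiguousarray(bonds[:, 1]),
            bond_kf=np.asarray(table.bond_kF, dtype=float),
            bond_r0=np.asarray(table.bond_r0, dtype=float),
            bond_dr=np.asarray(table.bond_drmax, dtype=float),
            ang_i=np.ascontiguousarray(angles[:, 0]) if angles.size else np.empty(0, np.int64),
            ang_j=np.ascontiguousarray(angles[:, 1]) if angles.size else np.empty(0, np.int64),
            ang_k=np.ascontiguousarray(angles[:, 2]) if angles.size else np.empty(0, np.int64),
            ang_kb=np.asarray(table.angle_kB, dtype=float),
            ang_cos0=np.cos(np.asarray(table.angle_theta0, dtype=float)),
            kind_m=kind_m, eps_m=eps_m, sigma_m=sigma_m,
            cutoff_m=cutoff_m, shift_m=shift_m,
            excluded=excluded, n_beads=n_beads, rmax=rmax,
        )

    def candidate_pairs(self, positions: np.ndarray, types: np.ndarray,
                        extra: float = 0.0):
        """Non-bonded candidate pairs within rmax + extra, with bonded pairs
        excluded and per-pair parameters resolved from the rule matrices.

        Pair rules are type-based and global: they apply across cells too
        (in a colony, membranes adhere through (0,0) and filament heads
        couple to any membrane within range through (0,3), the junctional
        face of contractility).
        """
        tree = cKDTree(positions)
        pairs = tree.query_pairs(self.rmax + extra, output_type="ndarray")
        if pairs.size:
            enc = pairs[:, 0].astype(np.int64) * self.n_beads + pairs[:, 1]
            keep = ~np.isin(enc, self.excluded)
            pairs = pairs[keep]
        ti = types[pairs[:, 0]] if pairs.size else np.empty(0, np.int64)
        tj = types[pairs[:, 1]] if pairs.size else np.empty(0, np.int64)
        return (
            np.ascontiguousarray(pairs[:, 0]) if pairs.size else np.empty(0, np.int64),
            np.ascontiguousarray(pairs[:, 1]) if pairs.size else np.empty(0, np.int64),
            self.kind_m[ti, tj],
            self.eps_m[ti, tj],
            self.sigma_m[ti, tj],
            self.cutoff_m[ti, tj],
            self.shift_m[ti, tj],
        )

    def evaluate(self, positions: np.ndarray, pair_arrays, forces_out: np.ndarray):
        """Accumulate all forces; returns potential energy.  Raises
        OverextensionError when a FENE bond leaves its window."""
        e_bond, bad = _kernels.bonded_forces(
            positions, self.bond_i, self.bond_j, self.bond_kf,
            self.bond_r0, self.bond_dr,
            self.ang_i, self.ang_j, self.ang_k, self.ang_kb, self.ang_cos0,
            forces_out)
        if bad >= 0:
            raise OverextensionError(int(bad))
        e_pair = _kernels.pair_forces(positions, *pair_arrays, forces_out)
        return e_bond + e_pair


def _packed(config: "BeadConfiguration", table: "InteractionTable"):
    packed = PackedInteractions.from_table(table, config.n_beads)
    pair_arrays = packed.candidate_pairs(config.positions, config.type_label)
    return packed, pair_arrays


def total_forces(config: "BeadConfiguration", table: "InteractionTable") -> np.ndarray:
    """Per-bead force vectors, the negative gradient of ``total_energy``."""
    packed, pair_arrays = _packed(config, table)
    forces = np.zeros_like(config.positions)
    packed.evaluate(config.positions, pair_arrays, forces)
    return forces


def total_energy(config: "BeadConfiguration", table: "InteractionTable") -> float:
    """Total potential energy (bonded + non-bonded) of a configuration."""
    packed, pair_arrays = _packed(config, table)
    forces = np.zeros_like(config.positions)
    return packed.evaluate(config.positions, pair_arrays, forces)


def bonded_energy(config: "BeadConfiguration", table: "InteractionTable") -> float:
    """FENE + bend energy only (zero for a freshly built relaxed cell)."""
    packed = PackedInteractions.from_table(table, config.n_beads)
    forces = np.zeros_like(config.positions)
    e, bad = _kernels.bonded_forces(
        config.positions, packed.bond_i, packed.bond_j, packed.bond_kf,
        packed.bond_r0, packed.bond_dr, packed.ang_i, packed.ang_j,
        packed.ang_k, packed.ang_kb, packed.ang_cos0, forces)
    if bad >= 0:
        raise OverextensionError(int(bad))
    return e
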