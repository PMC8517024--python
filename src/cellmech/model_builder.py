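"""Construction of single-cell and colony bead-spring geometries.

A cell is a closed membrane ring (type-0 beads), a closed nuclear ring
(type-1 beads) and radial actin filaments.  Type I filaments are bonded to
the nuclear ring at their inner end; type II filaments float free in the
annulus.  The outermost bead of every filament (the "head", closest to the
membrane) carries label 3 so that the head-membrane attraction ``eps03``
- the model's stand-in for actomyosin contractility - can address it.

All dynamics run in reduced units.  The default mapping sets the membrane
bead spacing (and the sigma of the (0,0) pair rule) to one length unit, and
``GeometryConfig.length_unit`` records how many micrometres that is.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .potentials import PairPotentialParams

__all__ = [
    "GeometryConfig", "SpringConstants", "BeadConfiguration",
    "InteractionTable", "GeometryError", "build_cell", "build_colony",
    "hex_centers", "save_model", "load_model",
    "TYPE_MEMBRANE", "TYPE_FILAMENT", "TYPE_HEAD", "TYPE_TIP",
    "BOND_MEMBRANE", "BOND_FILAMENT", "BOND_HEAD",
]

TYPE_MEMBRANE = 0   # cell-membrane ring beads
TYPE_FILAMENT = 1   # filament interior + nuclear-ring beads
TYPE_HEAD = 3       # filament bead nearest the membrane
TYPE_TIP = 7        # virtual AFM tip bead
VALID_TYPES = frozenset((TYPE_MEMBRANE, TYPE_FILAMENT, TYPE_HEAD, TYPE_TIP))

# FENE bond classes, named after the bead types they join
BOND_MEMBRANE = 0   # membrane-membrane (kF00)
BOND_FILAMENT = 1   # filament-internal and nuclear-ring/nuclear-anchor (kF11)
BOND_HEAD = 3       # filament-head to membrane (kF13), optional


class GeometryError(ValueError):
    """Raised when a requested geometry is infeasible."""


@dataclass(frozen=True)
class GeometryConfig:
    """Bead-count and size parameters of one cell.

    Lengths are in micrometres; ``length_unit`` (micrometres per reduced
    unit) defaults to the membrane bead spacing pi*d/n so that the membrane
    spacing, and with it the sigma of the (0,0) pair rule, equals 1.
    """

    n_membrane_beads: int = 201
    cell_diameter: float = 5.25
    n_nuclear_beads: int = 33
    nucleus_diameter: float = 1.5
    typeI_beads: int = 10
    typeI_length: float = 1.5
    typeII_beads: int = 8
    typeII_length: float = 1.2
    n_typeI_filaments: int = 11
    interspersal_pattern: tuple[str, ...] = ("I", "II", "II")
    length_unit: float | None = None
    head_clearance: float = 1.0  # reduced gap between filament head and membrane

    def __post_init__(self):
        for name in ("n_membrane_beads", "n_nuclear_beads", "typeI_beads",
                     "typeII_beads"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3")
        if self.n_typeI_filaments < 1:
            raise ValueError("n_typeI_filaments must be >= 1")
        if self.cell_diameter <= 0 or self.nucleus_diameter <= 0:
            raise ValueError("diameters must be > 0")
        if self.nucleus_diameter >= self.cell_diameter:
            raise ValueError("nucleus_diameter must be < cell_diameter")
        if self.typeI_length + self.nucleus_diameter / 2 >= self.cell_diameter / 2:
            raise ValueError("type I filament cannot fit between nucleus and membrane")
        if "I" not in self.interspersal_pattern or not all(
                s in ("I", "II") for s in self.interspersal_pattern):
            raise ValueError("interspersal_pattern must mix 'I' and 'II' labels")
        if self.length_unit is None:
            object.__setattr__(
                self, "length_unit",
                math.pi * self.cell_diameter / self.n_membrane_beads)
        elif self.length_unit <= 0:
            raise ValueError("length_unit must be > 0")

    # reduced-unit views -------------------------------------------------
    def to_reduced(self, micrometres: float) -> float:
        return micrometres / self.length_unit

    @property
    def cell_radius(self) -> float:
        return self.to_reduced(self.cell_diameter) / 2

    @property
    def nucleus_radius(self) -> float:
        return self.to_reduced(self.nucleus_diameter) / 2

    @property
    def filament_slots(self) -> tuple[str, ...]:
        """Angular slot labels: the interspersal pattern repeated until
        n_typeI_filaments type I slots have been placed."""
        per_cycle = self.interspersal_pattern.count("I")
        n_cycles, rem = divmod(self.n_typeI_filaments, per_cycle)
        slots = list(self.interspersal_pattern) * n_cycles
        if rem:
            got = 0
            for lab in self.interspersal_pattern:
                slots.append(lab)
                if lab == "I":
                    got += 1
                    if got == rem:
                        break
        return tuple(slots)

    @classmethod
    def compact(cls) -> "GeometryConfig":
        """A reduced-size cell for colony-scale runs: same cell and nucleus
        diameters, ~3x coarser bead resolution, and shortened filaments so
        that the fat filament beads keep their excluded-volume clearance
        from the nuclear ring at this resolution."""
        return cls(n_membrane_beads=60, n_nuclear_beads=12,
                   typeI_beads=4, typeI_length=1.0,
                   typeII_beads=3, typeII_length=0.8,
                   n_typeI_filaments=4)


@dataclass(frozen=True)
class SpringConstants:
    """FENE and bend stiffnesses.  ``None`` fields derive their defaults:
    kF11 = kF00, kF13 = 5*kF11, drmax = drmax_frac * r0 per bond, r0 and
    theta0 = as-constructed spacing/angle (so the built state is relaxed)."""

    kF00: float = 40.0
    kF11: float | None = None
    kF13: float | None = None
    kB: float = 5.0
    drmax: float | None = None
    drmax_frac: float = 0.5
    r0: float | None = None
    theta0: float | None = None

    def __post_init__(self):
        if self.kF11 is None:
            object.__setattr__(self, "kF11", self.kF00)
        if self.kF13 is None:
            object.__setattr__(self, "kF13", 5.0 * self.kF11)
        if self.kF00 <= 0 or self.kF11 <= 0 or self.kF13 <= 0:
            raise ValueError("FENE stiffnesses must be > 0")
        if self.drmax is not None and self.drmax <= 0:
            raise ValueError("drmax must be > 0")
        if not (0 < self.drmax_frac < 1):
            raise ValueError("drmax_frac must be in (0, 1)")

    def kf_for(self, bond_class: int) -> float:
        return {BOND_MEMBRANE: self.kF00, BOND_FILAMENT: self.kF11,
                BOND_HEAD: self.kF13}[bond_class]

    def drmax_for(self, r0: float) -> float:
        return self.drmax if self.drmax is not None else self.drmax_frac * r0


@dataclass
class BeadConfiguration:
    """Positions, velocities, type labels and cell ids for all beads."""

    positions: np.ndarray
    velocities: np.ndarray
    type_label: np.ndarray
    cell_id: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        n = self.positions.shape[0]
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 2)
        self.type_label = np.asarray(self.type_label, dtype=np.int64).reshape(n)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64).reshape(n)
        bad = set(np.unique(self.type_label)) - VALID_TYPES
        if bad:
            raise ValueError(f"invalid bead type labels: {sorted(bad)}")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "BeadConfiguration":
        return BeadConfiguration(self.positions.copy(), self.velocities.copy(),
                                 self.type_label.copy(), self.cell_id.copy())


@dataclass
class InteractionTable:
    """Bonded terms plus the (type_i, type_j) -> pair-rule map."""

    bonds: np.ndarray          # (M, 2) bead indices
    bond_class: np.ndarray     # (M,) in {BOND_MEMBRANE, BOND_FILAMENT, BOND_HEAD}
    bond_kF: np.ndarray
    bond_r0: np.ndarray
    bond_drmax: np.ndarray
    angles: np.ndarray         # (K, 3) bead indices, middle bead central
    angle_kB: np.ndarray
    angle_theta0: np.ndarray
    pair_rules: dict[tuple[int, int], PairPotentialParams] = field(default_factory=dict)

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        m = self.bonds.shape[0]
        self.bond_class = np.asarray(self.bond_class, dtype=np.int64).reshape(m)
        self.bond_kF = np.asarray(self.bond_kF, dtype=float).reshape(m)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float).reshape(m)
        self.bond_drmax = np.asarray(self.bond_drmax, dtype=float).reshape(m)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        k = self.angles.shape[0]
        self.angle_kB = np.asarray(self.angle_kB, dtype=float).reshape(k)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float).reshape(k)
        # canonicalize pair-rule keys so the map is symmetric by construction
        self.pair_rules = {(min(a, b), max(a, b)): p
                           for (a, b), p in self.pair_rules.items()}

    def validate_indices(self, n_beads: int) -> None:
        for arr in (self.bonds, self.angles):
            if arr.size and (arr.min() < 0 or arr.max() >= n_beads):
                raise ValueError("bond/angle references an invalid bead index")

    def rule(self, ti: int, tj: int) -> PairPotentialParams:
        return self.pair_rules[(min(ti, tj), max(ti, tj))]

    @property
    def eps00(self) -> float:
        return self.rule(TYPE_MEMBRANE, TYPE_MEMBRANE).epsilon

    @property
    def eps03(self) -> float:
        return self.rule(TYPE_MEMBRANE, TYPE_HEAD).epsilon

    def with_pair_epsilon(self, ti: int, tj: int, epsilon: float) -> "InteractionTable":
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        rules = dict(self.pair_rules)
        key = (min(ti, tj), max(ti, tj))
        rules[key] = replace(rules[key], epsilon=epsilon)
        return InteractionTable(self.bonds, self.bond_class, self.bond_kF,
                                self.bond_r0, self.bond_drmax, self.angles,
                                self.angle_kB, self.angle_theta0, rules)

    def with_eps00(self, epsilon: float) -> "InteractionTable":
        return self.with_pair_epsilon(TYPE_MEMBRANE, TYPE_MEMBRANE, epsilon)

    def with_eps03(self, epsilon: float) -> "InteractionTable":
        return self.with_pair_epsilon(TYPE_MEMBRANE, TYPE_HEAD, epsilon)


def default_pair_rules(eps00: float = 1.0, eps03: float = 0.8,
                       eps_repulsive: float = 1.0, sigma: float = 1.0,
                       sigma_filament: float = 2.0,
                       lj_cutoff: float = 2.5) -> dict:
    """The model's pair-rule map: LJ attraction for (0,0) adhesion and (0,3)
    contractility, WCA excluded volume for every other cell-bead pair.

    Filament/nuclear beads carry a larger excluded-volume diameter
    (``sigma_filament``) than membrane beads: the filament scaffold then
    forms a crowded, load-bearing interior whose coupling to the membrane
    is controlled by eps03 - the mechanism by which contractility stiffens
    the cell's indentation response.
    """
    rules = {
        (TYPE_MEMBRANE, TYPE_MEMBRANE): PairPotentialParams(eps00, sigma, lj_cutoff * sigma, "lj"),
        (TYPE_MEMBRANE, TYPE_HEAD): PairPotentialParams(eps03, sigma, lj_cutoff * sigma, "lj"),
        (TYPE_MEMBRANE, TYPE_FILAMENT): PairPotentialParams(
            eps_repulsive, 0.5 * (sigma + sigma_filament), kind="wca"),
    }
    for pair in ((TYPE_FILAMENT, TYPE_FILAMENT), (TYPE_FILAMENT, TYPE_HEAD),
                 (TYPE_HEAD, TYPE_HEAD)):
        rules[pair] = PairPotentialParams(eps_repulsive, sigma_filament, kind="wca")
    return rules


def _ring(n: int, radius: float, center: np.ndarray, phase: float = 0.0):
    ang = phase + 2 * math.pi * np.arange(n) / n
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def build_cell(config: GeometryConfig | None = None,
               springs: SpringConstants | None = None,
               center=(0.0, 0.0),
               eps00: float = 1.0, eps03: float = 0.8,
               anchor_heads: bool = False,
               cell_id: int = 0):
    """Build one cell: returns ``(BeadConfiguration, InteractionTable)``.

    The construction is mechanically relaxed: every FENE r0 is the as-built
    bond length and every bend theta0 the as-built angle (overridable via
    ``SpringConstants``), so the total bonded energy of the fresh build is
    zero.  ``anchor_heads=True`` additionally bonds each filament head to
    its nearest membrane bead with the stiff kF13 class.
    """
    config = config or GeometryConfig()
    springs = springs or SpringConstants()
    center = np.asarray(center, dtype=float)

    R = config.cell_radius
    r_nuc = config.nucleus_radius

    pos_parts, type_parts = [], []
    bonds, bclass = [], []
    angles = []

    def add_ring(n, radius, bead_type, bond_class):
        start = sum(p.shape[0] for p in pos_parts)
        pos_parts.append(_ring(n, radius, center))
        type_parts.append(np.full(n, bead_type, dtype=np.int64))
        idx = start + np.arange(n)
        for a in range(n):
            bonds.append((idx[a], idx[(a + 1) % n]))
            bclass.append(bond_class)
            angles.append((idx[(a - 1) % n], idx[a], idx[(a + 1) % n]))
        return idx

    add_ring(config.n_membrane_beads, R, TYPE_MEMBRANE, BOND_MEMBRANE)
    nuc_idx = add_ring(config.n_nuclear_beads, r_nuc, TYPE_FILAMENT, BOND_FILAMENT)

    # radial filaments on equally spaced angular slots
    slots = config.filament_slots
    n_slots = len(slots)
    head_r = R - config.head_clearance
    fil_theta0 = []  # per-filament-angle theta0 (pi: straight)
    head_indices = []
    for s, lab in enumerate(slots):
        ang = 2 * math.pi * s / n_slots
        u = np.array([math.cos(ang), math.sin(ang)])
        if lab == "I":
            nb, L = config.typeI_beads, config.to_reduced(config.typeI_length)
        else:
            nb, L = config.typeII_beads, config.to_reduced(config.typeII_length)
        inner_r = head_r - L
        if inner_r <= r_nuc and lab == "II":
            raise GeometryError(
                f"type II filament at slot {s} would penetrate the nucleus")
        if lab == "I" and inner_r <= r_nuc * 0.99:
            raise GeometryError(
                f"type I filament at slot {s} does not fit between nucleus and membrane")
        if head_r >= R:
            raise GeometryError("filament head would cross the membrane")
        radii = head_r - L + L * np.arange(nb) / (nb - 1)  # inner -> head
        start = sum(p.shape[0] for p in pos_parts)
        pos_parts.append(center + np.outer(radii, u))
        tl = np.full(nb, TYPE_FILAMENT, dtype=np.int64)
        tl[-1] = TYPE_HEAD
        type_parts.append(tl)
        idx = start + np.arange(nb)
        head_indices.append(idx[-1])
        for a in range(nb - 1):
            bonds.append((idx[a], idx[a + 1]))
            bclass.append(BOND_FILAMENT)
        for a in range(1, nb - 1):
            angles.append((idx[a - 1], idx[a], idx[a + 1]))
            fil_theta0.append(len(angles) - 1)
        if lab == "I":
            # anchor the innermost bead to the nearest nuclear-ring bead
            nuc_ang = 2 * math.pi * np.arange(config.n_nuclear_beads) / config.n_nuclear_beads
            j = int(np.argmin(np.abs(np.angle(np.exp(1j * (nuc_ang - ang))))))
            bonds.append((nuc_idx[j], idx[0]))
            bclass.append(BOND_FILAMENT)

    positions = np.vstack(pos_parts)
    types = np.concatenate(type_parts)

    if anchor_heads:
        mem = positions[:config.n_membrane_beads]
        for h in head_indices:
            j = int(np.argmin(np.sum((mem - positions[h]) ** 2, axis=1)))
            bonds.append((h, j))
            bclass.append(BOND_HEAD)

    bonds = np.asarray(bonds, dtype=np.int64)
    bclass = np.asarray(bclass, dtype=np.int64)
    d = positions[bonds[:, 0]] - positions[bonds[:, 1]]
    built_r0 = np.sqrt(np.sum(d * d, axis=1))
    r0 = np.full_like(built_r0, springs.r0) if springs.r0 is not None else built_r0
    kf = np.array([springs.kf_for(c) for c in bclass])
    drmax = np.array([springs.drmax_for(r) for r in r0])

    angles = np.asarray(angles, dtype=np.int64)
    if springs.theta0 is not None:
        theta0 = np.full(angles.shape[0], springs.theta0)
    else:
        u = positions[angles[:, 0]] - positions[angles[:, 1]]
        v = positions[angles[:, 2]] - positions[angles[:, 1]]
        c = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        theta0 = np.arccos(np.clip(c, -1.0, 1.0))
    kb = np.full(angles.shape[0], springs.kB)

    beads = BeadConfiguration(positions, np.zeros_like(positions), types,
                              np.full(positions.shape[0], cell_id, dtype=np.int64))
    table = InteractionTable(bonds, bclass, kf, r0, drmax, angles, kb, theta0,
                             default_pair_rules(eps00=eps00, eps03=eps03))
    table.validate_indices(beads.n_beads)
    _check_no_hard_overlap(beads, table)
    return beads, table


def _check_no_hard_overlap(beads: BeadConfiguration, table: InteractionTable,
                           tolerance: float = 0.85) -> None:
    """Reject built geometries where non-bonded beads start deep inside each
    other's repulsive core (they would overextend bonds within a few steps)."""
    from .potentials import PackedInteractions
    packed = PackedInteractions.from_table(table, beads.n_beads)
    pi, pj, kind, eps, sigma, cutoff, shift = packed.candidate_pairs(
        beads.positions, beads.type_label)
    if pi.size == 0:
        return
    r = np.linalg.norm(beads.positions[pi] - beads.positions[pj], axis=1)
    ratio = r / sigma
    bad = (kind != 0) & (ratio < tolerance)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise GeometryError(
            f"beads {int(pi[k])} and {int(pj[k])} start at separation "
            f"{r[k]:.3f} < {tolerance} x sigma ({sigma[k]:.3f}); "
            "the requested geometry is infeasible at this bead resolution")


def hex_centers(n_cells: int, spacing: float) -> np.ndarray:
    """Centers of a hexagonal-packing spiral (closest to origin first)."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n_cells:
        # walk the hexagonal ring at radius `ring`
        q, r = ring, 0
        dirs = [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]
        for dq, dr in dirs:
            for _ in range(ring):
                x = spacing * (q + r / 2.0)
                y = spacing * (math.sqrt(3) / 2.0) * r
                pts.append((x, y))
                q += dq
                r += dr
        ring += 1
    pts = np.asarray(pts[:n_cells * 4], dtype=float)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    return pts[order][:n_cells]


def build_colony(n_cells: int, arrangement="hex",
                 config: GeometryConfig | None = None,
                 springs: SpringConstants | None = None,
                 gap: float = 1.0,
                 eps00: float = 1.0, eps03: float = 0.8,
                 anchor_heads: bool = False):
    """Build ``n_cells`` identical cells on a lattice.

    Returns ``(BeadConfiguration, InteractionTable, roles)`` where roles[i]
    is 'center' (six neighbours at lattice distance) or 'edge'.  Cells only
    interact through non-bonded pair rules; membrane-membrane adhesion
    across cells is the (0,0) LJ rule with ``eps00``.
    """
    if n_cells < 2:
        raise ValueError("a colony needs >= 2 cells")
    config = config or GeometryConfig.compact()
    cutoff = default_pair_rules()[(TYPE_MEMBRANE, TYPE_MEMBRANE)].cutoff
    D = 2 * config.cell_radius
    if isinstance(arrangement, str):
        if arrangement != "hex":
            raise ValueError(f"unknown arrangement {arrangement!r}")
        if gap <= 0:
            raise GeometryError("initial membranes would overlap (gap <= 0)")
        if gap >= cutoff:
            raise GeometryError(
                f"inter-cell gap {gap} exceeds the (0,0) cutoff {cutoff}; "
                "adhesion would never engage")
        centers = hex_centers(n_cells, D + gap)
        lattice = D + gap
    else:
        centers = np.asarray(arrangement, dtype=float).reshape(-1, 2)
        if centers.shape[0] != n_cells:
            raise ValueError("arrangement must supply one center per cell")
        dmat = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        if dmat.min() <= D:
            raise GeometryError("initial membranes would overlap")
        if dmat.min() - D >= cutoff:
            raise GeometryError("cells too far apart for adhesion to engage")
        lattice = dmat.min()

    parts, tables = [], []
    for c, ctr in enumerate(centers):
        beads, table = build_cell(config, springs, center=ctr, eps00=eps00,
                                  eps03=eps03, anchor_heads=anchor_heads,
                                  cell_id=c)
        parts.append(beads)
        tables.append(table)

    offsets = np.cumsum([0] + [b.n_beads for b in parts[:-1]])
    merged = BeadConfiguration(
        np.vstack([b.positions for b in parts]),
        np.vstack([b.velocities for b in parts]),
        np.concatenate([b.type_label for b in parts]),
        np.concatenate([b.cell_id for b in parts]),
    )
    table = InteractionTable(
        np.vstack([t.bonds + o for t, o in zip(tables, offsets)]),
        np.concatenate([t.bond_class for t in tables]),
        np.concatenate([t.bond_kF for t in tables]),
        np.concatenate([t.bond_r0 for t in tables]),
        np.concatenate([t.bond_drmax for t in tables]),
        np.vstack([t.angles + o for t, o in zip(tables, offsets)]),
        np.concatenate([t.angle_kB for t in tables]),
        np.concatenate([t.angle_theta0 for t in tables]),
        tables[0].pair_rules,
    )
    table.validate_indices(merged.n_beads)

    dmat = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(dmat, np.inf)
    n_neighbors = np.sum(dmat < 1.1 * lattice, axis=1)
    roles = ["center" if n >= 6 else "edge" for n in n_neighbors]
    return merged, table, roles


# ---------------------------------------------------------------------------
# Serialization: JSON interaction/config + CSV bead table

def save_model(directory, beads: BeadConfiguration, table: InteractionTable,
               metadata: dict | None = None) -> None:
    """Write ``model.json`` (bonded terms + pair rules) and ``beads.csv``.

    The round trip through :func:`load_model` is lossless: floats are
    serialized with shortest-repr precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "metadata": metadata or {},
        "bonds": table.bonds.tolist(),
        "bond_class": table.bond_class.tolist(),
        "bond_kF": table.bond_kF.tolist(),
        "bond_r0": table.bond_r0.tolist(),
        "bond_drmax": table.bond_drmax.tolist(),
        "angles": table.angles.tolist(),
        "angle_kB": table.angle_kB.tolist(),
        "angle_theta0": table.angle_theta0.tolist(),
        "pair_rules": [
            {"types": list(k), "kind": p.kind, "epsilon": p.epsilon,
             "sigma": p.sigma, "cutoff": p.cutoff}
            for k, p in sorted(table.pair_rules.items())
        ],
    }
    (directory / "model.json").write_text(json.dumps(doc, indent=1))
    df = pd.DataFrame({
        "id": np.arange(beads.n_beads),
        "cell_id": beads.cell_id,
        "type": beads.type_label,
        "x": beads.positions[:, 0],
        "y": beads.positions[:, 1],
        "vx": beads.velocities[:, 0],
        "vy": beads.velocities[:, 1],
    })
    # %.17g round-trips every float64 exactly
    df.to_csv(directory / "beads.csv", index=False, float_format="%.17g")


def load_model(directory):
    """Read a model written by :func:`save_model`."""
    directory = Path(directory)
    doc = json.loads((directory / "model.json").read_text())
    df = pd.read_csv(directory / "beads.csv", float_precision="round_trip")
    beads = BeadConfiguration(
        np.column_stack([df["x"], df["y"]]),
        np.column_stack([df["vx"], df["vy"]]),
        df["type"].to_numpy(),
        df["cell_id"].to_numpy(),
    )
    rules = {tuple(r["types"]): PairPotentialParams(
        r["epsilon"], r["sigma"], r["cutoff"], r["kind"])
        for r in doc["pair_rules"]}
    table = InteractionTable(
        np.asarray(doc["bonds"]), np.asarray(doc["bond_class"]),
        np.asarray(doc["bond_kF"]), np.asarray(doc["bond_r0"]),
        np.asarray(doc["bond_drmax"]), np.asarray(doc["angles"]),
        np.asarray(doc["angle_kB"]), np.asarray(doc["angle_theta0"]), rules)
    table.validate_indices(beads.n_beads)
    return beads, table
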