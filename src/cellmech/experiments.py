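"""Parameter sweeps and the colony cohesion pull assay.

Two sweep scenarios mirror the model's central comparison: vary the
filament-head/membrane attraction ``eps03`` (contractility) at fixed
membrane-membrane attraction ``eps00`` (adhesion), or the reverse.  Each
(level, seed) cell is probed with one virtual-AFM indentation; the tidy
result table carries a stiffness proxy (post-contact slope) and the force
read out mid-indentation.  ``compare_scenarios`` quantifies which knob
actually moves the force response.

The pull assay ramps a spring attached to the outward-facing membrane arc
of one colony cell until the cell detaches (centroid displaced by more
than one cell diameter); the pull-out force is the maximum spring force
seen before detachment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .md_engine import HarmonicTethers, SimulationConfig, run
from .model_builder import (TYPE_MEMBRANE, BeadConfiguration, GeometryConfig,
                            InteractionTable, SpringConstants, build_cell)
from .virtual_afm import (ForceDistanceCurve, TipConfig, force_at_travel,
                          reference_travel, run_indentation, stiffness_proxy)

__all__ = [
    "SweepSpec", "SweepResult", "ScenarioComparison", "PullSpec",
    "run_sweep", "compare_scenarios", "run_pull_assay",
    "VARY_EPS03", "VARY_EPS00",
]

VARY_EPS03 = "vary_eps03_fixed_eps00"
VARY_EPS00 = "vary_eps00_fixed_eps03"


#: baseline attraction energies; sweep levels default to {0.5, 1, 2} x these
BASELINE_EPS03 = 0.8
BASELINE_EPS00 = 1.0


@dataclass(frozen=True)
class SweepSpec:
    """One sweep scenario: which epsilon varies, its levels, and the seeds.

    ``values`` defaults to {0.5, 1, 2} times the scenario's baseline
    epsilon and ``fixed_value`` to the other knob's baseline.
    """

    scenario: str = VARY_EPS03
    values: tuple[float, ...] | None = None
    fixed_value: float | None = None
    seeds: tuple[int, ...] = (1, 2, 3)
    geometry: GeometryConfig | None = None
    springs: SpringConstants | None = None
    tip: TipConfig | None = None
    sim: SimulationConfig | None = None
    readout_frac: float = 0.65       # centre of the readout band, post-contact
    readout_halfwidth_frac: float = 0.25  # band half-width as post-contact frac

    def __post_init__(self):
        if self.scenario not in (VARY_EPS03, VARY_EPS00):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        base = BASELINE_EPS03 if self.scenario == VARY_EPS03 else BASELINE_EPS00
        other = BASELINE_EPS00 if self.scenario == VARY_EPS03 else BASELINE_EPS03
        if self.values is None:
            object.__setattr__(self, "values",
                               (0.5 * base, 1.0 * base, 2.0 * base))
        if self.fixed_value is None:
            object.__setattr__(self, "fixed_value", other)
        if len(self.values) < 3:
            raise ValueError("a sweep needs >= 3 levels")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("levels must be strictly increasing")
        if len(self.seeds) < 1:
            raise ValueError("at least one seed is required")

    @property
    def relative_span(self) -> float:
        return self.values[-1] / self.values[0]


@dataclass
class SweepResult:
    """Tidy per-run table plus the spec that produced it."""

    table: pd.DataFrame
    spec: SweepSpec
    curves: list[ForceDistanceCurve] = field(default_factory=list)

    def level_summary(self) -> pd.DataFrame:
        """Per-level mean and sd of the readouts, over seeds."""
        return (self.table.groupby("level")
                [["stiffness_proxy", "force_at_reference_travel"]]
                .agg(["mean", "std"]))

    def dynamic_range(self, column: str = "force_at_reference_travel") -> float:
        means = self.table.groupby("level")[column].mean()
        return float(means.max() - means.min())


def run_sweep(spec: SweepSpec) -> SweepResult:
    """One indentation per (level, seed), all else held fixed."""
    geometry = spec.geometry or GeometryConfig()
    tip = spec.tip or TipConfig()
    base_sim = spec.sim or SimulationConfig(damping=0.1, temperature=0.002,
                                            record_every=400)

    rows = []
    curves = []
    for level in spec.values:
        if spec.scenario == VARY_EPS03:
            eps00, eps03 = spec.fixed_value, level
        else:
            eps00, eps03 = level, spec.fixed_value
        for seed in spec.seeds:
            beads, table = build_cell(geometry, spec.springs,
                                      eps00=eps00, eps03=eps03)
            sim = SimulationConfig(
                dt=base_sim.dt, n_steps=base_sim.n_steps,
                damping=base_sim.damping, temperature=base_sim.temperature,
                seed=seed, neighbor_skin=base_sim.neighbor_skin,
                record_every=base_sim.record_every)
            row = {"scenario": spec.scenario, "level": level, "seed": seed,
                   "stiffness_proxy": np.nan,
                   "force_at_reference_travel": np.nan, "rupture": False}
            try:
                curve = run_indentation(beads, table, tip, sim)
                row["rupture"] = bool(curve.metadata.get("rupture", False))
                t_ref = reference_travel(curve, spec.readout_frac)
                post = float(curve.travel[-1]) - curve.contact_travel()
                row["force_at_reference_travel"] = force_at_travel(
                    curve, t_ref,
                    halfwidth=spec.readout_halfwidth_frac * post)
                row["stiffness_proxy"] = stiffness_proxy(curve)
                curves.append(curve)
            except (RuntimeError, ValueError) as err:
                row["error"] = str(err)  # failed runs recorded, not fatal
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), spec, curves)


@dataclass(frozen=True)
class ScenarioComparison:
    dynamic_range_a: float
    dynamic_range_b: float
    dominant: str  # "a", "b", or "tie"

    @property
    def ratio(self) -> float:
        return self.dynamic_range_a / self.dynamic_range_b


def compare_scenarios(a: SweepResult, b: SweepResult,
                      column: str = "force_at_reference_travel",
                      span_rtol: float = 1e-9) -> ScenarioComparison:
    """Compare the force-response dynamic range of two sweeps that cover
    the same multiplicative parameter span."""
    if not math.isclose(a.spec.relative_span, b.spec.relative_span,
                        rel_tol=span_rtol):
        raise ValueError(
            f"sweeps span different relative ranges: "
            f"{a.spec.relative_span} vs {b.spec.relative_span}")
    ra = a.dynamic_range(column)
    rb = b.dynamic_range(column)
    if math.isclose(ra, rb):
        dom = "tie"
    else:
        dom = "a" if ra > rb else "b"
    return ScenarioComparison(ra, rb, dom)


# ---------------------------------------------------------------------------
# Colony cohesion pull assay

@dataclass(frozen=True)
class PullSpec:
    """Pull a colony cell with a ramped spring until it detaches."""

    target: str = "edge"
    pull_spring: float = 20.0
    ramp_rate: float = 0.05
    detach_multiple: float = 1.0     # centroid displacement, in cell diameters
    max_travel_multiple: float = 2.0  # anchor travel budget, in cell diameters
    seeds: tuple[int, ...] = (1, 2, 3)
    arc_fraction: float = 0.25
    substrate_k: float = 5.0         # tether on non-target nuclei
    equilibrate_steps: int = 15000   # colony contraction settles before pulling
    sim: SimulationConfig | None = None

    def __post_init__(self):
        if self.target not in ("edge", "center"):
            raise ValueError("target must be 'edge' or 'center'")
        if self.ramp_rate <= 0 or self.pull_spring <= 0:
            raise ValueError("ramp_rate and pull_spring must be > 0")


class _PullDriver:
    """Tethers an arc of membrane beads to anchors ramped outward."""

    def __init__(self, indices, base_anchors, direction, rate, k_total,
                 t_start):
        self.indices = np.asarray(indices, dtype=np.int64)
        self.base = np.asarray(base_anchors, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.rate = rate
        self.k = k_total / len(indices)
        self.t_start = t_start
        self.max_force = 0.0

    def add_forces(self, t, pos, forces):
        s = self.rate * max(0.0, t - self.t_start)
        anchors = self.base + self.direction * s
        d = anchors - pos[self.indices]
        forces[self.indices] += self.k * d
        f_proj = self.k * float(np.sum(d @ self.direction))
        if f_proj > self.max_force:
            self.max_force = f_proj
        return 0.5 * self.k * float(np.sum(d * d))


def run_pull_assay(colony, spec: PullSpec,
                   geometry: GeometryConfig | None = None) -> pd.DataFrame:
    """Pull-out force per seed for the requested target cell.

    ``colony`` is the ``(beads, table, roles)`` triple from
    :func:`~cellmech.model_builder.build_colony`; ``geometry`` identifies
    the per-cell bead layout (defaults to the compact colony geometry).
    Non-target cells have their nuclear rings softly tethered to the
    substrate so the colony cannot drift as a rigid body.
    """
    beads0, table, roles = colony
    geometry = geometry or GeometryConfig.compact()
    sim0 = spec.sim or SimulationConfig(damping=0.1, temperature=0.002,
                                        record_every=200)
    targets = [i for i, r in enumerate(roles) if r == spec.target]
    if not targets:
        raise ValueError(f"colony has no {spec.target!r} cell")
    target = targets[0]

    D = 2 * geometry.cell_radius
    nm, nn = geometry.n_membrane_beads, geometry.n_nuclear_beads
    centers = np.array([beads0.positions[beads0.cell_id == c].mean(axis=0)
                        for c in range(len(roles))])
    colony_centroid = centers.mean(axis=0)
    direction = centers[target] - colony_centroid
    if np.linalg.norm(direction) < 1e-9:
        direction = np.array([1.0, 0.0])  # center cell: pull along +x
    direction = direction / np.linalg.norm(direction)

    target_mask = beads0.cell_id == target
    target_idx = np.nonzero(target_mask)[0]
    mem_idx = target_idx[:nm]
    u = beads0.positions[mem_idx] - centers[target]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    arc = mem_idx[u @ direction >= math.cos(math.pi * spec.arc_fraction)]

    # substrate tethers: nuclear rings of all non-target cells
    sub_idx = np.concatenate([
        np.nonzero(beads0.cell_id == c)[0][nm:nm + nn]
        for c in range(len(roles)) if c != target])

    rows = []
    for seed in spec.seeds:
        state = beads0.copy()
        sim_eq = SimulationConfig(dt=sim0.dt, n_steps=spec.equilibrate_steps,
                                  damping=sim0.damping,
                                  temperature=sim0.temperature, seed=seed,
                                  neighbor_skin=sim0.neighbor_skin,
                                  record_every=spec.equilibrate_steps)
        subs = HarmonicTethers(sub_idx, beads0.positions[sub_idx],
                               spec.substrate_k)
        eq = run(state, table, sim_eq, external=[subs])
        state = eq.final

        t_eq = 0.0
        driver = _PullDriver(arc, state.positions[arc], direction,
                             spec.ramp_rate, spec.pull_spring, t_eq)
        max_travel = spec.max_travel_multiple * D
        n_steps = math.ceil(max_travel / (spec.ramp_rate * sim0.dt))
        sim_pull = SimulationConfig(dt=sim0.dt, n_steps=n_steps,
                                    damping=sim0.damping,
                                    temperature=sim0.temperature,
                                    seed=seed + 7919,
                                    neighbor_skin=sim0.neighbor_skin,
                                    record_every=sim0.record_every)
        start_centroid = state.positions[target_idx].mean(axis=0)
        detach_at = spec.detach_multiple * D

        def detached(s, integ):
            c = integ.state.positions[target_idx].mean(axis=0)
            return float(np.linalg.norm(c - start_centroid)) > detach_at

        censored = False
        try:
            traj = run(state, table, sim_pull, external=[driver, subs],
                       until=detached)
            final_c = traj.final.positions[target_idx].mean(axis=0)
            censored = float(np.linalg.norm(final_c - start_centroid)) <= detach_at
        except Exception as err:  # per-run failure recorded, not fatal
            rows.append({"target": spec.target, "seed": seed,
                         "pullout_force": np.nan, "censored": True,
                         "error": str(err)})
            continue
        rows.append({"target": spec.target, "seed": seed,
                     "pullout_force": driver.max_force, "censored": censored})
    return pd.DataFrame(rows)
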