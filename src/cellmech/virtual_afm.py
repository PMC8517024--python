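"""Virtual AFM indentation and Hertz-Sneddon elastography.

The tip is a single type-7 bead coupled to a moving apparatus anchor by two
orthogonal springs (kx, ky).  The anchor advances toward the cell at
constant velocity; the restoring force reported at each sample is the
spring deformation projected on the approach direction, averaged over the
recording interval, with the constant viscous-drag offset of the free tip
subtracted so the pre-contact baseline is exactly zero at T = 0.

The same module hosts the contact-mechanics fit used for experimental
force-indentation curves: F = C * E/(1 - nu^2) * tan(alpha) * delta^2 with
C = 2/pi for a conical (Sneddon) indenter or C = 0.7453 for a pyramidal
one, fitted jointly for the modulus E and the contact point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .md_engine import (HarmonicTethers, SimulationConfig,
                        SimulationUnstableError, run)
from .model_builder import (TYPE_FILAMENT, TYPE_HEAD, TYPE_MEMBRANE, TYPE_TIP,
                            BeadConfiguration, InteractionTable)
from .potentials import PairPotentialParams

__all__ = [
    "TipConfig", "ForceDistanceCurve", "HertzFit", "HertzFitError",
    "run_indentation", "stiffness_proxy", "force_at_travel",
    "reference_travel", "fit_hertz", "filter_moduli", "ModulusFilter",
    "HERTZ_PREFACTOR",
]

HERTZ_PREFACTOR = {"cone": 2.0 / math.pi, "pyramid": 0.7453}


@dataclass(frozen=True)
class TipConfig:
    """Virtual tip: spring constants, interaction radius and approach."""

    kx: float = 50.0
    ky: float = 50.0
    radius: float = 12.0
    velocity: float = 0.05
    approach_direction: tuple[float, float] = (-1.0, 0.0)
    start_gap: float = 2.0
    max_travel: float = 12.0
    damping: float = 1.0       # apparatus drag on the tip bead
    rampup_travel: float = 0.5  # soft-start distance to reach full speed

    def __post_init__(self):
        if self.kx <= 0 or self.ky <= 0:
            raise ValueError("tip spring constants must be > 0")
        if self.velocity <= 0 or self.radius <= 0:
            raise ValueError("velocity and radius must be > 0")
        n = math.hypot(*self.approach_direction)
        if n == 0:
            raise ValueError("approach_direction must be a nonzero vector")
        object.__setattr__(self, "approach_direction",
                           (self.approach_direction[0] / n,
                            self.approach_direction[1] / n))


@dataclass
class ForceDistanceCurve:
    """Tip travel vs restoring force, with run provenance in metadata."""

    travel: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.travel = np.asarray(self.travel, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if np.any(np.diff(self.travel) < 0):
            raise ValueError("travel must be non-decreasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")

    def contact_index(self, threshold_frac: float = 0.01) -> int:
        """First of two consecutive samples above threshold_frac * max force
        (two samples are required so isolated blips do not register)."""
        thr = threshold_frac * float(np.max(self.force))
        above = self.force > thr
        idx = np.nonzero(above[:-1] & above[1:])[0]
        if idx.size == 0:
            raise ValueError("no contact detected in curve")
        return int(idx[0])

    def contact_travel(self, threshold_frac: float = 0.01) -> float:
        return float(self.travel[self.contact_index(threshold_frac)])

    def to_csv(self, path) -> None:
        path = Path(path)
        pd.DataFrame({"travel": self.travel, "force": self.force}).to_csv(
            path, index=False)
        meta = {k: v for k, v in self.metadata.items()
                if isinstance(v, (int, float, str, bool, list, tuple, type(None)))}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "ForceDistanceCurve":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(df["travel"].to_numpy(), df["force"].to_numpy(), meta)


class _TipDriver:
    """Anchor springs on the tip bead with a soft-started constant-velocity
    ramp.  The projected spring force, minus the instantaneous apparatus
    drag gamma*v(t), is accumulated between recording samples so each
    curve point is a window average."""

    def __init__(self, tip_index, anchor0, direction, velocity, kx, ky,
                 t_start: float, rampup_travel: float, drag_gamma: float):
        self.tip_index = tip_index
        self.anchor0 = np.asarray(anchor0, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.velocity = velocity
        self.k = np.array([kx, ky])
        self.t_start = t_start
        self.t_ramp = 2.0 * rampup_travel / velocity if rampup_travel > 0 else 0.0
        self.drag_gamma = drag_gamma
        self._acc = 0.0
        self._n = 0

    def _speed(self, t: float) -> float:
        tau = t - self.t_start
        if tau <= 0:
            return 0.0
        if tau < self.t_ramp:
            return self.velocity * tau / self.t_ramp
        return self.velocity

    def travel(self, t: float) -> float:
        tau = t - self.t_start
        if tau <= 0:
            return 0.0
        if tau < self.t_ramp:
            return 0.5 * self.velocity * tau * tau / self.t_ramp
        return self.velocity * (tau - 0.5 * self.t_ramp)

    def anchor(self, t: float) -> np.ndarray:
        return self.anchor0 + self.direction * self.travel(t)

    def add_forces(self, t, pos, forces):
        d = self.anchor(t) - pos[self.tip_index]
        f = self.k * d
        forces[self.tip_index] += f
        self._acc += float(np.dot(f, self.direction)) \
            - self.drag_gamma * self._speed(t)
        self._n += 1
        return 0.5 * float(np.sum(self.k * d * d))

    def mean_force(self) -> float:
        if self._n == 0:
            return 0.0
        m = self._acc / self._n
        self._acc = 0.0
        self._n = 0
        return m


def _with_tip_rules(table: InteractionTable, sigma07: float) -> InteractionTable:
    rules = dict(table.pair_rules)
    for ty in (TYPE_MEMBRANE, TYPE_FILAMENT, TYPE_HEAD):
        rules[(ty, TYPE_TIP)] = PairPotentialParams(1.0, sigma07, kind="wca")
    return InteractionTable(table.bonds, table.bond_class, table.bond_kF,
                            table.bond_r0, table.bond_drmax, table.angles,
                            table.angle_kB, table.angle_theta0, rules)


def run_indentation(beads: BeadConfiguration, table: InteractionTable,
                    tip: TipConfig | None = None,
                    sim: SimulationConfig | None = None,
                    equilibrate_steps: int = 20000,
                    pin_fraction: float = 0.35,
                    pin_k: float = 20.0) -> ForceDistanceCurve:
    """Indent a (single-cell) model with the virtual tip.

    The membrane arc on the far side of the cell (fraction ``pin_fraction``
    of the ring, opposite the tip) is tethered to its initial position,
    standing in for substrate adhesion; without it the whole cell would
    simply translate.  The system equilibrates with a stationary anchor
    before the approach starts.  On membrane rupture (FENE overextension)
    the curve recorded so far is returned, flagged in the metadata.
    """
    tip = tip or TipConfig()
    sim = sim or SimulationConfig(damping=0.1, temperature=0.002,
                                  record_every=400)

    mem = beads.type_label == TYPE_MEMBRANE
    mem_indices = np.nonzero(mem)[0]
    center = beads.positions[mem].mean(axis=0)
    d = np.asarray(tip.approach_direction)
    sigma00 = table.rule(TYPE_MEMBRANE, TYPE_MEMBRANE).sigma
    sigma07 = tip.radius + 0.5 * sigma00

    # pin the membrane arc opposite the contact side (substrate adhesion)
    u = (beads.positions[mem] - center)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    arc = mem_indices[u @ d >= math.cos(math.pi * pin_fraction)]
    pins = HarmonicTethers(arc, beads.positions[arc], pin_k)

    # equilibrate the cell alone first: contractility (eps03) can pull the
    # whole cortex inward, so the tip is placed relative to the relaxed,
    # possibly contracted surface
    sim_eq = SimulationConfig(dt=sim.dt, n_steps=equilibrate_steps,
                              damping=sim.damping,
                              temperature=sim.temperature, seed=sim.seed,
                              neighbor_skin=sim.neighbor_skin,
                              record_every=equilibrate_steps)
    relaxed = run(beads, table, sim_eq, external=[pins]).final

    # membrane extent along the approach axis, on the tip's side
    extent = float(np.max((relaxed.positions[mem] - center) @ (-d)))
    tip_pos = center - d * (extent + sigma07 + tip.start_gap)
    state = BeadConfiguration(
        np.vstack([relaxed.positions, tip_pos]),
        np.vstack([relaxed.velocities, np.zeros(2)]),
        np.concatenate([relaxed.type_label, [TYPE_TIP]]),
        np.concatenate([relaxed.cell_id, [relaxed.cell_id.max() + 1]]),
    )
    tip_index = state.n_beads - 1
    full_table = _with_tip_rules(table, sigma07)

    driver = _TipDriver(tip_index, tip_pos, d, tip.velocity,
                        tip.kx, tip.ky, t_start=0.0,
                        rampup_travel=tip.rampup_travel,
                        drag_gamma=tip.damping)
    n_travel = math.ceil((tip.max_travel + tip.rampup_travel)
                         / (tip.velocity * sim.dt))
    sim_run = SimulationConfig(dt=sim.dt, n_steps=n_travel,
                               damping=sim.damping,
                               temperature=sim.temperature,
                               seed=sim.seed + 104729,
                               neighbor_skin=sim.neighbor_skin,
                               record_every=sim.record_every)
    gamma = np.full(state.n_beads, sim.damping)
    gamma[tip_index] = tip.damping
    thermostat = np.ones(state.n_beads)
    thermostat[tip_index] = 0.0  # the tip apparatus is damped but athermal

    travels, forces = [], []

    def on_record(s, integ):
        travels.append(driver.travel(integ.t))
        forces.append(driver.mean_force())

    meta = {"eps00": table.eps00, "eps03": table.eps03, "seed": sim.seed,
            "velocity": tip.velocity, "max_travel": tip.max_travel,
            "start_gap": tip.start_gap, "rupture": False}
    try:
        run(state, full_table, sim_run, external=[driver, pins],
            per_bead_damping=gamma, thermostat_mask=thermostat,
            on_record=on_record)
    except SimulationUnstableError as err:
        meta["rupture"] = True
        meta["rupture_step"] = err.step_index
    if len(travels) < 2:
        raise RuntimeError("indentation recorded fewer than 2 samples")
    return ForceDistanceCurve(np.asarray(travels), np.asarray(forces), meta)


def stiffness_proxy(curve: ForceDistanceCurve,
                    window: tuple[float, float] | None = None,
                    contact_frac: float = 0.01) -> float:
    """Least-squares slope of force vs travel over a post-contact window.

    ``window`` is an absolute travel interval; by default the middle
    60 percent of the post-contact range is used.  A window that starts
    before the detected contact point is an error.
    """
    c = curve.contact_travel(contact_frac)
    tmax = float(curve.travel[-1])
    if window is None:
        window = (c + 0.2 * (tmax - c), c + 0.8 * (tmax - c))
    t0, t1 = window
    if t0 < c:
        raise ValueError(f"window start {t0} precedes contact at {c}")
    sel = (curve.travel >= t0) & (curve.travel <= t1)
    if np.count_nonzero(sel) < 2:
        raise ValueError("window contains fewer than 2 samples")
    slope, _ = np.polyfit(curve.travel[sel], curve.force[sel], 1)
    return float(slope)


def force_at_travel(curve: ForceDistanceCurve, travel: float,
                    halfwidth: float = 1.0) -> float:
    """Force at a travel point, averaged over +-halfwidth around it to
    suppress stick-slip jitter (halfwidth=0 gives plain interpolation)."""
    if halfwidth <= 0:
        return float(np.interp(travel, curve.travel, curve.force))
    sel = (curve.travel >= travel - halfwidth) & \
        (curve.travel <= travel + halfwidth)
    if not np.any(sel):
        return float(np.interp(travel, curve.travel, curve.force))
    return float(curve.force[sel].mean())


def reference_travel(curve: ForceDistanceCurve, frac: float = 0.5,
                     contact_frac: float = 0.01) -> float:
    """Mid-indentation readout point: contact + frac * post-contact range."""
    c = curve.contact_travel(contact_frac)
    return c + frac * (float(curve.travel[-1]) - c)


# ---------------------------------------------------------------------------
# Hertz / Sneddon fitting (physical units: travel in um, force in nN -> kPa)

class HertzFitError(RuntimeError):
    """Raised when the contact-model fit fails to converge."""


@dataclass(frozen=True)
class HertzFit:
    half_angle: float      # degrees
    poisson: float
    modulus: float         # same pressure unit as the input curve implies
    contact_point: float
    model_form: str
    residual: float = 0.0

    def __post_init__(self):
        if not (0 < self.poisson <= 0.5):
            raise ValueError("poisson must lie in (0, 0.5]")
        if self.modulus <= 0:
            raise ValueError("modulus must be > 0")


def fit_hertz(curve: ForceDistanceCurve, half_angle: float = 9.0,
              poisson: float = 0.45, model_form: str = "cone",
              contact_frac: float = 0.01) -> HertzFit:
    """Fit F(delta) = C * E/(1-nu^2) * tan(alpha) * delta^2 jointly for the
    modulus E and the contact point.

    With travel in micrometres and force in nanonewtons the returned
    modulus is in kilopascals.  Requires >= 20 post-contact samples.
    """
    if model_form not in HERTZ_PREFACTOR:
        raise ValueError(f"model_form must be one of {sorted(HERTZ_PREFACTOR)}")
    pref = HERTZ_PREFACTOR[model_form] * math.tan(math.radians(half_angle)) \
        / (1.0 - poisson ** 2)
    t = curve.travel
    f = curve.force
    ci = curve.contact_index(contact_frac)
    if t.size - ci < 20:
        raise ValueError("need >= 20 post-contact samples to fit")
    c0 = t[ci]
    delta_last = max(t[-1] - c0, np.finfo(float).eps)
    a0 = max(f[-1], np.finfo(float).tiny) / delta_last ** 2

    def model(params):
        a, c = params
        delta = np.maximum(t - c, 0.0)
        return a * delta * delta - f

    res = least_squares(model, x0=[a0, c0],
                        bounds=([0.0, t[0] - delta_last], [np.inf, t[-1]]))
    if not res.success or res.x[0] <= 0:
        raise HertzFitError(
            f"contact-model fit failed: {res.message}; "
            f"residual norm {np.linalg.norm(res.fun):.3g}")
    modulus = res.x[0] / pref
    return HertzFit(half_angle, poisson, float(modulus), float(res.x[1]),
                    model_form, float(np.sqrt(np.mean(res.fun ** 2))))


@dataclass(frozen=True)
class ModulusFilter:
    kept: tuple
    n_removed: int


def filter_moduli(values, max_modulus: float = 20.0) -> ModulusFilter:
    """Drop moduli above ``max_modulus`` (substrate-effect artefacts),
    preserving order and reporting how many were removed."""
    vals = [float(v) for v in values]
    if any(not math.isfinite(v) or v <= 0 for v in vals):
        raise ValueError("moduli must be finite and positive")
    kept = tuple(v for v in vals if v <= max_modulus)
    return ModulusFilter(kept, len(vals) - len(kept))
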