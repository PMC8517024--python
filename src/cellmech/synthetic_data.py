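"""Seeded generators with known ground truth for every pipeline input.

Each generator returns ``(data, truth)`` where ``truth`` is a plain dict
holding the planted parameters (the values an analyzer should recover),
and is deterministic under a fixed seed.  ``save_fixture`` serializes any
generated fixture to the same on-disk formats the analyzers read
(CSV/TIFF + JSON sidecar carrying the spec and truth).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import ConvexHull
from scipy.special import ellipe
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .morphometrics import HeightProfile
from .virtual_afm import HERTZ_PREFACTOR, ForceDistanceCurve

__all__ = [
    "FixtureSpec", "make_sneddon_curve", "make_shape_mask", "make_fa_scene",
    "make_fret_stack", "make_point_pattern", "make_height_profile",
    "save_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Provenance record stored next to every generated fixture."""

    kind: str
    parameters: dict = field(default_factory=dict)
    noise_model: str = "none"
    seed: int = 0


def _apply_noise(values: np.ndarray, noise, seed: int, scale: float):
    """noise = None | ('gaussian', sigma) | ('multiplicative', sigma);
    gaussian sigma is absolute in units of ``scale``."""
    if noise is None:
        return values, "none"
    kind, sigma = noise
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        return values + rng.normal(0.0, sigma * scale, values.shape), \
            f"gaussian({sigma})"
    if kind == "multiplicative":
        return values * (1.0 + rng.normal(0.0, sigma, values.shape)), \
            f"multiplicative({sigma})"
    raise ValueError(f"unknown noise model {kind!r}")


def make_sneddon_curve(E: float, half_angle: float = 9.0,
                       poisson: float = 0.45, contact_point: float = 0.5,
                       noise=None, seed: int = 0, model_form: str = "cone",
                       max_travel: float = 2.5, n_samples: int = 250):
    """Forward-model force-indentation curve with known modulus.

    Travel is in micrometres and force in nanonewtons, so ``E`` is in
    kilopascals: F = C * E/(1-nu^2) * tan(alpha) * delta^2 past contact,
    zero before.  Returns ``(ForceDistanceCurve, truth)``.
    """
    if E < 0:
        raise ValueError("modulus must be >= 0")
    travel = np.linspace(0.0, max_travel, n_samples)
    delta = np.maximum(travel - contact_point, 0.0)
    pref = HERTZ_PREFACTOR[model_form] * math.tan(math.radians(half_angle)) \
        / (1.0 - poisson ** 2)
    force = pref * E * delta ** 2
    force, noise_tag = _apply_noise(force, noise, seed, scale=max(force.max(), 1e-12))
    truth = {"E": E, "half_angle": half_angle, "poisson": poisson,
             "contact_point": contact_point, "model_form": model_form}
    spec = FixtureSpec("sneddon_curve", truth, noise_tag, seed)
    curve = ForceDistanceCurve(travel, force,
                               {"fixture": asdict(spec), **truth})
    return curve, truth


def _ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter 4 a E(e^2) via the complete elliptic integral."""
    a, b = max(a, b), min(a, b)
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(m))


def make_shape_mask(kind: str, parameters: dict, margin: int = 10):
    """Rasterized shape plus closed-form shape-index truths.

    Kinds: ``disc`` (radius), ``ellipse`` (a, b semi-axes), ``rectangle``
    (length, width), ``polygon`` (vertices, row/col pairs).  Truth carries
    the analytic area, perimeter, circularity and solidity.
    """
    if kind == "disc":
        r = int(parameters["radius"])
        side = 2 * (r + margin) + 1
        mask = np.zeros((side, side), dtype=bool)
        rr, cc = draw_disk((side // 2, side // 2), r + 0.5, shape=mask.shape)
        mask[rr, cc] = True
        area, perim = math.pi * r ** 2, 2 * math.pi * r
        sol = 1.0
    elif kind == "ellipse":
        a, b = float(parameters["a"]), float(parameters["b"])
        shape = (2 * (int(b) + margin) + 1, 2 * (int(a) + margin) + 1)
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_ellipse(shape[0] // 2, shape[1] // 2, b, a, shape=shape)
        mask[rr, cc] = True
        area, perim = math.pi * a * b, _ellipse_perimeter(a, b)
        sol = 1.0
    elif kind == "rectangle":
        L, W = int(parameters["length"]), int(parameters["width"])
        mask = np.zeros((W + 2 * margin, L + 2 * margin), dtype=bool)
        mask[margin:margin + W, margin:margin + L] = True
        area, perim = float(L * W), 2.0 * (L + W)
        sol = 1.0
    elif kind == "polygon":
        verts = np.asarray(parameters["vertices"], dtype=float)
        shape = (int(verts[:, 0].max()) + margin,
                 int(verts[:, 1].max()) + margin)
        mask = np.zeros(shape, dtype=bool)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
        mask[rr, cc] = True
        x, y = verts[:, 1], verts[:, 0]
        area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) -
                               np.dot(y, np.roll(x, -1))))
        perim = float(np.sum(np.linalg.norm(
            verts - np.roll(verts, -1, axis=0), axis=1)))
        sol = area / float(ConvexHull(verts).volume)
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    truth = {"area": area, "perimeter": perim,
             "circularity": 4.0 * math.pi * area / perim ** 2,
             "solidity": sol}
    return mask, truth


def make_fa_scene(n_nuclei: int = 3, fas_per_cell: int = 4,
                  fa_axes: tuple[float, float] = (6.0, 3.0),
                  shape: tuple[int, int] = (256, 256),
                  background: float = 10.0, fa_intensity: float = 200.0,
                  actin_intensity: float = 100.0,
                  n_outside_fas: int = 0,
                  noise=None, seed: int = 0):
    """Synthetic TIRF scene: bright elliptical focal adhesions planted in an
    actin-positive region above labelled nuclei.

    ``n_outside_fas`` additionally plants FAs outside the actin footprint
    (they must be excluded by the mask AND).  Returns
    ``(paxillin, actin, nuclei_labels, truth)``.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    actin = np.full(shape, background, dtype=float)
    # actin-positive footprint: central rectangle with a margin for outsiders
    m_h, m_w = h // 6, w // 6
    actin[m_h:h - m_h, m_w:w - m_w] += actin_intensity
    actin_region = (slice(m_h, h - m_h), slice(m_w, w - m_w))

    nuclei = np.zeros(shape, dtype=np.int32)
    nuc_r = min(h, w) // 16
    xs = np.linspace(m_w + 2 * nuc_r, w - m_w - 2 * nuc_r, max(n_nuclei, 1))
    for i in range(n_nuclei):
        rr, cc = draw_disk((h // 2, xs[i]), nuc_r, shape=shape)
        nuclei[rr, cc] = i + 1

    pax = np.full(shape, background, dtype=float)
    n_inside = n_nuclei * fas_per_cell
    # grid placement inside the actin region, away from its border
    rows = np.linspace(m_h + 3 * fa_axes[0], h - m_h - 3 * fa_axes[0],
                       max(2, int(math.ceil(math.sqrt(n_inside)))))
    cols = np.linspace(m_w + 3 * fa_axes[0], w - m_w - 3 * fa_axes[0],
                       max(2, int(math.ceil(n_inside / max(2, len(rows)))) + 1))
    grid = [(r, c) for r in rows for c in cols]
    if len(grid) < n_inside:
        raise ValueError("scene too small for the requested FA count")
    centers = []
    for i in range(n_inside):
        r, c = grid[i]
        ang = rng.uniform(0, math.pi)
        rr, cc = draw_ellipse(r, c, fa_axes[1], fa_axes[0],
                              shape=shape, rotation=ang)
        pax[rr, cc] = fa_intensity
        centers.append((float(r), float(c)))
    outside_centers = []
    for i in range(n_outside_fas):
        r = m_h // 2  # above the actin footprint
        c = m_w + (i + 1) * (w - 2 * m_w) / (n_outside_fas + 1)
        rr, cc = draw_ellipse(r, c, fa_axes[1], fa_axes[0], shape=shape)
        pax[rr, cc] = fa_intensity
        outside_centers.append((float(r), float(c)))

    pax, noise_tag = _apply_noise(pax, noise, seed, scale=fa_intensity)
    actin, _ = _apply_noise(actin, noise, seed + 1, scale=actin_intensity)
    truth = {"n_nuclei": n_nuclei, "n_fas_inside": n_inside,
             "n_fas_outside": n_outside_fas,
             "fas_per_cell": n_inside / n_nuclei,
             "fa_area": math.pi * fa_axes[0] * fa_axes[1],
             "fa_centers": centers, "outside_centers": outside_centers,
             "noise": noise_tag}
    return pax, actin, nuclei, truth


def make_fret_stack(true_index_map, alpha: float, beta: float,
                    donor_map, acceptor_map=None, noise=None, seed: int = 0):
    """Three-channel FRET fixture obeying the bleed-through forward model.

    FRET channel = true_index * donor + alpha * donor + beta * acceptor,
    so the ratiometric correction recovers ``true_index_map`` exactly in
    the noise-free case.  Returns ``(donor, fret, acceptor, truth)``.
    """
    R = np.asarray(true_index_map, dtype=float)
    donor = np.asarray(donor_map, dtype=float)
    acceptor = donor.copy() if acceptor_map is None \
        else np.asarray(acceptor_map, dtype=float)
    if not (R.shape == donor.shape == acceptor.shape):
        raise ValueError("index, donor and acceptor maps must share a shape")
    fret = R * donor + alpha * donor + beta * acceptor
    scale = max(float(fret.max()), 1e-12)
    fret, noise_tag = _apply_noise(fret, noise, seed, scale)
    truth = {"alpha": alpha, "beta": beta, "noise": noise_tag,
             "mean_index": float(R.mean())}
    return donor, fret, acceptor, truth


def make_point_pattern(kind: str = "lattice", n: int = 36,
                       spacing: float = 1.0, intensity: float = 1.0,
                       n_clusters: int = 4, cluster_sigma: float = 0.05,
                       seed: int = 0):
    """2D centroid sets with known neighbour-distance structure.

    ``lattice``: ceil(sqrt(n))^2 grid points at ``spacing`` (interior
    points have 4 neighbours at spacing and 4 at spacing*sqrt(2));
    ``poisson``: homogeneous Poisson process of the given intensity in a
    window sized to expect ``n`` points; ``clustered``: Gaussian clusters.
    Coincident points are rejected as invalid.
    """
    rng = np.random.default_rng(seed)
    if kind == "lattice":
        m = int(math.ceil(math.sqrt(n)))
        xx, yy = np.meshgrid(np.arange(m), np.arange(m))
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float) * spacing
        truth = {"kind": kind, "m": m, "spacing": spacing,
                 "interior_distances": [spacing, spacing * math.sqrt(2)]}
    elif kind == "poisson":
        side = math.sqrt(n / intensity)
        count = rng.poisson(intensity * side * side)
        pts = rng.uniform(0, side, size=(count, 2))
        truth = {"kind": kind, "intensity": intensity, "window": side,
                 "expected_mean_nn": 1.0 / (2.0 * math.sqrt(intensity))}
    elif kind == "clustered":
        parents = rng.uniform(0, 1, size=(n_clusters, 2))
        reps = int(math.ceil(n / n_clusters))
        pts = (parents[np.repeat(np.arange(n_clusters), reps)][:n]
               + rng.normal(0, cluster_sigma, size=(n, 2)))
        truth = {"kind": kind, "n_clusters": n_clusters,
                 "cluster_sigma": cluster_sigma}
    else:
        raise ValueError(f"unknown point pattern kind {kind!r}")
    if pts.shape[0] > 1:
        rounded = np.unique(pts.round(decimals=12), axis=0)
        if rounded.shape[0] != pts.shape[0]:
            raise ValueError("generated pattern contains duplicate points")
    return pts, truth


def make_height_profile(peak_prominences=(20.0,), spacing: int = 20,
                        peak_width: int = 5, baseline: float = 0.0,
                        noise=None, seed: int = 0,
                        threshold: float = 15.0):
    """Flat baseline with triangular peaks of the given prominences (nm).

    Returns ``(HeightProfile, truth)`` where the truth records how many
    planted prominences strictly exceed ``threshold``.
    """
    proms = list(peak_prominences)
    n = spacing * (len(proms) + 1) + 1
    y = np.full(n, baseline, dtype=float)
    half = peak_width // 2
    for i, p in enumerate(proms):
        c = spacing * (i + 1)
        for o in range(-half, half + 1):
            if 0 <= c + o < n:
                y[c + o] = max(y[c + o],
                               baseline + p * (1.0 - abs(o) / (half + 1)))
    y, noise_tag = _apply_noise(y, noise, seed,
                                scale=max(proms, default=1.0))
    truth = {"prominences": proms, "threshold": threshold,
             "count_above_threshold": int(sum(p > threshold for p in proms)),
             "noise": noise_tag}
    return HeightProfile(y), truth


# ---------------------------------------------------------------------------

def save_fixture(directory, name: str, data, truth: dict,
                 spec: FixtureSpec | None = None) -> None:
    """Write a fixture in the format its analyzer reads, plus a JSON
    sidecar with the ground truth (and FixtureSpec when given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {"truth": _jsonable(truth)}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
    if isinstance(data, ForceDistanceCurve):
        data.to_csv(directory / f"{name}.csv")
    elif isinstance(data, HeightProfile):
        pd.DataFrame({"height": data.samples}).to_csv(
            directory / f"{name}.csv", index=False)
    elif isinstance(data, np.ndarray) and data.ndim == 2 and data.shape[1] == 2 \
            and data.dtype == float:
        pd.DataFrame(data, columns=["x", "y"]).to_csv(
            directory / f"{name}.csv", index=False)
    elif isinstance(data, np.ndarray):
        tifffile.imwrite(directory / f"{name}.tif",
                         np.asarray(data, dtype=np.float32))
    elif isinstance(data, (tuple, list)):
        for i, channel in enumerate(data):
            tifffile.imwrite(directory / f"{name}_{i}.tif",
                             np.asarray(channel, dtype=np.float32))
    else:
        raise TypeError(f"don't know how to serialize {type(data)!r}")
    (directory / f"{name}.truth.json").write_text(json.dumps(sidecar, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
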