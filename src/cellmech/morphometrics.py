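"""Image and profile quantification for cell mechanics experiments.

Implements the measurement battery applied to microscopy data: shape
indices (circularity 4*pi*area/perimeter^2 and solidity area/hull-area),
the pooled k-nearest-neighbour cell-distance density, membrane-ruffle
counting on AFM height profiles, the focal-adhesion segmentation pipeline
(rolling-ball background, moments/mean auto-thresholds, mask AND),
ratiometric and single-chain FRET indices, and the nuclear-vs-cytoplasmic
intensity classifiers.

Images are plain 2D numpy arrays: label images hold non-negative integers
with 0 as background; intensity images hold finite non-negative values.
The default perimeter estimator measures the smoothed sub-pixel
marching-squares contour (see :func:`region_perimeter`), accurate to well
under one percent for smooth shapes - naive boundary-pixel counting would
make a digitized circle's circularity land far from 1.  The 4-direction
Crofton estimator is available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import convex_hull_image
from skimage.restoration import rolling_ball

__all__ = [
    "HeightProfile", "FretParams", "FASegmentation",
    "circularity", "solidity", "region_perimeter", "nn_distance_density",
    "count_ruffles",
    "threshold_moments", "threshold_mean", "segment_focal_adhesions",
    "fret_index_ratiometric", "fret_index_singlechain",
    "nuclear_cytoplasmic_class", "boundary_cytoplasm_ratio",
]


@dataclass
class HeightProfile:
    """Surface height samples (probe deflection, nm) along a scan line."""

    samples: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 3:
            raise ValueError("a height profile needs >= 3 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("height samples must be finite")


@dataclass(frozen=True)
class FretParams:
    """Spectral bleed-through coefficients: alpha (donor), beta (acceptor)."""

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("bleed-through coefficients must be >= 0")


def _as_region(region) -> np.ndarray:
    mask = np.asarray(region).astype(bool)
    if mask.ndim != 2:
        raise ValueError("region must be a 2D mask")
    if not mask.any():
        raise ValueError("region is empty")
    return mask


def region_perimeter(mask: np.ndarray, estimator: str = "contour",
                     smoothing_window: int = 7) -> float:
    """Perimeter of a binary region.

    ``contour`` (default) measures the length of the sub-pixel
    marching-squares boundary after a short moving-average smoothing that
    removes the staircase bias; it is accurate to well under 1 percent for
    smooth shapes at >= 50 px scale.  ``crofton`` is the 4-direction
    Crofton estimator (exactly invariant under 90-degree rotations, but
    biased for elongated axis-aligned shapes).
    """
    if estimator == "crofton":
        return float(perimeter_crofton(mask, directions=4))
    if estimator != "contour":
        raise ValueError("estimator must be 'contour' or 'crofton'")
    from scipy.ndimage import uniform_filter1d
    from skimage.measure import find_contours
    total = 0.0
    for c in find_contours(mask.astype(float), 0.5):
        closed = bool(np.allclose(c[0], c[-1]))
        pts = c[:-1] if closed else c
        if len(pts) > smoothing_window:
            mode = "wrap" if closed else "nearest"
            pts = np.column_stack([
                uniform_filter1d(pts[:, i], smoothing_window, mode=mode)
                for i in (0, 1)])
        if closed:
            pts = np.vstack([pts, pts[:1]])
        total += float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return total


def circularity(region, perimeter_estimator: str = "contour") -> float:
    """4*pi*area/perimeter^2 of a single connected region.

    1.0 indicates a perfect circle; values approach 0 for increasingly
    elongated shapes.  Slightly above 1 is possible on coarse rasters.
    """
    mask = _as_region(region)
    if sk_label(mask, connectivity=2).max() != 1:
        raise ValueError("region must be a single connected component")
    area = float(mask.sum())
    perim = region_perimeter(mask, perimeter_estimator)
    return 4.0 * math.pi * area / perim ** 2


def solidity(region) -> float:
    """Region area divided by its convex-hull area; 1 for convex shapes."""
    mask = _as_region(region)
    hull = convex_hull_image(mask)
    return float(mask.sum()) / float(hull.sum())


def nn_distance_density(centroids, k: int = 5, bins="auto",
                        return_kde: bool = False):
    """Pooled k-nearest-neighbour distance density of a point set.

    For every point the distances to its ``k`` nearest neighbours are
    pooled; the histogram is normalized to unit area.  Returns
    ``(density, bin_edges, pooled_distances)`` and, with
    ``return_kde=True``, a ``scipy.stats.gaussian_kde`` as a fourth item.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if pts.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)
    pooled = dist[:, 1:].ravel()
    density, edges = np.histogram(pooled, bins=bins, density=True)
    if return_kde:
        from scipy.stats import gaussian_kde
        return density, edges, pooled, gaussian_kde(pooled)
    return density, edges, pooled


def count_ruffles(profiles, min_amplitude: float = 15.0) -> int:
    """Total membrane-ruffle count over one cell's height profiles.

    A ruffle is a local maximum whose topographic prominence strictly
    exceeds ``min_amplitude`` (nm).  ``profiles`` may be one profile or a
    sequence (conventionally four per cell); counts are summed.
    """
    if isinstance(profiles, (HeightProfile, np.ndarray)) or (
            len(profiles) and np.isscalar(profiles[0])):
        profiles = [profiles]
    total = 0
    for p in profiles:
        samples = p.samples if isinstance(p, HeightProfile) else \
            np.asarray(p, dtype=float).ravel()
        if samples.size < 3:
            raise ValueError("a height profile needs >= 3 samples")
        _, props = find_peaks(samples, prominence=0)
        total += int(np.sum(props["prominences"] > min_amplitude))
    return total


# ---------------------------------------------------------------------------
# Focal-adhesion segmentation

def threshold_mean(image) -> float:
    """Mean-of-all-pixels auto-threshold."""
    return float(np.mean(image))


def threshold_moments(image, nbins: int = 256) -> float:
    """Tsai's moment-preserving auto-threshold.

    Chooses the threshold so that the binary image preserves the first
    three gray-level moments of the input.  Operates on a ``nbins``-level
    histogram of the image range, mirroring common GUI implementations.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return lo
    hist, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    p = hist / hist.sum()
    z = np.arange(nbins, dtype=float)
    m1 = float(np.sum(z * p))
    m2 = float(np.sum(z * z * p))
    m3 = float(np.sum(z * z * z * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        return lo
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        return lo
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels below threshold
    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, p0))
    idx = min(max(idx, 0), nbins - 1)
    return float(edges[idx + 1])  # upper edge of the selected bin


@dataclass
class FASegmentation:
    """Result of the paxillin/actin focal-adhesion pipeline."""

    labels: np.ndarray
    n_fas: int
    n_nuclei: int
    fas_per_cell: float
    per_fa: pd.DataFrame  # columns: label, area, circularity


def segment_focal_adhesions(paxillin, actin, nuclei,
                            rolling_ball_radius: float = 30.0,
                            footprint: np.ndarray | None = None) -> FASegmentation:
    """Segment focal adhesions from TIRF paxillin/actin channels.

    Pipeline: rolling-ball background subtraction (radius in pixels) on
    paxillin, moments auto-threshold, fill holes; mean auto-threshold on
    actin, dilate, fill holes, open (3x3 square, one iteration); the final
    FA mask is the logical AND of the two.  FAs-per-cell divides the
    component count by the nucleus count from the provided label mask.
    """
    pax = np.asarray(paxillin, dtype=float)
    act = np.asarray(actin, dtype=float)
    nuc = np.asarray(nuclei)
    if pax.shape != act.shape or pax.shape != nuc.shape:
        raise ValueError("paxillin, actin and nuclei images must share a shape")
    n_nuclei = int(len(np.unique(nuc[nuc > 0])))
    if n_nuclei == 0:
        raise ZeroDivisionError("nuclei mask contains no labels")
    if footprint is None:
        footprint = np.ones((3, 3), dtype=bool)

    bg = rolling_ball(pax, radius=rolling_ball_radius)
    pax_sub = pax - bg
    pax_mask = pax_sub > threshold_moments(pax_sub)
    pax_mask = ndimage.binary_fill_holes(pax_mask)

    act_mask = act > threshold_mean(act)
    act_mask = ndimage.binary_dilation(act_mask, structure=footprint)
    act_mask = ndimage.binary_fill_holes(act_mask)
    act_mask = ndimage.binary_opening(act_mask, structure=footprint)

    fa_mask = pax_mask & act_mask
    labels = sk_label(fa_mask, connectivity=1)
    props = regionprops(labels)
    rows = [{"label": rp.label, "area": float(rp.area),
             "circularity": circularity(labels == rp.label)} for rp in props]
    n_fas = len(props)
    return FASegmentation(labels, n_fas, n_nuclei, n_fas / n_nuclei,
                          pd.DataFrame(rows, columns=["label", "area",
                                                      "circularity"]))


# ---------------------------------------------------------------------------
# FRET indices

def fret_index_ratiometric(donor, fret, acceptor, params: FretParams,
                           mask) -> pd.Series:
    """Bleed-through-corrected ratiometric FRET index per masked region.

    Pixel-wise ``R = (FRET - alpha*donor - beta*acceptor) / donor``
    averaged over each label of ``mask``.  Pixels with non-positive donor
    signal are excluded with a warning; a region with no usable pixels is
    an error.
    """
    d = np.asarray(donor, dtype=float)
    f = np.asarray(fret, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    m = np.asarray(mask)
    if not (d.shape == f.shape == a.shape == m.shape):
        raise ValueError("all channels and the mask must share a shape")
    out = {}
    for lab in np.unique(m[m > 0]):
        sel = m == lab
        ok = sel & (d > 0)
        n_bad = int(sel.sum() - ok.sum())
        if n_bad:
            warnings.warn(f"region {lab}: excluded {n_bad} pixels with "
                          "non-positive donor signal", stacklevel=2)
        if not ok.any():
            raise ValueError(f"region {lab} has no pixels with positive donor")
        r = (f[ok] - params.alpha * d[ok] - params.beta * a[ok]) / d[ok]
        out[int(lab)] = float(np.mean(r))
    return pd.Series(out, name="fret_index")


def fret_index_singlechain(fret, cfp, fa_mask) -> pd.Series:
    """Single-chain sensor index: per-FA mean of FRET / CFP."""
    f = np.asarray(fret, dtype=float)
    c = np.asarray(cfp, dtype=float)
    m = np.asarray(fa_mask)
    if not (f.shape == c.shape == m.shape):
        raise ValueError("channels and FA mask must share a shape")
    out = {}
    for lab in np.unique(m[m > 0]):
        sel = m == lab
        ok = sel & (c > 0)
        n_bad = int(sel.sum() - ok.sum())
        if n_bad:
            warnings.warn(f"FA {lab}: excluded {n_bad} pixels with "
                          "non-positive CFP signal", stacklevel=2)
        if not ok.any():
            raise ValueError(f"FA {lab} has no pixels with positive CFP")
        out[int(lab)] = float(np.mean(f[ok] / c[ok]))
    return pd.Series(out, name="fret_index")


def nuclear_cytoplasmic_class(nuc_intensity: float, cyt_intensity: float,
                              equal_tolerance: float = 0.1) -> str:
    """Classify a cell as 'N>C', 'N=C' or 'N<C'.

    Intensities within ``equal_tolerance * max(nuc, cyt)`` of each other
    count as equal.
    """
    if nuc_intensity < 0 or cyt_intensity < 0:
        raise ValueError("intensities must be >= 0")
    ref = max(nuc_intensity, cyt_intensity)
    if abs(nuc_intensity - cyt_intensity) <= equal_tolerance * ref:
        return "N=C"
    return "N>C" if nuc_intensity > cyt_intensity else "N<C"


def boundary_cytoplasm_ratio(image, boundary_mask, cytoplasm_mask) -> float:
    """Mean boundary intensity over mean cytoplasm intensity."""
    img = np.asarray(image, dtype=float)
    b = np.asarray(boundary_mask).astype(bool)
    c = np.asarray(cytoplasm_mask).astype(bool)
    if not b.any() or not c.any():
        raise ValueError("masks must be non-empty")
    if (b & c).any():
        raise ValueError("boundary and cytoplasm masks must be disjoint")
    cyt_mean = float(img[c].mean())
    if cyt_mean == 0:
        raise ZeroDivisionError("cytoplasmic mean intensity is zero")
    return float(img[b].mean()) / cyt_mean
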