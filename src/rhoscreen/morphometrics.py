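"""Quantification of planar cell polarity, follicle orientation and shape.

These procedures operate on already-extracted measurements: angle lists
(hair-follicle orientation relative to the anterior-posterior axis, 0 deg =
perfect A-P alignment), straight-line pixel-intensity profiles across single
cells, per-cell cortical CELSR1 intensity as a function of cortical angle,
and 2-D label masks from upstream segmentation.  Image segmentation itself is
an input, never a responsibility; synthetic generators at the bottom of the
module (Voronoi cell fields, ellipse adhesions, bimodal cortical profiles)
provide ground-truth test inputs.

Angle conventions: degrees throughout; A-P axis = 0, counterclockwise
positive; directional angles (follicle orientation) live in (-180, 180],
non-directional axes (polarity) in (-90, 90].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage import measure


# --- follicle orientation -------------------------------------------------

def orientation_histogram(angles: Sequence[float],
                          bin_width: float = 20.0) -> pd.DataFrame:
    """Frequency distribution of orientations over (-180, 180].

    Bins are right-closed, ``(left, right]``, with edges at multiples of
    ``bin_width`` from -180; ``bin_width`` must divide 360.  Frequencies sum
    to 1.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if not np.all((angles > -180.0) & (angles <= 180.0)):
        raise ValueError("angles must lie in (-180, 180]")
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    n_bins = int(round(n_bins))
    idx = np.ceil((angles + 180.0) / bin_width).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "frequency": counts / counts.sum(),
    })


def compare_angle_distributions(a: Sequence[float],
                                b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on two angle samples: (D, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty angle sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def classify_follicle_growth(
    follicle_axis: Sequence[float],
    skin_normal: Sequence[float],
    perpendicular_threshold: float = 15.0,
) -> str:
    """'PERPENDICULAR' if the follicle axis is within ``threshold`` degrees of
    the skin normal (inclusive), else 'ANGLED'.  Axes are undirected."""
    v = np.asarray(follicle_axis, float)
    n = np.asarray(skin_normal, float)
    nv, nn = np.linalg.norm(v), np.linalg.norm(n)
    if nv == 0 or nn == 0:
        raise ValueError("zero vector")
    cosang = abs(float(v @ n) / (nv * nn))
    angle = math.degrees(math.acos(min(1.0, cosang)))
    return "PERPENDICULAR" if angle <= perpendicular_threshold else "ANGLED"


# --- intensity profiles ---------------------------------------------------

def bin_intensity_profile(positions: Sequence[float],
                          intensities: Sequence[float],
                          n_bins: int = 20) -> np.ndarray:
    """Average a line profile into ``n_bins`` equal-width bins along the cell.

    Positions are rescaled to [0, 1] (cell-size normalization); each sample
    falls in bin ``floor(x * n_bins)`` (last bin right-inclusive) and bin
    means are returned.  Requires at least ``n_bins`` samples and no empty
    bin.  With equally many samples per bin the global mean is preserved
    exactly, and a profile already of length ``n_bins`` is a fixed point.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("positions and intensities must be equal-length 1-D")
    if x.size < n_bins:
        raise ValueError(f"need >= {n_bins} samples, got {x.size}")
    span = x.max() - x.min()
    u = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    idx = np.minimum((u * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError("profile leaves empty bins; sample more densely")
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    return sums / counts


# --- planar cell polarity -------------------------------------------------

@dataclass(frozen=True)
class PolarityParams:
    """Operational definition of 'two opposing CELSR1 domains'.

    A cell is polarized when its two most intense cortical peaks are
    separated by 180 +/- ``opposition_tolerance`` degrees and each peak's
    prominence exceeds ``min_prominence_rel`` of the profile's dynamic range.
    """

    opposition_tolerance: float = 30.0
    min_prominence_rel: float = 0.2


@dataclass(frozen=True)
class PolarityCall:
    is_polarized: bool
    polarity_angle: float  # degrees in (-90, 90]; NaN when not polarized


def _axis_angle(theta_deg: np.ndarray, weights: np.ndarray) -> float:
    """Orientation of the dominant intensity axis via the doubled-angle mean,
    mapped to (-90, 90]."""
    t2 = np.deg2rad(2.0 * theta_deg)
    ang = 0.5 * math.degrees(math.atan2(float(np.sum(weights * np.sin(t2))),
                                        float(np.sum(weights * np.cos(t2)))))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def classify_polarized_cell(
    theta: Sequence[float],
    intensity: Sequence[float],
    params: PolarityParams = PolarityParams(),
) -> PolarityCall:
    """Detect two opposing cortical domains and measure the polarity axis.

    ``theta`` samples the cell cortex over the full circle [0, 360) in
    degrees; ``intensity`` is the CELSR1 signal at each angle.  Peaks are
    found on the circularly tiled profile; the cell is polarized when the
    two tallest peaks oppose each other within the tolerance.  The polarity
    angle is the doubled-angle mean orientation of the above-median signal
    (exactly rotation-covariant), reported in (-90, 90].
    """
    th = np.asarray(theta, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if th.shape != y.shape or th.ndim != 1 or th.size < 8:
        raise ValueError("need matching 1-D theta/intensity covering the circle")
    span = th.max() - th.min()
    if span < 270.0:
        raise ValueError("profile must cover the full circle")
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        return PolarityCall(False, float("nan"))

    order = np.argsort(th)
    th, y = th[order], y[order]
    n = th.size
    tiled = np.r_[y, y, y]
    prominence = params.min_prominence_rel * rng_y
    peaks, props = signal.find_peaks(tiled, prominence=prominence)
    centre = peaks[(peaks >= n) & (peaks < 2 * n)]
    if centre.size < 2:
        return PolarityCall(False, float("nan"))
    heights = tiled[centre]
    top2 = centre[np.argsort(heights)[-2:]]
    sep = abs(th[top2[0] - n] - th[top2[1] - n])
    sep = min(sep % 360.0, 360.0 - sep % 360.0)  # circular separation
    if abs(sep - 180.0) > params.opposition_tolerance:
        return PolarityCall(False, float("nan"))

    weights = np.maximum(y - np.median(y), 0.0)
    return PolarityCall(True, _axis_angle(th, weights))


def percent_polarized(cells: Sequence[tuple[Sequence[float], Sequence[float]]],
                      params: PolarityParams = PolarityParams()) -> float:
    """Fraction of cells classified as planar-polarized."""
    if len(cells) == 0:
        raise ValueError("no cells")
    calls = [classify_polarized_cell(t, i, params).is_polarized for t, i in cells]
    return sum(calls) / len(calls)


# --- label-mask morphometry ----------------------------------------------

def cell_shape_metrics(
    mask: np.ndarray,
    pixel_size: float,
    apical_basal_axis: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-cell area/eccentricity (and optional height) plus field density.

    ``mask`` is a 2-D integer label image (0 = background); ``pixel_size`` is
    micrometres per pixel.  Returns (per-cell table, density in cells/um^2 of
    the full field).  With ``apical_basal_axis`` (a 2-vector in (row, col)
    pixel coordinates, e.g. ``(1, 0)`` for image-vertical), each cell's
    height is its pixel extent projected on that axis, in micrometres.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if pixel_size <= 0:
        raise ValueError("pixel size must be > 0")
    if not (mask > 0).any():
        raise ValueError("empty mask")
    rows = []
    axis = None
    if apical_basal_axis is not None:
        axis = np.asarray(apical_basal_axis, float)
        axis = axis / np.linalg.norm(axis)
    for region in measure.regionprops(mask):
        entry = {
            "label": region.label,
            "area_um2": region.area * pixel_size ** 2,
            "eccentricity": region.eccentricity,
        }
        if axis is not None:
            proj = region.coords @ axis
            entry["height_um"] = (proj.max() - proj.min() + 1.0) * pixel_size
        rows.append(entry)
    table = pd.DataFrame(rows)
    field_area = mask.size * pixel_size ** 2
    density = len(table) / field_area
    return table, density


def focal_adhesion_metrics(
    mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.3,
) -> pd.DataFrame:
    """Measure focal adhesions on a thresholded binary mask.

    Connected components (8-connectivity) with area >= ``min_area_um2``
    (inclusive: the study's size filter is 0.3 um^2 to infinity) are kept;
    returns per-object area (um^2) and major-axis length (um).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if pixel_size <= 0:
        raise ValueError("pixel size must be > 0")
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        area = region.area * pixel_size ** 2
        if area < min_area_um2:
            continue
        rows.append({
            "label": region.label,
            "area_um2": area,
            "major_axis_um": region.axis_major_length * pixel_size,
        })
    return pd.DataFrame(rows, columns=["label", "area_um2", "major_axis_um"])


# --- synthetic test-input generators --------------------------------------

def synthetic_voronoi_field(shape: tuple[int, int], n_cells: int,
                            seed: int = 0) -> np.ndarray:
    """Voronoi-style label mask: every pixel joins its nearest seed point."""
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0, shape[0], n_cells),
                           rng.uniform(0, shape[1], n_cells)])
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((coords[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return (d2.argmin(axis=1) + 1).reshape(shape)


def synthetic_adhesion_mask(shape: tuple[int, int],
                            ellipses: Sequence[tuple[int, int, int, int]],
                            ) -> np.ndarray:
    """Binary mask of axis-aligned ellipses ((r, c, semi_r, semi_c) each)."""
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r0, c0, ar, ac in ellipses:
        mask |= ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
    return mask


def synthetic_cortical_profile(
    axis_angle: float,
    kappa: float = 8.0,
    noise_sd: float = 0.0,
    n_samples: int = 360,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal (von Mises mixture) cortical profile with opposing domains at
    ``axis_angle`` and ``axis_angle + 180``; returns (theta_deg, intensity)."""
    rng = np.random.default_rng(seed)
    theta = np.arange(n_samples) * 360.0 / n_samples
    rad = np.deg2rad(theta)
    mu = math.radians(axis_angle)
    y = (np.exp(kappa * np.cos(rad - mu)) + np.exp(kappa * np.cos(rad - mu - math.pi)))
    y /= y.max()
    if noise_sd > 0:
        y = np.maximum(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0)
    return theta, y
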