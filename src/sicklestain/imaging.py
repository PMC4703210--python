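"""Stain detection and index computation from scanned stain images.

The assay deposits a droplet of blood mixed with a hemoglobin solubility
buffer on chromatography paper.  Polymerized, insoluble sickle hemoglobin
(HbS) stays in a dark red center spot; soluble hemoglobins wick outward into
a pale peripheral ring.  A flatbed scan of the dried sheet is scored from
the Blue channel of each RGB pixel: red color intensity = 255 - B, which is
high where hemoglobin is dense.

Two scalar scores are computed per stain:

* **S-index** — mean intensity of the center spot divided by mean intensity
  of the peripheral ring; tracks the HbS fraction of total hemoglobin and is
  insensitive to total hemoglobin concentration.
* **C-index** — total center-spot intensity times the mean intensity on a
  thin annulus 5 mm from the center; couples HbS amount with total
  hemoglobin and separates HbSC disease (low total Hb) from trait carriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import (
    DomainError,
    FormatError,
    MergedStainWarning,
    NoStainError,
    UndefinedIndexError,
)

MM_PER_INCH = 25.4


def px_per_mm(dpi: float) -> float:
    """Pixels per millimetre at the given scan resolution."""
    return dpi / MM_PER_INCH


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StainImage:
    """An 8-bit RGB raster of one stain or a whole sheet, with physical scale.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array of RGB values.
    dpi
        Scan resolution in dots per inch; converts pixels to millimetres.
    source_id
        Provenance string (file name or generator tag).
    """

    pixels: np.ndarray
    dpi: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError("StainImage requires an (H, W, 3) RGB array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise DomainError("image must contain at least one pixel")
        if self.dpi <= 0:
            raise DomainError("dpi must be positive")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class IntensityMap:
    """Per-pixel red color intensity (255 - Blue), 0-255 scale."""

    values: np.ndarray
    dpi: float
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise FormatError("IntensityMap requires a 2-D array")
        if self.dpi <= 0:
            raise DomainError("dpi must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StainGeometry:
    """Detected stain center (sub-pixel) and region radii in millimetres."""

    center_xy: tuple[float, float]
    r_center: float
    r_outer: float

    def __post_init__(self) -> None:
        if not (0 < self.r_center < self.r_outer):
            raise DomainError("geometry requires 0 < r_center < r_outer")


@dataclass(frozen=True)
class RadialProfile:
    """Mean intensity per annular distance bin around a stain center."""

    bin_center_mm: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bin_center_mm, dtype=np.float64)
        m = np.asarray(self.mean_intensity, dtype=np.float64)
        if b.shape != m.shape or b.ndim != 1:
            raise DomainError("profile bins and means must be matching 1-D arrays")
        if b.size and np.any(np.diff(b) <= 0):
            raise DomainError("profile bins must be strictly increasing")
        object.__setattr__(self, "bin_center_mm", b)
        object.__setattr__(self, "mean_intensity", m)


@dataclass(frozen=True)
class StainIndices:
    """The S-index and C-index of one stain plus the geometry used."""

    s_index: float
    c_index: float
    geometry: StainGeometry


@dataclass(frozen=True)
class GeometryConfig:
    """Rules for reducing a radial profile to (r_center, r_outer).

    ``r_outer`` is the smallest radius beyond which every bin mean falls below
    ``background + fraction_outer * (peak - background)``; ``r_center`` is the
    smallest radius at which the profile drops below ``background +
    fraction_center * (plateau - background)`` where the plateau is the mean
    over the innermost ``plateau_mm``.  ``r_center`` is clamped to
    ``[0.5 mm, r_outer - 0.5 mm]``.
    """

    fraction_center: float = 0.5
    fraction_outer: float = 0.1
    plateau_mm: float = 1.0
    bin_width_mm: float = 0.25
    min_contrast: float = 1.0  # intensity units above background to count as a stain


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of sheet-level stain detection.

    Pixels brighter than ``median + k_mad * MAD`` of the whole sheet are
    thresholded, connected components whose equivalent diameter lies in the
    accepted range are kept, and each component yields one stain geometry.
    ``geometry`` selects how region radii are assigned: ``"fixed"`` uses the
    nominal assay radii (the readout overlays circles of constant size on
    every stain); ``"profile"`` estimates per-stain radii from the radial
    profile, which is reliable only while the peripheral ring stays above
    ``fraction_outer`` of the center peak (low-to-moderate %HbS).
    """

    k_mad: float = 5.0
    min_diameter_mm: float = 8.0
    max_diameter_mm: float = 25.0
    merged_factor: float = 1.5
    closing_mm: float = 0.3
    geometry: Literal["fixed", "profile"] = "fixed"
    fixed_r_center_mm: float = 2.5
    fixed_r_outer_mm: float = 7.5
    geometry_config: GeometryConfig = field(default_factory=GeometryConfig)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def to_intensity(image: StainImage) -> IntensityMap:
    """Convert an RGB stain image to the red color intensity map (255 - Blue)."""
    px = image.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise FormatError("intensity conversion requires an RGB image with a Blue channel")
    values = 255.0 - px[:, :, 2].astype(np.float64)
    return IntensityMap(values=values, dpi=image.dpi, source_id=image.source_id)


def _distances_mm(
    shape: tuple[int, int], center_xy: tuple[float, float], dpi: float
) -> np.ndarray:
    """Distance of every pixel center from ``center_xy`` (x, y in px), in mm."""
    h, w = shape
    cx, cy = center_xy
    y = np.arange(h, dtype=np.float64)[:, None] - cy
    x = np.arange(w, dtype=np.float64)[None, :] - cx
    return np.hypot(y, x) / px_per_mm(dpi)


def _crop(
    stain: IntensityMap, center_xy: tuple[float, float], radius_mm: float
) -> tuple[np.ndarray, tuple[float, float]]:
    """Square crop around the center covering ``radius_mm``, with shifted center."""
    ppmm = px_per_mm(stain.dpi)
    cx, cy = center_xy
    r_px = int(np.ceil(radius_mm * ppmm)) + 1
    h, w = stain.shape
    x0, x1 = max(0, int(cx) - r_px), min(w, int(cx) + r_px + 1)
    y0, y1 = max(0, int(cy) - r_px), min(h, int(cy) + r_px + 1)
    return stain.values[y0:y1, x0:x1], (cx - x0, cy - y0)


def compute_radial_profile(
    stain: IntensityMap,
    center_xy: tuple[float, float],
    bin_width_mm: float = 0.25,
    max_radius_mm: float | None = None,
) -> RadialProfile:
    """Bin pixels by distance to the center and average intensity per bin.

    Bins of width ``bin_width_mm`` start at radius zero; bins containing no
    pixel centers are omitted.  ``max_radius_mm`` restricts the profile to a
    neighbourhood (used on sheets so neighbouring stains do not leak in).
    """
    if bin_width_mm <= 0:
        raise DomainError("bin_width_mm must be positive")
    h, w = stain.shape
    cx, cy = center_xy
    if not (0 <= cx < w and 0 <= cy < h):
        raise DomainError("profile center lies outside the image")
    if max_radius_mm is not None:
        values, center = _crop(stain, center_xy, max_radius_mm)
    else:
        values, center = stain.values, (cx, cy)
    r = _distances_mm(values.shape, center, stain.dpi)
    if max_radius_mm is not None:
        keep = r <= max_radius_mm
        r, values = r[keep], values[keep]
    idx = np.floor(r / bin_width_mm).astype(np.intp).ravel()
    flat = np.asarray(values, dtype=np.float64).ravel()
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=flat)
    nonempty = counts > 0
    means = sums[nonempty] / counts[nonempty]
    centers = (np.flatnonzero(nonempty) + 0.5) * bin_width_mm
    return RadialProfile(bin_center_mm=centers, mean_intensity=means)


def estimate_geometry(
    profile: RadialProfile,
    config: GeometryConfig = GeometryConfig(),
    background: float = 0.0,
) -> tuple[float, float]:
    """Estimate (r_center, r_outer) in mm from a radial profile.

    Raises :class:`NoStainError` when the profile never rises more than
    ``config.min_contrast`` above background.
    """
    bins = profile.bin_center_mm
    means = profile.mean_intensity
    if bins.size < 5:
        raise DomainError("geometry estimation needs at least 5 profile bins")
    peak = float(means.max())
    if peak - background < config.min_contrast:
        raise NoStainError("radial profile is indistinguishable from background")

    thr_outer = background + config.fraction_outer * (peak - background)
    above = np.flatnonzero(means >= thr_outer)
    r_outer = float(bins[above[-1]])

    plateau_sel = bins <= max(config.plateau_mm, bins[0])
    plateau = float(means[plateau_sel].mean())
    thr_center = background + config.fraction_center * (plateau - background)
    below = np.flatnonzero(means < thr_center)
    r_center = float(bins[below[0]]) if below.size else r_outer
    r_center = float(np.clip(r_center, 0.5, r_outer - 0.5))
    if r_center >= r_outer:  # degenerate tiny stain
        r_center = r_outer / 2.0
    return r_center, r_outer


def detect_stains(
    sheet: IntensityMap, config: DetectionConfig = DetectionConfig()
) -> list[StainGeometry]:
    """Locate stains on a scanned sheet and return one geometry per stain.

    Background is estimated as the sheet median; pixels above
    ``median + k_mad * MAD`` are thresholded (after a small morphological
    closing to bridge pixel noise), connected components with equivalent
    diameter inside the accepted range and not touching the image border are
    kept.  Component centers are intensity-weighted centroids.  An empty list
    means no stain qualified; a component wider than ``merged_factor *
    max_diameter_mm`` raises :class:`MergedStainWarning` on the warnings
    channel.  Results are ordered row-major by center position.
    """
    values = sheet.values
    ppmm = px_per_mm(sheet.dpi)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    mask = values > med + config.k_mad * mad
    if config.closing_mm > 0:
        r = max(1, int(round(config.closing_mm * ppmm)))
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        selem = (yy * yy + xx * xx) <= r * r
        mask = ndimage.binary_closing(mask, structure=selem)
        mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []

    h, w = values.shape
    geometries: list[StainGeometry] = []
    weights = np.clip(values - med, 0.0, None)
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        count = int(comp.sum())
        eq_diam_mm = 2.0 * np.sqrt(count / np.pi) / ppmm
        if eq_diam_mm > config.merged_factor * config.max_diameter_mm:
            warnings.warn(
                f"component of equivalent diameter {eq_diam_mm:.1f} mm exceeds "
                f"{config.merged_factor} x max diameter; possible merged stains",
                MergedStainWarning,
                stacklevel=2,
            )
        if not (config.min_diameter_mm <= eq_diam_mm <= config.max_diameter_mm):
            continue
        if sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == h or sl[1].stop == w:
            continue  # touching the border: partial stain
        wgt = weights[sl] * comp
        total = wgt.sum()
        if total <= 0:
            continue
        ys, xs = np.mgrid[sl[0], sl[1]]
        cy = float((wgt * ys).sum() / total)
        cx = float((wgt * xs).sum() / total)

        if config.geometry == "fixed":
            r_c, r_o = config.fixed_r_center_mm, config.fixed_r_outer_mm
        else:
            gc = config.geometry_config
            profile = compute_radial_profile(
                sheet,
                (cx, cy),
                bin_width_mm=gc.bin_width_mm,
                max_radius_mm=config.max_diameter_mm / 2 * 1.2,
            )
            r_c, r_o = estimate_geometry(profile, gc, background=med)
        geometries.append(StainGeometry(center_xy=(cx, cy), r_center=r_c, r_outer=r_o))

    row_tol = config.min_diameter_mm * ppmm / 2.0
    geometries.sort(key=lambda g: g.center_xy[1])
    rows: list[list[StainGeometry]] = []
    for g in geometries:
        if rows and g.center_xy[1] - rows[-1][0].center_xy[1] <= row_tol:
            rows[-1].append(g)
        else:
            rows.append([g])
    ordered: list[StainGeometry] = []
    for row in rows:
        ordered.extend(sorted(row, key=lambda g: g.center_xy[0]))
    return ordered


def _region_masks(
    stain: IntensityMap, geom: StainGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values, center = _crop(stain, geom.center_xy, geom.r_outer)
    r = _distances_mm(values.shape, center, stain.dpi)
    center_mask = r <= geom.r_center
    ring_mask = (r > geom.r_center) & (r <= geom.r_outer)
    return values, center_mask, ring_mask


def compute_s_index(
    stain: IntensityMap,
    geom: StainGeometry,
    subtract_background: float | None = None,
) -> float:
    """Mean center-spot intensity divided by mean peripheral-ring intensity.

    Raw intensities are used by default; region membership uses pixel-center
    distance with a half-open ring ``(r_center, r_outer]`` so each pixel
    belongs to exactly one region.  ``subtract_background`` optionally removes
    a constant background from both means before the quotient (off by
    default: the index is defined on raw intensities).
    """
    values, center_mask, ring_mask = _region_masks(stain, geom)
    if not ring_mask.any():
        raise DomainError("ring region contains no pixels")
    if not center_mask.any():
        raise DomainError("center region contains no pixels")
    bg = subtract_background or 0.0
    center_mean = float(values[center_mask].mean()) - bg
    ring_mean = float(values[ring_mask].mean()) - bg
    if ring_mean == 0.0:
        raise UndefinedIndexError("ring mean intensity is zero; S-index undefined")
    return center_mean / ring_mean


def compute_c_index(
    stain: IntensityMap,
    geom: StainGeometry,
    c_radius_mm: float = 5.0,
    half_width_mm: float = 0.25,
) -> float:
    """Total center-spot intensity times mean intensity at ``c_radius_mm``.

    The "distance of 5 mm from the center" is realised as a thin annulus of
    half-width ``half_width_mm`` (a zero-width circle contains no pixel
    centers).  The annulus must lie fully inside the image.
    """
    ppmm = px_per_mm(stain.dpi)
    cx, cy = geom.center_xy
    h, w = stain.shape
    reach = (c_radius_mm + half_width_mm) * ppmm
    if cx - reach < -0.5 or cy - reach < -0.5 or cx + reach > w - 0.5 or cy + reach > h - 0.5:
        raise DomainError("C-index annulus extends outside the image")
    values, center = _crop(stain, geom.center_xy, max(geom.r_outer, c_radius_mm + half_width_mm))
    r = _distances_mm(values.shape, center, stain.dpi)
    center_mask = r <= geom.r_center
    annulus = np.abs(r - c_radius_mm) <= half_width_mm
    if not annulus.any():
        raise DomainError("C-index annulus contains no pixels")
    total_center = float(values[center_mask].sum())
    mean_annulus = float(values[annulus].mean())
    return total_center * mean_annulus


def compute_indices(
    stain: IntensityMap,
    geom: StainGeometry,
    c_radius_mm: float = 5.0,
    half_width_mm: float = 0.25,
) -> StainIndices:
    """Convenience wrapper computing both indices for one stain."""
    return StainIndices(
        s_index=compute_s_index(stain, geom),
        c_index=compute_c_index(stain, geom, c_radius_mm, half_width_mm),
        geometry=geom,
    )


__all__ = [
    "StainImage",
    "IntensityMap",
    "StainGeometry",
    "RadialProfile",
    "StainIndices",
    "GeometryConfig",
    "DetectionConfig",
    "to_intensity",
    "detect_stains",
    "compute_radial_profile",
    "estimate_geometry",
    "compute_s_index",
    "compute_c_index",
    "compute_indices",
    "px_per_mm",
]
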