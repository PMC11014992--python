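"""Macro-style fluorescence quantifications.

Re-implementations of the FIJI-macro measurements used across the muscle
figures, as composable functions:

* ``percent_active_mitochondria`` — thresholded TMRE area divided by
  thresholded MitoTracker Green area, x100 (fraction of mitochondria that
  hold a membrane potential);
* ``count_particles`` — connected-component particle analysis with a
  calibrated size filter, for lipid-droplet counts and densities per mm²;
* ``tccf`` — total corrected cell fluorescence: integrated ROI intensity
  minus ROI area x mean background intensity;
* ``nuclear_ratio`` — per-ROI mean-intensity ratios (FOXO/DAPI,
  mCherry/GFP);
* ``muscle_integrity`` — thresholded fluorescent area inside a cuticle ROI
  divided by the ROI area (% muscle attachment), optionally normalised to
  a control mean.

Pre-processing primitives (8-bit conversion, Gaussian blur, outlier
removal, IsoData auto-threshold) follow their ImageJ counterparts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.morphology import disk

from .stack import ImageStack, max_project

__all__ = [
    "Roi",
    "ParticleFilter",
    "TmreConfig",
    "TmreResult",
    "TccfResult",
    "to_8bit",
    "gaussian_blur",
    "remove_outliers",
    "isodata_threshold",
    "percent_active_mitochondria",
    "count_particles",
    "tccf",
    "nuclear_ratio",
    "muscle_integrity",
    "max_project",
]


@dataclass
class Roi:
    """A rectangular or polygonal region of interest.

    Vertices are 0-based (row, col) pixel coordinates. A rectangle is
    given by its two opposite corners (inclusive); a polygon needs at
    least three vertices.
    """

    shape: str  # "rectangle" | "polygon"
    vertices: list[tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "polygon"):
            raise ValueError(f"unknown ROI shape: {self.shape!r}")
        if self.shape == "rectangle" and len(self.vertices) != 2:
            raise ValueError("rectangle ROI needs exactly 2 corner vertices")
        if self.shape == "polygon" and len(self.vertices) < 3:
            raise ValueError("polygon ROI needs >= 3 vertices")

    def to_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask on an image of the given (h, w) shape."""
        h, w = image_shape
        if self.shape == "rectangle":
            (r0, c0), (r1, c1) = self.vertices
            r0, r1 = sorted((int(r0), int(r1)))
            c0, c1 = sorted((int(c0), int(c1)))
            mask = np.zeros((h, w), dtype=bool)
            mask[max(r0, 0) : min(r1 + 1, h), max(c0, 0) : min(c1 + 1, w)] = True
        else:
            mask = polygon2mask((h, w), np.asarray(self.vertices, dtype=float))
        if not mask.any():
            raise ValueError(f"ROI {self.label!r} has zero area on this image")
        return mask


@dataclass
class ParticleFilter:
    """Half-open calibrated size window [min_area, max_area) in µm²."""

    min_area: float = 0.0
    max_area: float = float("inf")

    def __post_init__(self) -> None:
        if not (0 <= self.min_area < self.max_area):
            raise ValueError("need 0 <= min_area < max_area")


@dataclass
class TmreConfig:
    """Processing parameters for the membrane-potential area ratio.

    Defaults follow the ImageJ macro conventions: Gaussian blur sigma 2 px,
    Remove Outliers radius 2 px / threshold 50 (bright mode). ``roi``
    restricts the measurement to a rectangular crop of the fillet.
    """

    blur_sigma_px: float = 2.0
    outlier_radius_px: int = 2
    outlier_threshold: float = 50.0
    roi: Roi | None = None


@dataclass
class TmreResult:
    """Total vs active mitochondrial area and their percentage ratio."""

    area_total_um2: float
    area_active_um2: float
    percent_active: float
    flagged_over_100: bool = False


@dataclass
class TccfResult:
    """Total corrected cell fluorescence and its components."""

    integrated_density: float
    roi_area_px: int
    background_mean: float
    tccf: float


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 255], rounding half-up.

    A constant image maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def gaussian_blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Isotropic Gaussian smoothing with reflective borders; sigma 0 = identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma_px == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma_px, mode="reflect")


def remove_outliers(
    image: np.ndarray,
    radius_px: int = 2,
    threshold: float = 50.0,
    mode: str = "bright",
) -> np.ndarray:
    """ImageJ-style despeckle: replace a pixel by its local circular median
    iff it deviates from that median by more than ``threshold``.

    ``mode='bright'`` removes hot pixels, ``'dark'`` removes cold ones,
    ``'both'`` removes either.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if mode not in ("bright", "dark", "both"):
        raise ValueError(f"unknown mode: {mode!r}")
    image = np.asarray(image, dtype=float)
    footprint = disk(radius_px)
    med = ndimage.median_filter(image, footprint=footprint, mode="reflect")
    dev = image - med
    if mode == "bright":
        replace = dev > threshold
    elif mode == "dark":
        replace = -dev > threshold
    else:
        replace = np.abs(dev) > threshold
    return np.where(replace, med, image)


def isodata_threshold(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Ridler–Calvard iterative intermeans threshold.

    Iterates T <- (mean of pixels <= T + mean of pixels > T) / 2 from the
    global mean until a fixed point; the mask selects pixels strictly
    above T. The converged T is equivariant to adding a constant to the
    image (T shifts by the same constant, the mask is unchanged).
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    t = float(image.mean())
    for _ in range(500):
        below = image <= t
        m0 = image[below].mean()
        m1 = image[~below].mean() if (~below).any() else hi
        t_new = 0.5 * (m0 + m1)
        if (image <= t_new).sum() == below.sum():
            # partition stable: fixed point reached
            t = t_new
            break
        t = t_new
    return t, image > t


def _area_chain(stack: ImageStack, cfg: TmreConfig) -> float:
    """max-project -> 8-bit -> blur -> remove outliers -> crop -> threshold -> µm²."""
    img = max_project(stack)
    img = to_8bit(img)
    img = gaussian_blur(img, cfg.blur_sigma_px)
    img = remove_outliers(img, cfg.outlier_radius_px, cfg.outlier_threshold)
    if cfg.roi is not None:
        mask_roi = cfg.roi.to_mask(img.shape)
        rows, cols = np.nonzero(mask_roi)
        img = img[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    _, mask = isodata_threshold(img)
    return float(mask.sum()) * stack.pixel_area_um2


def percent_active_mitochondria(
    total_stack: ImageStack,
    active_stack: ImageStack,
    cfg: TmreConfig | None = None,
) -> TmreResult:
    """Active (TMRE) over total (MitoTracker) thresholded area, x100.

    Both channels pass through the identical processing chain; only the
    final thresholded areas differ. A ratio above 100% is returned but
    flagged.
    """
    cfg = cfg or TmreConfig()
    if total_stack.shape != active_stack.shape:
        raise ValueError("channel stacks must share dimensions")
    if total_stack.pixel_size_um != active_stack.pixel_size_um:
        raise ValueError("channel stacks must share pixel calibration")
    area_total = _area_chain(total_stack, cfg)
    if area_total == 0:
        raise ValueError("zero total-mitochondria area: nothing to normalise to")
    try:
        area_active = _area_chain(active_stack, cfg)
    except ValueError:
        # constant active channel after processing: no signal at all
        area_active = 0.0
    pct = 100.0 * area_active / area_total
    return TmreResult(area_total, area_active, pct, flagged_over_100=pct > 100.0)


_STRUCT_8CONN = np.ones((3, 3), dtype=bool)


def count_particles(
    mask: np.ndarray,
    particle_filter: ParticleFilter,
    pixel_size_um: float,
    field_area_mm2: float,
) -> tuple[int, np.ndarray, float]:
    """Analyse-Particles style counting on a binary mask.

    8-connected components are measured in calibrated µm² and kept iff
    min_area <= area < max_area. Returns (count, kept areas in µm²,
    density per mm² of field).
    """
    if field_area_mm2 <= 0:
        raise ValueError("field_area_mm2 must be > 0")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = np.asarray(mask) > 0
    labelled, n = ndimage.label(mask, structure=_STRUCT_8CONN)
    if n == 0:
        return 0, np.empty(0), 0.0
    counts = np.bincount(labelled.ravel())[1:]
    areas = counts * pixel_size_um**2
    keep = (areas >= particle_filter.min_area) & (areas < particle_filter.max_area)
    kept = areas[keep]
    return int(kept.size), kept, float(kept.size) / field_area_mm2


def tccf(
    image: np.ndarray,
    cell_roi: Roi,
    background_rois: list[Roi],
) -> TccfResult:
    """Total corrected cell fluorescence.

    tccf = integrated density over the cell ROI − (cell ROI pixel count) ×
    (mean intensity over the pooled background ROIs). Invariant to adding
    a constant offset to the whole image.
    """
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    image = np.asarray(image, dtype=float)
    cell_mask = cell_roi.to_mask(image.shape)
    bg_mask = np.zeros(image.shape, dtype=bool)
    for roi in background_rois:
        bg_mask |= roi.to_mask(image.shape)
    if (cell_mask & bg_mask).any():
        warnings.warn("cell and background ROIs overlap; computing anyway")
    integrated = float(image[cell_mask].sum())
    n_px = int(cell_mask.sum())
    bg_mean = float(image[bg_mask].mean())
    return TccfResult(integrated, n_px, bg_mean, integrated - n_px * bg_mean)


def nuclear_ratio(
    numerator_image: np.ndarray,
    denominator_image: np.ndarray,
    nuclear_rois: list[Roi],
) -> list[float]:
    """Per-ROI mean-intensity ratios (e.g. FOXO/DAPI, mCherry/GFP).

    An ROI whose denominator mean is zero yields NaN (with a warning);
    the other ROIs are still returned.
    """
    num = np.asarray(numerator_image, dtype=float)
    den = np.asarray(denominator_image, dtype=float)
    if num.shape != den.shape:
        raise ValueError("channel images must share dimensions")
    ratios = []
    for roi in nuclear_rois:
        m = roi.to_mask(num.shape)
        d = den[m].mean()
        if d == 0:
            warnings.warn(f"ROI {roi.label!r}: zero denominator mean; ratio undefined")
            ratios.append(float("nan"))
        else:
            ratios.append(float(num[m].mean() / d))
    return ratios


def muscle_integrity(
    image: np.ndarray,
    cuticle_roi: Roi,
    control_mean: float | None = None,
) -> tuple[float, float | None]:
    """% muscle attachment: thresholded fluorescent area / cuticle ROI area.

    The IsoData threshold is computed from the ROI pixels only. A
    zero-contrast ROI cannot be thresholded and is scored 1.0 if its
    constant value is positive (solid muscle), else 0.0. When a control
    group mean is supplied the raw fraction is also returned normalised
    to it (control ≙ 1).
    """
    image = np.asarray(image, dtype=float)
    mask = cuticle_roi.to_mask(image.shape)
    vals = image[mask]
    if vals.min() == vals.max():
        raw = 1.0 if vals[0] > 0 else 0.0
    else:
        t, _ = isodata_threshold(vals)
        raw = float((vals > t).sum()) / float(vals.size)
    normalized = raw / control_mean if control_mean else None
    return raw, normalized
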