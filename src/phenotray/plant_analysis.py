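"""Per-quadrant canopy analysis.

Implements the core image-analysis chain used for top-view tray
phenotyping: grayscale conversion, intensity histogram, plant/background
thresholding, connected-component plant counting, and conversion of
plant pixel area to projected canopy size (PCS) in cm² via a known-object
calibration:

    pcs_cm2 = area_px / (a / b)**2

where ``a`` is the length of a known reference object in pixels and ``b``
its length in cm, so ``a / b`` is the spatial resolution in px/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure


class DegenerateImageWarning(UserWarning):
    """Raised as a flag value, never an exception: constant-image threshold."""


@dataclass(frozen=True)
class CalibrationReference:
    """Known-object calibration: ``a`` px and ``b`` cm of the same object."""

    a: float  # length of known object, pixels
    b: float  # length of known object, cm

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                f"calibration lengths must be positive, got a={self.a} px, b={self.b} cm"
            )

    @property
    def px_per_cm(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray  # boolean, same shape as source
    threshold_used: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class CanopyMeasurement:
    """Per-quadrant measurement row.

    ``pcs_per_plant_cm2`` is 0 when no plant was detected; germination is
    capped at 100% (counts above ``n_sown`` are clutter or split blobs and
    are flagged instead).
    """

    plant_count: int
    area_px: int
    pcs_cm2: float
    pcs_per_plant_cm2: float
    germination_pct: float
    threshold_used: float = float("nan")
    flags: tuple[str, ...] = field(default_factory=tuple)


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """8-bit luma conversion, 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {rgb_image.shape}")
    luma = (
        0.299 * rgb_image[..., 0].astype(np.float64)
        + 0.587 * rgb_image[..., 1].astype(np.float64)
        + 0.114 * rgb_image[..., 2].astype(np.float64)
    )
    return np.floor(luma + 0.5).astype(np.uint8)


def intensity_histogram(gray_image: np.ndarray) -> np.ndarray:
    """256-bin pixel-intensity histogram; bins sum to the pixel count."""
    gray_image = np.asarray(gray_image)
    if gray_image.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {gray_image.shape}")
    if gray_image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {gray_image.dtype}")
    return np.bincount(gray_image.ravel(), minlength=256)


def otsu_threshold(gray_image: np.ndarray) -> float:
    """Histogram-based Otsu threshold maximizing between-class variance.

    Foreground is ``pixel > threshold``.  When several thresholds attain
    the maximal between-class variance (a plateau, common for strictly
    bimodal images), the midpoint of the plateau is returned so the
    threshold sits between the two modes rather than on the lower one.
    """
    hist = intensity_histogram(gray_image).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # weight of class <= t
    w1 = n - w0
    mu_cum = np.cumsum(hist * levels)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    best = sigma_b.max()
    if best <= 0:  # constant image: no split improves on a single class
        return float("nan")
    plateau = np.flatnonzero(sigma_b == best)
    return float(plateau.mean())


def excess_green(rgb_image: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - R - B (signed int16 per pixel)."""
    rgb_image = np.asarray(rgb_image)
    if rgb_image.ndim != 3 or rgb_image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {rgb_image.shape}")
    r = rgb_image[..., 0].astype(np.int16)
    g = rgb_image[..., 1].astype(np.int16)
    b = rgb_image[..., 2].astype(np.int16)
    return 2 * g - r - b


def segment_plants(
    image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    exg_threshold: float = 20.0,
) -> SegmentationResult:
    """Separate plant pixels from background.

    method="otsu"          grayscale input; bright pixels are plant
                           (chlorophyll-fluorescence convention).
    method="fixed"         grayscale input thresholded at ``fixed_threshold``.
    method="excess_green"  RGB input; foreground where 2G - R - B exceeds
                           ``exg_threshold``.

    A constant image under Otsu yields an empty mask with the degenerate
    flag set rather than an arbitrary split.
    """
    image = np.asarray(image)
    if method == "excess_green":
        exg = excess_green(image)
        mask = exg > exg_threshold
        return SegmentationResult(mask, float(exg_threshold), method)
    if image.ndim == 3:
        image = to_grayscale(image)
    if method == "otsu":
        t = otsu_threshold(image)
        if np.isnan(t):
            return SegmentationResult(
                np.zeros(image.shape, dtype=bool), t, method, degenerate=True
            )
        return SegmentationResult(image > t, t, method)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        return SegmentationResult(image > fixed_threshold, float(fixed_threshold), method)
    raise ValueError(f"unknown segmentation method {method!r}")


def count_plants(
    mask: np.ndarray, min_area_px: int = 5, connectivity: int = 8
) -> tuple[int, int, np.ndarray]:
    """Count connected foreground components of area >= ``min_area_px``.

    Returns (plant_count, area_px, labeled) where ``area_px`` sums pixels
    of retained components only and ``labeled`` keeps only retained labels.
    """
    if min_area_px < 0:
        raise ValueError(f"min_area_px must be non-negative, got {min_area_px}")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    labeled = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    if labeled.max() == 0:
        return 0, 0, labeled
    areas = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area_px) + 1
    retained = np.where(np.isin(labeled, keep), labeled, 0)
    return len(keep), int(areas[keep - 1].sum()), retained


def pixels_to_cm2(x: float, calib: CalibrationReference) -> float:
    """Convert plant pixel area ``x`` to projected canopy size in cm²."""
    if x < 0:
        raise ValueError(f"pixel area must be non-negative, got {x}")
    return x / calib.px_per_cm**2


def calibrate_from_image(
    image: np.ndarray, object_length_cm: float, threshold: float = 128.0
) -> CalibrationReference:
    """Measure a bright calibration bar's pixel length against its known cm length."""
    image = np.asarray(image)
    if image.ndim == 3:
        image = to_grayscale(image)
    cols = np.flatnonzero((image > threshold).any(axis=0))
    if cols.size == 0:
        raise ValueError("no calibration object found above threshold")
    return CalibrationReference(a=float(cols[-1] - cols[0] + 1), b=object_length_cm)


def measure_quadrant(
    quadrant_image: np.ndarray,
    calib: CalibrationReference,
    n_sown: int,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    exg_threshold: float = 20.0,
    min_area_px: int = 5,
    connectivity: int = 8,
) -> CanopyMeasurement:
    """Full per-quadrant measurement: segment, count, convert, rate germination."""
    if n_sown <= 0:
        raise ValueError(f"n_sown must be positive, got {n_sown}")
    seg = segment_plants(
        quadrant_image,
        method=method,
        fixed_threshold=fixed_threshold,
        exg_threshold=exg_threshold,
    )
    count, area_px, _ = count_plants(seg.mask, min_area_px=min_area_px, connectivity=connectivity)
    pcs = pixels_to_cm2(area_px, calib)
    flags: list[str] = []
    if seg.degenerate:
        flags.append("degenerate_image")
    if count > n_sown:
        flags.append("count_exceeds_sown")
    germination_pct = 100.0 * min(count, n_sown) / n_sown
    return CanopyMeasurement(
        plant_count=count,
        area_px=area_px,
        pcs_cm2=pcs,
        pcs_per_plant_cm2=pcs / count if count > 0 else 0.0,
        germination_pct=germination_pct,
        threshold_used=seg.threshold_used,
        flags=tuple(flags),
    )
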