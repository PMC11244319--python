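"""Fiducial detection, perspective rectification, and quadrant splitting.

A tray carries four colored pins at the corners of a square; detecting
their centroids lets an oblique capture be warped into a "perfect square"
which is then divided into four equal positional quadrants, one cultivar
per quadrant.  Pixel coordinates are 0-based (row, column) with the origin
at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, measure, transform

#: Named hue centers (HSV hue in [0, 1)) for common pin colors.
HUE_CENTERS = {"red": 0.0, "blue": 2.0 / 3.0, "green": 1.0 / 3.0}


class MarkerDetectionError(ValueError):
    """Marker detection did not yield exactly four plausible fiducials."""


@dataclass(frozen=True)
class MarkerSet:
    """Four fiducial centroids ordered top-left, top-right, bottom-right, bottom-left."""

    points: tuple[tuple[float, float], ...]  # (row, col)

    def __post_init__(self) -> None:
        if len(self.points) != 4:
            raise ValueError(f"exactly 4 marker points required, got {len(self.points)}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=np.float64)


@dataclass(frozen=True)
class QuadrantImage:
    """One of the four equal tiles of a rectified tray image.

    quadrant_id: 1 top-left, 2 top-right, 3 bottom-left, 4 bottom-right.
    """

    quadrant_id: int
    image: np.ndarray


def order_markers(points: np.ndarray) -> np.ndarray:
    """Order four points TL, TR, BR, BL by angle about their common centroid."""
    points = np.asarray(points, dtype=np.float64)
    centroid = points.mean(axis=0)
    # atan2(d_row, d_col): TL falls in (-pi, -pi/2), TR in (-pi/2, 0),
    # BR in (0, pi/2), BL in (pi/2, pi) -- ascending sort yields TL,TR,BR,BL.
    angles = np.arctan2(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    return points[np.argsort(angles)]


def detect_markers(
    image: np.ndarray,
    color_spec: str | float = "red",
    hue_tolerance: float = 0.07,
    min_saturation: float = 0.45,
    min_value: float = 0.25,
    min_area_px: int = 5,
) -> MarkerSet:
    """Find the four corner fiducials of the given color.

    Pixels are matched in HSV by a circular hue window around the target
    hue plus saturation/value floors; connected components smaller than
    ``min_area_px`` are discarded as speckle.  Exactly four components
    must remain, otherwise a MarkerDetectionError reports the count found.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an 8-bit RGB image, got shape {image.shape}")
    hue0 = HUE_CENTERS[color_spec] if isinstance(color_spec, str) else float(color_spec)
    hsv = color.rgb2hsv(image)
    dh = np.abs(hsv[..., 0] - hue0)
    hue_dist = np.minimum(dh, 1.0 - dh)  # hue is circular
    mask = (hue_dist <= hue_tolerance) & (hsv[..., 1] >= min_saturation) & (hsv[..., 2] >= min_value)

    labeled = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labeled) if p.area >= min_area_px]
    if len(props) != 4:
        raise MarkerDetectionError(
            f"{len(props)} markers found after filtering (need exactly 4); "
            f"color={color_spec!r}, hue_tolerance={hue_tolerance}"
        )
    centroids = np.array([p.centroid for p in props])
    ordered = order_markers(centroids)
    return MarkerSet(points=tuple((float(r), float(c)) for r, c in ordered))


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    """True if any three of the four points are (near-)collinear."""
    from itertools import combinations

    for i, j, k in combinations(range(4), 3):
        v1 = points[j] - points[i]
        v2 = points[k] - points[i]
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        scale = max(np.abs(v1).max(), np.abs(v2).max(), 1.0)
        if abs(cross) <= tol * scale**2:
            return True
    return False


def rectify_to_square(image: np.ndarray, markers: MarkerSet, side_px: int) -> np.ndarray:
    """Warp the marker quadrilateral onto a side_px x side_px square.

    The four marker centroids map to the four corner pixels of the output;
    bilinear interpolation is used, so for markers already at the corners
    of an axis-aligned square of the requested side the result is an exact
    crop.  An even side is required so the square splits into equal tiles.
    """
    if side_px <= 0 or side_px % 2 != 0:
        raise ValueError(f"side_px must be positive and even, got {side_px}")
    pts = markers.as_array()
    if _collinear(pts):
        raise ValueError("degenerate marker set: three markers are collinear")
    # skimage transforms work in (x, y) = (col, row)
    dst_xy = pts[:, ::-1]
    s = side_px - 1
    src_xy = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=np.float64)  # TL,TR,BR,BL
    tform = transform.ProjectiveTransform.from_estimate(src_xy, dst_xy)
    if not tform:
        raise ValueError("could not estimate a projective transform from the markers")
    warped = transform.warp(
        image.astype(np.float64),
        tform,
        output_shape=(side_px, side_px) + image.shape[2:],
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return np.clip(np.rint(warped), 0, 255).astype(np.uint8)


def split_quadrants(square_image: np.ndarray) -> list[QuadrantImage]:
    """Split a rectified square into four equal non-overlapping tiles.

    Numbering is row-major from the top-left (1 TL, 2 TR, 3 BL, 4 BR);
    stacking the tiles back reconstructs the input exactly.
    """
    square_image = np.asarray(square_image)
    h, w = square_image.shape[:2]
    if h != w:
        raise ValueError(f"expected a square image, got {h}x{w}")
    if h % 2 != 0:
        raise ValueError(
            f"side {h} is odd; rectify with an even side_px so quadrants are equal"
        )
    half = h // 2
    return [
        QuadrantImage(1, square_image[:half, :half]),
        QuadrantImage(2, square_image[:half, half:]),
        QuadrantImage(3, square_image[half:, :half]),
        QuadrantImage(4, square_image[half:, half:]),
    ]
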