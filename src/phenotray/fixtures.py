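"""Synthetic tray scenes with exact ground truth.

Renders top-view tray images that emulate the study layout: four colored
corner fiducials bounding a square tray region, four positional quadrants
(one cultivar each), and disc-shaped seedlings whose rasterized pixel
areas are known exactly.  Time series follow per-plant germination days
and logistic radius growth, emulating the gradual emergence over days
three to five and exponential canopy growth thereafter seen in lettuce
seedlings.

All stochastic draws (background noise, per-frame seeds) derive from a
single integer seed, so every rendering is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .plant_analysis import CalibrationReference

QUADRANT_IDS = (1, 2, 3, 4)  # 1 top-left, 2 top-right, 3 bottom-left, 4 bottom-right


@dataclass(frozen=True)
class PlantSpec:
    """One rendered seedling: a filled disc in a specific quadrant."""

    quadrant_id: int
    center: tuple[float, float]  # (row, col), full-image pixels
    radius: float
    intensity: int = 200  # green channel (RGB mode) or gray value


@dataclass(frozen=True)
class GroundTruth:
    """Exact expected analysis output for a rendered scene.

    ``area_px`` equals the rendered foreground pixel count exactly when
    the scene's noise sigma is 0.
    """

    plant_count: dict[int, int]
    area_px: dict[int, int]
    marker_coords: tuple[tuple[float, float], ...]
    overlap: bool = False

    @property
    def total_area_px(self) -> int:
        return sum(self.area_px.values())

    @property
    def total_count(self) -> int:
        return sum(self.plant_count.values())


def _default_markers() -> tuple[tuple[float, float], ...]:
    return ((20.0, 20.0), (20.0, 219.0), (219.0, 219.0), (219.0, 20.0))


@dataclass(frozen=True)
class TrayScene:
    """Scene specification for one tray image.

    ``markers`` are disc centers ordered top-left, top-right, bottom-right,
    bottom-left; the generator requires them to form an axis-aligned square
    with an even pixel side so the quadrant geometry of the ground truth is
    pixel-exact.  ``markers=None`` renders a fiducial-free (fluorescence
    style) frame whose tray region is the whole image.
    """

    side_px: int = 260
    markers: tuple[tuple[float, float], ...] | None = field(default_factory=_default_markers)
    marker_color: tuple[int, int, int] = (255, 0, 0)
    marker_radius: int = 5
    plants: tuple[PlantSpec, ...] = ()
    background: int = 20
    noise_sigma: float = 0.0
    seed: int = 0
    mode: str = "rgb"  # "rgb" or "gray"

    def __post_init__(self) -> None:
        if self.mode not in ("rgb", "gray"):
            raise ValueError(f"mode must be 'rgb' or 'gray', got {self.mode!r}")
        if self.markers is not None and len(self.markers) != 4:
            raise ValueError(f"exactly 4 markers required, got {len(self.markers)}")
        r0, r1, c0, c1 = self.tray_bounds()
        if (r1 - r0) != (c1 - c0):
            raise ValueError("marker quadrilateral must be a square")
        if (r1 - r0 + 1) % 2 != 0:
            raise ValueError("tray side (marker spacing) must span an even pixel count")
        for p in self.plants:
            if p.quadrant_id not in QUADRANT_IDS:
                raise ValueError(f"quadrant_id must be in 1..4, got {p.quadrant_id}")
            qr0, qr1, qc0, qc1 = self.quadrant_bounds(p.quadrant_id)
            rows, cols = _disc_pixels(p.center, p.radius)
            if rows.size and (
                rows.min() < qr0 or rows.max() > qr1 or cols.min() < qc0 or cols.max() > qc1
            ):
                raise ValueError(
                    f"plant disc at {p.center} r={p.radius} crosses the boundary of "
                    f"quadrant {p.quadrant_id} (tray region rows {qr0}..{qr1}, "
                    f"cols {qc0}..{qc1})"
                )

    def tray_bounds(self) -> tuple[int, int, int, int]:
        """Inclusive (row0, row1, col0, col1) of the tray region."""
        if self.markers is None:
            return 0, self.side_px - 1, 0, self.side_px - 1
        m = np.asarray(self.markers)
        return (
            int(round(m[:, 0].min())),
            int(round(m[:, 0].max())),
            int(round(m[:, 1].min())),
            int(round(m[:, 1].max())),
        )

    def quadrant_bounds(self, quadrant_id: int) -> tuple[int, int, int, int]:
        """Inclusive pixel bounds of one quadrant within the tray region."""
        r0, r1, c0, c1 = self.tray_bounds()
        half = (r1 - r0 + 1) // 2
        top = quadrant_id in (1, 2)
        left = quadrant_id in (1, 3)
        qr0 = r0 if top else r0 + half
        qc0 = c0 if left else c0 + half
        return qr0, qr0 + half - 1, qc0, qc0 + half - 1


def _disc_pixels(center: tuple[float, float], radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force rasterization: pixels with ||p - center|| <= radius."""
    if radius <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    r0 = math.floor(center[0] - radius)
    r1 = math.ceil(center[0] + radius)
    c0 = math.floor(center[1] - radius)
    c1 = math.ceil(center[1] + radius)
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[inside], cc[inside]


def render_tray(scene: TrayScene) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit image and its exact ground truth.

    Deterministic given the scene seed; at noise sigma 0 the per-quadrant
    ``area_px`` equals the rendered foreground pixel count exactly.
    """
    shape = (scene.side_px, scene.side_px, 3) if scene.mode == "rgb" else (scene.side_px, scene.side_px)
    img = np.full(shape, scene.background, dtype=np.float64)

    counts = {q: 0 for q in QUADRANT_IDS}
    areas = {q: 0 for q in QUADRANT_IDS}
    union = {q: set() for q in QUADRANT_IDS}
    overlap = False
    for p in scene.plants:
        rows, cols = _disc_pixels(p.center, p.radius)
        pix = set(zip(rows.tolist(), cols.tolist()))
        if union[p.quadrant_id] & pix:
            overlap = True
        union[p.quadrant_id] |= pix
        counts[p.quadrant_id] += 1
        if scene.mode == "rgb":
            img[rows, cols, 0] = 0
            img[rows, cols, 1] = p.intensity
            img[rows, cols, 2] = 0
        else:
            img[rows, cols] = p.intensity
    for q in QUADRANT_IDS:
        areas[q] = len(union[q])

    if scene.markers is not None and scene.mode == "rgb":
        for mc in scene.markers:
            rows, cols = _disc_pixels(mc, scene.marker_radius)
            ok = (rows >= 0) & (rows < scene.side_px) & (cols >= 0) & (cols < scene.side_px)
            img[rows[ok], cols[ok]] = scene.marker_color

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)

    gt = GroundTruth(
        plant_count=counts,
        area_px=areas,
        marker_coords=scene.markers if scene.markers is not None else (),
        overlap=overlap,
    )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), gt


@dataclass(frozen=True)
class PlantGrowth:
    """Growth schedule for one seedling.

    The rendered radius is 0 before ``germination_day`` and afterwards
    follows a logistic r(t) = r_max / (1 + exp(-rate (t - germination_day
    - t_mid))), floored at 2 px (a just-emerged cotyledon spans a few
    millimetres, and a 2 px disc rasterizes to at least 12 pixels at any
    sub-pixel center, so an emerged seedling always renders and survives
    speck filtering).
    """

    quadrant_id: int
    center: tuple[float, float]
    germination_day: float
    r_max: float = 10.0
    rate: float = 0.9  # per day
    t_mid: float = 3.0  # days after emergence to half of r_max

    def __post_init__(self) -> None:
        if self.germination_day < 0:
            raise ValueError("germination_day must be non-negative")

    def radius(self, day: float) -> float:
        if day < self.germination_day:
            return 0.0
        t = day - self.germination_day
        return max(2.0, self.r_max / (1.0 + math.exp(-self.rate * (t - self.t_mid))))


@dataclass(frozen=True)
class GrowthSchedule:
    plants: tuple[PlantGrowth, ...]
    capture_days: tuple[int, ...]
    capture_times: tuple[str, ...] = ("00:00", "05:00", "12:00", "15:00")

    def __post_init__(self) -> None:
        if list(self.capture_days) != sorted(self.capture_days):
            raise ValueError("capture days must be sorted ascending")

    def emerged_count(self, day: float) -> int:
        return sum(1 for p in self.plants if p.germination_day <= day)


@dataclass(frozen=True)
class TrayFrame:
    day: int
    time: str
    image: np.ndarray
    ground_truth: GroundTruth


def simulate_growth_series(
    schedule: GrowthSchedule, scene_template: TrayScene
) -> list[TrayFrame]:
    """Render one frame per (capture day, time of day).

    Emergence is gated on the nominal day (a seedling with germination_day
    <= day appears in all of that day's captures); the radius is evaluated
    at the fractional time day + hour/24 so within-day captures show a
    little growth, which exercises daily averaging downstream.
    """
    frames: list[TrayFrame] = []
    idx = 0
    for day in schedule.capture_days:
        for time_str in schedule.capture_times:
            hh, mm = time_str.split(":")
            t = day + (int(hh) * 60 + int(mm)) / 1440.0
            plants = tuple(
                PlantSpec(p.quadrant_id, p.center, p.radius(t))
                for p in schedule.plants
                if p.germination_day <= day
            )
            scene = replace(scene_template, plants=plants, seed=scene_template.seed + idx)
            image, gt = render_tray(scene)
            frames.append(TrayFrame(day=day, time=time_str, image=image, ground_truth=gt))
            idx += 1
    return frames


def make_calibration_image(
    object_length_cm: float, px_per_cm: float, margin_px: int = 12, bar_height_px: int = 7
) -> tuple[np.ndarray, CalibrationReference]:
    """Render a bright horizontal bar of known physical length on black.

    The bar spans round(object_length_cm * px_per_cm) pixels; the returned
    reference carries that pixel length and the cm length.
    """
    if object_length_cm <= 0 or px_per_cm <= 0:
        raise ValueError(
            f"object_length_cm and px_per_cm must be positive, got "
            f"{object_length_cm}, {px_per_cm}"
        )
    a_px = round(object_length_cm * px_per_cm)
    height = bar_height_px + 2 * margin_px
    width = a_px + 2 * margin_px
    img = np.zeros((height, width), dtype=np.uint8)
    img[margin_px : margin_px + bar_height_px, margin_px : margin_px + a_px] = 255
    return img, CalibrationReference(a=float(a_px), b=object_length_cm)


def default_growth_schedule(
    n_per_quadrant: int = 4,
    capture_days: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
    seed: int = 0,
    scene: TrayScene | None = None,
) -> GrowthSchedule:
    """A realistic tray schedule: emergence concentrated on days 3-5.

    Plants sit on a jittered grid inside each quadrant so discs stay
    inside quadrant bounds at their maximum radius.
    """
    rng = np.random.default_rng(seed)
    scene = scene or TrayScene()
    plants: list[PlantGrowth] = []
    grid = math.ceil(math.sqrt(n_per_quadrant))
    for q in QUADRANT_IDS:
        qr0, qr1, qc0, qc1 = scene.quadrant_bounds(q)
        cell = (qr1 - qr0 + 1) / grid
        r_max = max(3.0, cell / 2 - 4)
        positions = [(i, j) for i in range(grid) for j in range(grid)][:n_per_quadrant]
        for i, j in positions:
            jitter = rng.uniform(-1.5, 1.5, size=2)
            center = (
                qr0 + (i + 0.5) * cell + jitter[0],
                qc0 + (j + 0.5) * cell + jitter[1],
            )
            plants.append(
                PlantGrowth(
                    quadrant_id=q,
                    center=(float(center[0]), float(center[1])),
                    germination_day=float(rng.integers(3, 6)),
                    r_max=r_max,
                    rate=0.9,
                    t_mid=3.0,
                )
            )
    return GrowthSchedule(plants=tuple(plants), capture_days=capture_days)
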