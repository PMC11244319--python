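"""Batch orchestration: ingest -> rectify -> split -> measure -> CSV -> outbox.

Runs the whole tray-phenotyping flow over a directory of captures (or a
simulated series), appending one measurement record per quadrant per
image to a CSV, saving audit images (per-quadrant crops and binary
masks), and mirroring outputs into a local outbox directory that any
cloud-sync agent can watch.  Per-image failures are logged and skipped
so one bad capture never aborts a batch; identical inputs and seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import shutil
from dataclasses import dataclass, field
from datetime import date, datetime, time as dtime
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import fixtures, germination, growth_model, plant_analysis, tray_geometry
from .plant_analysis import CalibrationReference

logger = logging.getLogger("phenotray")

_FNAME_RE = re.compile(r"_d(\d+)_(\d{2})(\d{2})")

RECORD_COLUMNS = [
    "timestamp",
    "device_id",
    "replication",
    "day",
    "time",
    "quadrant_id",
    "cultivar",
    "n_sown",
    "plant_count",
    "area_px",
    "pcs_cm2",
    "pcs_per_plant_cm2",
    "germination_pct",
    "threshold_used",
    "flags",
]


@dataclass(frozen=True)
class QuadrantMeta:
    cultivar: str
    n_sown: int

    def __post_init__(self) -> None:
        if self.n_sown <= 0:
            raise ValueError(f"n_sown must be positive, got {self.n_sown}")


def _default_quadrants() -> dict[int, QuadrantMeta]:
    return {q: QuadrantMeta(cultivar=f"cv{q}", n_sown=4) for q in (1, 2, 3, 4)}


@dataclass
class PipelineConfig:
    """Everything one batch run needs; loadable from YAML."""

    input_dir: str = ""
    output_dir: str = "out"
    calibration_a: float | None = None  # known object, px
    calibration_b: float | None = None  # known object, cm
    calibration_image: str | None = None
    object_length_cm: float | None = None
    quadrants: dict[int, QuadrantMeta] = field(default_factory=_default_quadrants)
    method: str = "excess_green"
    fixed_threshold: float | None = None
    exg_threshold: float = 20.0
    min_area_px: int = 5
    connectivity: int = 8
    marker_color: str = "red"
    side_px: int = 200
    device_id: str = "dev0"
    replication: int = 1
    start_date: str = "2024-01-01"
    seed: int = 0
    save_audit_images: bool = True
    # simulation settings (used by the `simulate` verb)
    n_per_quadrant: int = 4
    capture_days: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    capture_times: tuple[str, ...] = ("00:00", "05:00", "12:00", "15:00")
    noise_sigma: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "quadrants" in raw:
            raw["quadrants"] = {
                int(q): QuadrantMeta(**meta) for q, meta in raw["quadrants"].items()
            }
        for key in ("capture_days", "capture_times"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def calibration(self) -> CalibrationReference:
        if self.calibration_a is not None and self.calibration_b is not None:
            return CalibrationReference(self.calibration_a, self.calibration_b)
        if self.calibration_image and self.object_length_cm:
            img = iio.imread(self.calibration_image)
            return plant_analysis.calibrate_from_image(img, self.object_length_cm)
        raise ValueError(
            "config must provide calibration_a/calibration_b or "
            "calibration_image + object_length_cm"
        )


def _timestamp(start_date: str, day: int | None, time_str: str | None) -> str:
    if day is None:
        return ""
    base = date.fromisoformat(start_date)
    hh, mm = (int(p) for p in (time_str or "00:00").split(":"))
    moment = datetime.combine(base, dtime(hh, mm)) + pd.Timedelta(days=day)
    return moment.isoformat()


def _parse_filename(path: Path) -> tuple[int | None, str | None]:
    m = _FNAME_RE.search(path.stem)
    if not m:
        return None, None
    return int(m.group(1)), f"{m.group(2)}:{m.group(3)}"


def simulate(config: PipelineConfig) -> Path:
    """Render a simulated capture series into ``input_dir`` with ground truth."""
    out = Path(config.input_dir or Path(config.output_dir) / "sim")
    out.mkdir(parents=True, exist_ok=True)
    scene = fixtures.TrayScene(noise_sigma=config.noise_sigma, seed=config.seed)
    schedule = fixtures.default_growth_schedule(
        n_per_quadrant=config.n_per_quadrant,
        capture_days=tuple(config.capture_days),
        seed=config.seed,
        scene=scene,
    )
    schedule = fixtures.GrowthSchedule(
        plants=schedule.plants,
        capture_days=schedule.capture_days,
        capture_times=tuple(config.capture_times),
    )
    frames = fixtures.simulate_growth_series(schedule, scene)
    rows = []
    for frame in frames:
        name = f"tray_d{frame.day:02d}_{frame.time.replace(':', '')}.png"
        iio.imwrite(out / name, frame.image)
        for q in fixtures.QUADRANT_IDS:
            rows.append(
                {
                    "day": frame.day,
                    "time": frame.time,
                    "quadrant_id": q,
                    "plant_count": frame.ground_truth.plant_count[q],
                    "area_px": frame.ground_truth.area_px[q],
                }
            )
    pd.DataFrame(rows).to_csv(out / "ground_truth.csv", index=False)
    return out


def analyze_image(
    image: np.ndarray, config: PipelineConfig, calib: CalibrationReference
) -> list[tuple[int, plant_analysis.CanopyMeasurement, np.ndarray]]:
    """Single-image flow: detect markers, rectify, split, measure each quadrant."""
    markers = tray_geometry.detect_markers(image, color_spec=config.marker_color)
    square = tray_geometry.rectify_to_square(image, markers, config.side_px)
    results = []
    for quad in tray_geometry.split_quadrants(square):
        meta = config.quadrants[quad.quadrant_id]
        m = plant_analysis.measure_quadrant(
            quad.image,
            calib,
            n_sown=meta.n_sown,
            method=config.method,
            fixed_threshold=config.fixed_threshold,
            exg_threshold=config.exg_threshold,
            min_area_px=config.min_area_px,
            connectivity=config.connectivity,
        )
        results.append((quad.quadrant_id, m, quad.image))
    return results


def run_analysis(config: PipelineConfig) -> pd.DataFrame:
    """Analyze every image in ``input_dir``; write records.csv and audit images.

    Unreadable or marker-less images are logged and skipped, never abort
    the batch.  Raises only when the input set is empty.
    """
    in_dir = Path(config.input_dir)
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise ValueError(f"no input images found in {in_dir}")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calib = config.calibration()

    rows = []
    n_failed = 0
    for path in paths:
        day, time_str = _parse_filename(path)
        try:
            image = iio.imread(path)
            per_quadrant = analyze_image(image, config, calib)
        except Exception as exc:  # per-image failure: log and move on
            n_failed += 1
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        for qid, m, quad_img in per_quadrant:
            logger.info(
                "%s q%d: count=%d area=%d px threshold=%.2f",
                path.name, qid, m.plant_count, m.area_px, m.threshold_used,
            )
            rows.append(
                {
                    "timestamp": _timestamp(config.start_date, day, time_str),
                    "device_id": config.device_id,
                    "replication": config.replication,
                    "day": day,
                    "time": time_str,
                    "quadrant_id": qid,
                    "cultivar": config.quadrants[qid].cultivar,
                    "n_sown": config.quadrants[qid].n_sown,
                    "plant_count": m.plant_count,
                    "area_px": m.area_px,
                    "pcs_cm2": round(m.pcs_cm2, 2),
                    "pcs_per_plant_cm2": round(m.pcs_per_plant_cm2, 2),
                    "germination_pct": round(m.germination_pct, 2),
                    "threshold_used": m.threshold_used,
                    "flags": ";".join(m.flags),
                }
            )
            if config.save_audit_images:
                audit = out_dir / "audit"
                audit.mkdir(exist_ok=True)
                iio.imwrite(audit / f"{path.stem}_q{qid}.png", quad_img)
    if n_failed:
        logger.warning("%d of %d images failed and were skipped", n_failed, len(paths))
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(out_dir / "records.csv", index=False)
    return df


def summarize_daily(records: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Collapse repeated within-day captures to daily per-quadrant rows.

    Projected canopy size and germination are averaged over the day's
    captures; cumulative germination per quadrant applies a running max
    across days (a germinated seed cannot un-germinate).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    required = {"day", "quadrant_id", "pcs_cm2", "germination_pct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records CSV is missing columns: {sorted(missing)}")
    bad = records.index[records["day"].isna()].tolist()
    if bad:
        raise ValueError(f"rows without a parseable day: {bad}")
    rows = []
    for (day, qid), grp in records.groupby(["day", "quadrant_id"], sort=True):
        pcs, n_cap = growth_model.daily_average(grp["pcs_cm2"].tolist())
        germ, _ = growth_model.daily_average(grp["germination_pct"].tolist())
        rows.append(
            {
                "day": int(day),
                "quadrant_id": int(qid),
                "cultivar": grp["cultivar"].iloc[0] if "cultivar" in grp else "",
                "n_sown": int(grp["n_sown"].iloc[0]) if "n_sown" in grp else 0,
                "n_captures": n_cap,
                "pcs_cm2": round(pcs, 4) if pcs is not None else float("nan"),
                "plant_count": float(grp["plant_count"].mean()) if "plant_count" in grp else float("nan"),
                "germination_pct": round(germ, 4) if germ is not None else float("nan"),
            }
        )
    daily = pd.DataFrame(rows).sort_values(["quadrant_id", "day"]).reset_index(drop=True)
    daily["germination_pct_cum"] = daily.groupby("quadrant_id")["germination_pct"].cummax()
    return daily


def build_quadrant_series(daily: pd.DataFrame, quadrant_id: int) -> germination.GerminationSeries:
    """Cumulative germination series for one quadrant of a daily summary."""
    sub = daily[daily["quadrant_id"] == quadrant_id].sort_values("day")
    return germination.build_series(
        sub["day"].to_numpy(),
        sub["germination_pct"].to_numpy(),
        n_sown=int(sub["n_sown"].iloc[0]) if sub["n_sown"].iloc[0] else 1,
        cultivar=str(sub["cultivar"].iloc[0]),
        values_are="percent",
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def sync_outbox(output_dir: str | Path, outbox_dir: str | Path) -> list[dict]:
    """Idempotently mirror new/changed artifacts into a local outbox.

    Returns the manifest of files copied in this run (relative path, size,
    sha256) and writes it to ``outbox/manifest.json``.  A second run with
    no changes copies nothing.
    """
    output_dir = Path(output_dir)
    outbox_dir = Path(outbox_dir)
    if not output_dir.is_dir():
        raise ValueError(f"output directory {output_dir} does not exist")
    outbox_dir.mkdir(parents=True, exist_ok=True)
    copied = []
    for src in sorted(p for p in output_dir.rglob("*") if p.is_file()):
        rel = src.relative_to(output_dir)
        dst = outbox_dir / rel
        checksum = _sha256(src)
        if dst.exists() and _sha256(dst) == checksum:
            continue
        dst.parent.mkdir(parents=True, exist_ok=True)
        shutil.copy2(src, dst)
        copied.append({"path": str(rel), "size": src.stat().st_size, "sha256": checksum})
    (outbox_dir / "manifest.json").write_text(json.dumps(copied, indent=2))
    return copied
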