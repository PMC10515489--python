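"""CSV/image plumbing shared by the CLI and the library surface.

All tables are comma-separated UTF-8 with a mandatory header row and a
"." decimal separator; units are spelled out in the column names (mm,
mm2, mm3, g, cm3) to prevent silent unit bugs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .evaluation import MixtureRecord
from .shape_metrics import (
    FIBER_ASPECT_THRESHOLD,
    ParticleMask,
    measure_fiber,
    measure_particle,
)

log = logging.getLogger(__name__)

__all__ = [
    "METRICS_COLUMNS",
    "MEASUREMENTS_COLUMNS",
    "measure_masks",
    "read_image",
    "write_metrics",
    "read_metrics",
    "records_from_tables",
    "write_mask_png",
]

METRICS_COLUMNS = [
    "id", "image", "area_mm2", "perimeter_mm", "major_mm", "minor_mm",
    "feret_mm", "circularity", "aspect_ratio", "orientation_deg",
    "is_fiber", "fiber_length_mm", "fiber_width_mm",
]
MEASUREMENTS_COLUMNS = ["group", "batch", "throw", "measured_volume", "unit", "method"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG image as a 2D grayscale array."""
    img = iio.imread(path)
    if img.ndim == 3:  # RGB(A) -> luminance
        img = img[..., :3].astype(float).mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {img.shape}")
    return img


def measure_masks(masks: list[ParticleMask], fiber_mode: bool = False) -> pd.DataFrame:
    """Per-particle metrics table for a list of masks.

    In fiber mode, components with aspect ratio at or above the fiber
    threshold are additionally measured with the skeleton-based fiber
    metrics and tagged ``is_fiber``.
    """
    rows = []
    for mask in masks:
        p = measure_particle(mask)
        row = {
            "id": p.particle_id, "image": mask.image_id,
            "area_mm2": p.area_mm2, "perimeter_mm": p.perimeter_mm,
            "major_mm": p.major_mm, "minor_mm": p.minor_mm,
            "feret_mm": p.feret_mm, "circularity": p.circularity,
            "aspect_ratio": p.aspect_ratio, "orientation_deg": p.orientation_deg,
            "is_fiber": False, "fiber_length_mm": np.nan, "fiber_width_mm": np.nan,
        }
        if fiber_mode and not p.degenerate and p.aspect_ratio >= FIBER_ASPECT_THRESHOLD:
            fib = measure_fiber(mask)
            row.update(is_fiber=True, fiber_length_mm=fib.length_mm,
                       fiber_width_mm=fib.width_mm)
        rows.append(row)
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("area_mm2", "major_mm", "minor_mm") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metrics columns {missing}")
    return df


def records_from_tables(metrics: pd.DataFrame, measurements: pd.DataFrame) -> list[MixtureRecord]:
    """Join a metrics table (tagged group/batch/throw) with measured volumes."""
    for col in ("group", "batch", "throw"):
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks the {col!r} column needed for the join")
    missing = [c for c in MEASUREMENTS_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurements table missing columns {missing}")
    records = []
    for _, m in measurements.iterrows():
        sel = metrics[
            (metrics["group"] == m["group"])
            & (metrics["batch"] == m["batch"])
            & (metrics["throw"] == m["throw"])
        ]
        if len(sel) == 0:
            log.warning("no particles for %s batch %s throw %s; skipped",
                        m["group"], m["batch"], m["throw"])
            continue
        records.append(MixtureRecord(
            group=str(m["group"]), batch=int(m["batch"]), throw=int(m["throw"]),
            particles=sel.reset_index(drop=True),
            measured_volume=float(m["measured_volume"]),
            unit=str(m["unit"]), method=str(m["method"]),
        ))
    return records


def write_mask_png(mask: ParticleMask, path: str | Path) -> None:
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))


def compose_canvas(masks: list[ParticleMask], gap_px: int = 12) -> np.ndarray:
    """Place masks on one shared canvas in a non-touching grid (row-major)."""
    if not masks:
        return np.zeros((8, 8), dtype=np.uint8)
    ncol = int(np.ceil(np.sqrt(len(masks))))
    hs = [m.pixels.shape[0] for m in masks]
    ws = [m.pixels.shape[1] for m in masks]
    cell_h, cell_w = max(hs) + gap_px, max(ws) + gap_px
    nrow = int(np.ceil(len(masks) / ncol))
    canvas = np.zeros((nrow * cell_h + gap_px, ncol * cell_w + gap_px), dtype=np.uint8)
    for k, m in enumerate(masks):
        r, c = divmod(k, ncol)
        r0 = gap_px + r * cell_h
        c0 = gap_px + c * cell_w
        h, w = m.pixels.shape
        canvas[r0:r0 + h, c0:c0 + w] |= m.pixels.astype(np.uint8)
    return canvas * 255
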