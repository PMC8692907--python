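"""Per-image vessel metrics: fill fraction, count, diameter, tortuosity.

Definitions
-----------
*Fill fraction* — vessel (foreground) area over total imaged area, %.

*Vessel count* — number of metric-eligible centerline segments after
spur pruning and minimum-length filtering.

*Diameter* — per segment, twice the mean distance-transform radius over
path points lying at least one local radius away from the segment ends
(near an end the distance transform reads the cap, not the tube wall,
and biases the estimate low).  Segments too short to exclude their ends
fall back to all points and are flagged.

*Tortuosity* — sum of absolute turning angles along the centerline
divided by arc length, in °/µm.  The raw 8-connected pixel chain
quantizes directions to multiples of 45°, which would make the angle
sum resolution-dependent, so the path is first resampled at a uniform
arc-length step (default 2× pixel size); turning angles are then
measured between consecutive chord directions.  Absolute values in
°/µm depend on the resampling step, which is therefore recorded with
every run; contrasts between groups processed identically are
step-independent to first order.

Per-image summaries use the *median* across segments; means ± SD are
formed only at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vasoquant.imaging_io import RasterImage
from vasoquant.preprocess import hb_content
from vasoquant.segmentation import VesselMask
from vasoquant.vessel_graph import VesselGraph, VesselSegment

__all__ = [
    "MetricsRecord",
    "fill_fraction",
    "segment_diameter",
    "segment_tortuosity",
    "resample_path",
    "turning_angles_deg",
    "summarize_image",
]


@dataclass
class MetricsRecord:
    """Summary metrics for one image plus its per-segment table."""

    image_id: str
    group: str = ""
    mouse: str = ""
    location: str = ""
    hb_content_au_per_mm2: float | None = None
    fill_fraction_pct: float = 0.0
    vessel_count: int = 0
    median_diameter_um: float | None = None
    median_tortuosity_deg_per_um: float | None = None
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "group": self.group,
            "mouse": self.mouse,
            "location": self.location,
            "hb_content_au_per_mm2": self.hb_content_au_per_mm2,
            "fill_fraction_pct": self.fill_fraction_pct,
            "vessel_count": self.vessel_count,
            "median_diameter_um": self.median_diameter_um,
            "median_tortuosity_deg_per_um": self.median_tortuosity_deg_per_um,
        }


def fill_fraction(mask: VesselMask) -> float:
    """Percentage of foreground pixels: 100 · |mask| / total pixels."""
    return 100.0 * float(np.count_nonzero(mask.mask)) / mask.mask.size


def segment_diameter(segment: VesselSegment) -> tuple[float, bool]:
    """Mean diameter of a segment from its centerline radii.

    Returns ``(diameter_um, used_all_points)``: twice the mean radius
    over interior points (arc distance from either end >= the point's
    own radius); ``used_all_points`` is True when the segment was too
    short to exclude its ends and all points were used instead.
    """
    if segment.radii_um is None:
        raise ValueError("segment has no radii; build the graph from a mask first")
    radii = np.asarray(segment.radii_um, dtype=float)
    steps = np.diff(segment.path.astype(float), axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1]) * segment.pixel_size_um
    arc = np.concatenate([[0.0], np.cumsum(step_len)])
    total = arc[-1]
    interior = (arc >= radii) & ((total - arc) >= radii)
    if interior.any():
        return 2.0 * float(radii[interior].mean()), False
    return 2.0 * float(radii.mean()), True


def resample_path(path_um: np.ndarray, step_um: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing.

    Input and output are (n, 2) arrays in µm.  The final point is always
    retained, so the last spacing may be shorter than ``step_um``.
    """
    path_um = np.asarray(path_um, dtype=float)
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    seg = np.diff(path_um, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    if total == 0:
        return path_um[:1].copy()
    n_steps = int(total / step_um)
    targets = np.arange(n_steps + 1) * step_um
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    ys = np.interp(targets, arc, path_um[:, 0])
    xs = np.interp(targets, arc, path_um[:, 1])
    return np.column_stack([ys, xs])


def turning_angles_deg(poly_um: np.ndarray) -> np.ndarray:
    """Absolute turning angle (deg) at each interior vertex of a polyline."""
    poly_um = np.asarray(poly_um, dtype=float)
    if len(poly_um) < 3:
        return np.empty(0)
    v = np.diff(poly_um, axis=0)
    keep = np.hypot(v[:, 0], v[:, 1]) > 0
    v = v[keep]
    if len(v) < 2:
        return np.empty(0)
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = (v[:-1] * v[1:]).sum(axis=1)
    return np.degrees(np.abs(np.arctan2(cross, dot)))


def segment_tortuosity(
    segment: VesselSegment | np.ndarray,
    resample_step_um: float,
    pixel_size_um: float | None = None,
) -> tuple[float | None, float | None]:
    """Tortuosity of a centerline: Σ|turning angle| / length, in °/µm.

    Accepts a :class:`VesselSegment` or a raw (n, 2) µm polyline.
    Returns ``(tortuosity_deg_per_um, angle_sum_deg)``; both are ``None``
    when the path is shorter than two resampling steps, in which case
    the segment is excluded from per-image medians.
    """
    if isinstance(segment, VesselSegment):
        path_um = segment.path_um
    else:
        path_um = np.asarray(segment, dtype=float)
        if pixel_size_um is not None:
            path_um = path_um * pixel_size_um
    seg = np.diff(path_um, axis=0)
    total = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if total < 2 * resample_step_um:
        return None, None
    poly = resample_path(path_um, resample_step_um)
    if len(poly) < 3:
        return None, None
    angles = turning_angles_deg(poly)
    angle_sum = float(angles.sum())
    length = float(np.hypot(*np.diff(poly, axis=0).T).sum())
    return angle_sum / length, angle_sum


def summarize_image(
    graph: VesselGraph,
    mask: VesselMask,
    raw: RasterImage | None = None,
    labels: dict[str, str] | None = None,
    resample_step_um: float | None = None,
) -> MetricsRecord:
    """Assemble the per-image metrics record.

    Hb content is filled only when a raw intensity image is supplied
    (externally binarized fluorescence whole-mounts have no meaningful
    intensity sum).  Diameter and tortuosity are medians across
    metric-eligible segments; an empty graph yields count 0 with absent
    medians while the fill fraction is still computed.
    """
    labels = labels or {}
    if resample_step_um is None:
        resample_step_um = 2 * graph.pixel_size_um

    rows = []
    for s in graph.metric_segments:
        diam, used_all = segment_diameter(s)
        tort, angle_sum = segment_tortuosity(s, resample_step_um)
        s.mean_diameter_um = diam
        s.tortuosity_deg_per_um = tort
        s.angle_sum_deg = angle_sum
        rows.append(
            {
                "segment_id": s.segment_id,
                "length_um": s.length_um,
                "mean_diameter_um": diam,
                "tortuosity_deg_per_um": tort,
                "angle_sum_deg": angle_sum,
                "diameter_used_all_points": used_all,
            }
        )
    seg_table = pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "length_um",
            "mean_diameter_um",
            "tortuosity_deg_per_um",
            "angle_sum_deg",
            "diameter_used_all_points",
        ],
    )

    def _median(col: str) -> float | None:
        if seg_table.empty:
            return None
        vals = seg_table[col].dropna()
        return float(vals.median()) if len(vals) else None

    return MetricsRecord(
        image_id=labels.get("image_id", ""),
        group=labels.get("group", ""),
        mouse=labels.get("mouse", ""),
        location=labels.get("location", ""),
        hb_content_au_per_mm2=None if raw is None else hb_content(raw),
        fill_fraction_pct=fill_fraction(mask),
        vessel_count=len(graph.metric_segments),
        median_diameter_um=_median("mean_diameter_um"),
        median_tortuosity_deg_per_um=_median("tortuosity_deg_per_um"),
        segments=seg_table,
    )
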