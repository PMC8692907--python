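"""End-to-end pipeline orchestration: manifest in, metrics + stats out.

Per image the stages run in acquisition order: depth MIP (volumes) →
Hb content on the raw projection → contrast enhancement → binarization
→ skeletonization and graph extraction → per-image metrics.  Records
are then aggregated and every parameter compared between the two groups
named in the manifest.

The full configuration, package version and per-stage outputs are
serialized into a JSON run report so any run is reproducible from its
report alone.  Images that fail are logged, skipped, and listed in the
report with a nonzero ``n_failed`` summary flag.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

import vasoquant
from vasoquant.imaging_io import RasterImage, read_volume, read_image, compute_mip
from vasoquant.preprocess import EnhanceParams, enhance
from vasoquant.segmentation import binarize
from vasoquant.vessel_graph import skeletonize_mask, build_graph, overlay_labels
from vasoquant.metrics import MetricsRecord, summarize_image
from vasoquant.stats import compare_all_parameters

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "process_image", "validate_report"]

MANIFEST_COLUMNS = ["path", "group", "mouse", "location", "pixel_size_um", "modality"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``manifest`` is a CSV with columns path, group, mouse, location,
    pixel_size_um, modality ∈ {lsom, whole_mount}; lsom inputs are TIFF
    stacks projected along depth, whole_mount inputs are 2D images for
    which Hb content is not computed (their intensities are stain
    fluorescence, not hemoglobin absorption).
    """

    manifest: str
    output_dir: str
    clahe_tile: int = 8
    clahe_clip: float = 0.01
    smooth_sigma_um: float | None = None
    binarize_method: str = "otsu"
    sensitivity: float = 0.5
    min_object_px: int | None = None
    adaptive_window_um: float = 200.0
    prune_len_um: float = 22.5
    min_segment_um: float | None = None
    resample_step_um: float | None = None
    axial_spacing_um: float = 50.0
    stats_level: str = "per_location"
    welch: bool = False
    write_overlays: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def process_image(
    image: RasterImage, config: RunConfig, labels: dict[str, str] | None = None,
    with_hb: bool = True,
):
    """Run all analysis stages on one raw 2D image.

    Returns ``(record, mask, graph, enhanced)``.
    """
    params = EnhanceParams(
        clahe_tile=config.clahe_tile,
        clahe_clip=config.clahe_clip,
        smooth_sigma_um=config.smooth_sigma_um,
    )
    enhanced = enhance(image, params)
    mask = binarize(
        enhanced,
        method=config.binarize_method,
        sensitivity=config.sensitivity,
        min_object_px=config.min_object_px,
        window_um=config.adaptive_window_um,
    )
    graph = build_graph(
        skeletonize_mask(mask),
        mask,
        prune_len_um=config.prune_len_um,
        min_segment_um=config.min_segment_um,
    )
    record = summarize_image(
        graph,
        mask,
        raw=image if with_hb else None,
        labels=labels,
        resample_step_um=config.resample_step_um,
    )
    return record, mask, graph, enhanced


def _load_manifest(path: Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"group": str, "mouse": str, "location": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    bad = set(manifest["modality"]) - {"lsom", "whole_mount"}
    if bad:
        raise ValueError(f"unknown modality values: {sorted(bad)}")
    return manifest


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline for every manifest row; write CSVs and a report."""
    t0 = time.perf_counter()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(Path(config.manifest))

    records: list[MetricsRecord] = []
    seg_tables: list[pd.DataFrame] = []
    failures: list[dict] = []
    timings: list[dict] = []

    for idx, row in manifest.iterrows():
        image_id = Path(str(row["path"])).stem
        labels = {
            "image_id": image_id,
            "group": str(row["group"]),
            "mouse": str(row["mouse"]),
            "location": str(row["location"]),
        }
        t_img = time.perf_counter()
        try:
            px_um = float(row["pixel_size_um"])
            if row["modality"] == "lsom":
                axial = float(row.get("axial_spacing_um", config.axial_spacing_um) or config.axial_spacing_um)
                volume = read_volume(row["path"], px_um, axial)
                raw = compute_mip(volume)
                with_hb = True
            else:
                raw = read_image(row["path"], px_um)
                with_hb = False
            record, mask, graph, _ = process_image(raw, config, labels, with_hb)
        except Exception as exc:  # per-image failure: log, record, continue
            logger.exception("image %s failed", image_id)
            failures.append({"image_id": image_id, "path": str(row["path"]), "error": str(exc)})
            continue
        records.append(record)
        seg = record.segments.copy()
        seg.insert(0, "image_id", image_id)
        seg_tables.append(seg)
        timings.append(
            {"image_id": image_id, "seconds": round(time.perf_counter() - t_img, 4)}
        )
        tifffile.imwrite(
            out_dir / f"{image_id}_mask.tif",
            (mask.mask.astype(np.uint8) * 255),
        )
        if config.write_overlays:
            tifffile.imwrite(
                out_dir / f"{image_id}_overlay.tif", overlay_labels(graph, mask)
            )
            with open(out_dir / f"{image_id}_graph.json", "w") as fh:
                json.dump(graph.to_dict(), fh)

    if not records:
        raise RuntimeError("all manifest images failed; nothing to report")

    metrics_df = pd.DataFrame([r.to_row() for r in records])
    metrics_df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")
    segments_df = (
        pd.concat(seg_tables, ignore_index=True) if seg_tables else pd.DataFrame()
    )
    segments_df.to_csv(out_dir / "segments.csv", index=False, float_format="%.10g")

    groups = sorted(metrics_df["group"].unique())
    comparisons = []
    if len(groups) == 2:
        comparisons = compare_all_parameters(
            metrics_df, groups[0], groups[1],
            level=config.stats_level, welch=config.welch,
        )
        pd.DataFrame([c.to_row() for c in comparisons]).to_csv(
            out_dir / "comparisons.csv", index=False, float_format="%.10g"
        )

    report = {
        "tool": "vasoquant",
        "version": vasoquant.__version__,
        "config": config.to_dict(),
        "n_images": int(len(records)),
        "n_failed": int(len(failures)),
        "failures": failures,
        "groups": groups,
        "outputs": {
            "metrics_csv": "metrics.csv",
            "segments_csv": "segments.csv",
            "comparisons_csv": "comparisons.csv" if comparisons else None,
        },
        "comparisons": [c.to_row() for c in comparisons],
        "timings": timings,
        "total_seconds": round(time.perf_counter() - t0, 4),
    }
    validate_report(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


# --- report schema -----------------------------------------------------------

def _schema() -> dict:
    schema_path = Path(__file__).with_name("report_schema.json")
    return json.loads(schema_path.read_text())


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check(instance, schema: dict, where: str) -> list[str]:
    errors = []
    typ = schema.get("type")
    if typ:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(
            (instance is None and t == "null")
            or (t in _TYPES and isinstance(instance, _TYPES[t])
                and not (t in ("number", "integer") and isinstance(instance, bool)))
            for t in allowed
        ):
            return [f"{where}: expected {typ}, got {type(instance).__name__}"]
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                errors.append(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                errors.extend(_check(instance[key], sub, f"{where}.{key}"))
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            errors.extend(_check(item, schema["items"], f"{where}[{i}]"))
    return errors


def validate_report(report: dict) -> None:
    """Validate a run report against the bundled schema.

    Covers the schema subset the report uses: type, required,
    properties, items.  Raises ``ValueError`` listing all violations.
    """
    errors = _check(report, _schema(), "report")
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))
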