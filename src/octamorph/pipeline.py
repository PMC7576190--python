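"""End-to-end orchestration: config, manifest, and the per-cohort pipeline.

Stages run in order per eye and layer: binarize → central crop → skeleton →
graph → regional metrics; the statistics stage then joins the metric table
to the clinical table. A failed eye is reported and skipped without
aborting the cohort, and every run writes its resolved configuration and a
manifest (input checksums, per-stage status) next to the outputs. Given
identical inputs, config and seeds, the metric CSVs are byte-identical
across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .images import AngioImage, read_angiogram
from .metrics import MorphometricRecord, records_to_frame, summarize_region
from .regions import OrientationConvention, assign_clinical_labels, crop_center
from .segmentation import PixelClassifier, binarize
from .skeleton import build_graph, skeletonize
from .stats import group_comparisons, regression_table


@dataclass
class PipelineConfig:
    scan_width_mm: float = 6.0
    crop_mm: float = 3.0
    superior_at: str = "top"
    segmentation_method: str = "otsu"  # classifier | otsu | fixed
    fixed_threshold: float | None = None
    seed: int = 0
    min_object_px: int = 0
    va_change_convention: str = "final_minus_baseline"
    out_dir: str = "."

    @property
    def orientation(self) -> OrientationConvention:
        return OrientationConvention(self.superior_at)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class RunManifest:
    inputs: dict[str, str] = field(default_factory=dict)   # path → sha256
    outputs: dict[str, str] = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_eye(image: AngioImage, *, eye_id: str, occluded_half: str = "none",
                config: PipelineConfig = PipelineConfig(),
                classifier: PixelClassifier | None = None,
                ) -> list[MorphometricRecord]:
    """Metrics for the full crop and both labeled hemifields of one layer."""
    mask = binarize(image, classifier=classifier,
                    method=config.segmentation_method,
                    threshold=config.fixed_threshold,
                    min_object_px=config.min_object_px)
    mask = crop_center(mask, config.crop_mm)
    skel = skeletonize(mask)
    graph = build_graph(skel)
    labels = assign_clinical_labels(
        occluded_half, is_rvo_hemifield=occluded_half in ("superior", "inferior"))
    records = [summarize_region(mask, graph, eye_id=eye_id, half="full",
                                orientation=config.orientation)]
    for half in ("superior", "inferior"):
        records.append(summarize_region(
            mask, graph, eye_id=eye_id, half=half,
            region_label=labels[half], orientation=config.orientation))
    return records


def run_pipeline(image_paths: dict[str, dict], clinical_csv: str | Path | None,
                 config: PipelineConfig, out_dir: str | Path,
                 classifiers: dict[str, PixelClassifier] | None = None,
                 ) -> dict:
    """Run the cohort pipeline.

    ``image_paths`` maps eye_id → {"path": ..., "layer": "SCP"/"DCP",
    "occluded_half": ...}. Emits metrics.csv, stats CSVs (when a clinical
    table is given), the resolved config, and a run manifest; returns the
    in-memory tables. Per-eye failures are recorded in the manifest instead
    of aborting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(started=datetime.now(timezone.utc).isoformat())
    records: list[MorphometricRecord] = []
    for eye_id in sorted(image_paths):
        entry = image_paths[eye_id]
        path = entry["path"]
        try:
            manifest.inputs[str(path)] = sha256_file(path)
            img = read_angiogram(path, layer_tag=entry.get("layer", "SCP"),
                                 scan_width_mm=config.scan_width_mm)
            cls = (classifiers or {}).get(entry.get("layer", "SCP"))
            records.extend(analyze_eye(
                img, eye_id=eye_id,
                occluded_half=entry.get("occluded_half", "none"),
                config=config, classifier=cls))
        except Exception as exc:  # noqa: BLE001 — per-eye fault isolation
            manifest.errors.append({"eye_id": eye_id, "error": str(exc)})
    metrics = records_to_frame(records)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.6f")
    manifest.outputs[str(metrics_path)] = sha256_file(metrics_path)

    result = {"metrics": metrics, "n_failed": len(manifest.errors)}
    if clinical_csv is not None:
        clinical = pd.read_csv(clinical_csv)
        required = {"eye_id", "group", "patient_id"}
        missing = required - set(clinical.columns)
        if missing:
            raise ValueError(f"clinical CSV missing column(s): {sorted(missing)}")
        manifest.inputs[str(clinical_csv)] = sha256_file(clinical_csv)
        comparisons = group_comparisons(metrics, clinical)
        comparisons.to_csv(out / "group_comparisons.csv", index=False,
                           float_format="%.6g")
        result["comparisons"] = comparisons
        merged = metrics.merge(clinical, on="eye_id", how="inner")
        from .metrics import METRIC_COLUMNS
        from .stats import va_change

        reg_frames = []
        if {"va_1yr", "va_baseline"} <= set(merged.columns):
            merged = merged.assign(va_change=va_change(
                merged["va_1yr"], merged["va_baseline"],
                config.va_change_convention))
        for outcome in ("va_octa_day", "va_1yr", "va_change"):
            if outcome not in merged.columns:
                continue
            for (layer, region), sub in merged.groupby(["layer", "region"]):
                try:
                    tab = regression_table(sub, METRIC_COLUMNS, outcome)
                except ValueError:
                    continue
                tab.insert(0, "outcome", outcome)
                tab.insert(1, "layer", layer)
                tab.insert(2, "region", region)
                reg_frames.append(tab)
        if reg_frames:
            regressions = pd.concat(reg_frames, ignore_index=True)
            regressions.to_csv(out / "regressions.csv", index=False,
                               float_format="%.6g")
            result["regressions"] = regressions

    config.to_yaml(out / "config.yaml")
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return result
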