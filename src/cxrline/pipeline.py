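"""End-to-end orchestration: crop -> [external segmenter] -> restore ->
postprocess -> tip -> evaluate, plus the method-comparison harness.

The CNN segmenter is an external interface: any program mapping a cropped
image to a binary mask of the same shape. For testing, the phantom module's
degraded prediction stands in for it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .connect import BDConnectParams, bidirectional_connect
from .errors import CxrlineError, EmptyMaskError
from .guidance import (
    CropFootprint,
    SearchBoxSpec,
    crop,
    define_search_region,
    restore_to_original,
    trachea_roi,
)
from .metrics import EvalRecord, assd, dsc, extract_tip, summarize, tip_distance
from .phantom import PhantomParams, generate_phantom
from .raster import BinaryMask, PointRC, RasterGrid, centroid, largest_component

__all__ = [
    "PipelineConfig",
    "METHODS",
    "run_crop",
    "apply_method",
    "run_postprocess",
    "evaluate_samples",
    "run_compare",
    "write_report",
]

METHODS = ("none", "largest_cc", "bd_connect")


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline; YAML keys mirror field names."""

    search_box: SearchBoxSpec = field(default_factory=SearchBoxSpec)
    bd_params: BDConnectParams = field(default_factory=BDConnectParams)
    spacing_mm: tuple[float, float] | str = "from-header"
    postprocess_method: str = "bd_connect"

    def __post_init__(self) -> None:
        if self.postprocess_method not in METHODS:
            raise CxrlineError(
                f"postprocess_method must be one of {METHODS}, got {self.postprocess_method!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "search_box" in raw:
            kwargs["search_box"] = SearchBoxSpec(**raw["search_box"])
        if "bd_params" in raw:
            kwargs["bd_params"] = BDConnectParams(**raw["bd_params"])
        if "spacing_mm" in raw:
            v = raw["spacing_mm"]
            kwargs["spacing_mm"] = v if isinstance(v, str) else tuple(v)
        if "postprocess_method" in raw:
            kwargs["postprocess_method"] = raw["postprocess_method"]
        return cls(**kwargs)


def run_crop(
    image: RasterGrid | BinaryMask,
    trachea_mask: BinaryMask,
    config: PipelineConfig | None = None,
) -> tuple[RasterGrid | BinaryMask, CropFootprint]:
    """Trachea-guided crop of an image (or ground-truth mask)."""
    config = config or PipelineConfig()
    roi = trachea_roi(trachea_mask)
    bbox = define_search_region(centroid(roi), image, config.search_box)
    return crop(image, bbox)


def apply_method(prediction: BinaryMask, method: str, bd_params: BDConnectParams) -> BinaryMask:
    """One of the three comparison variants: passthrough, largest CC, BD Connect."""
    if method == "none":
        return prediction
    if method == "largest_cc":
        return largest_component(prediction)
    if method == "bd_connect":
        return bidirectional_connect(prediction, bd_params)
    raise CxrlineError(f"unknown postprocess method {method!r}")


def run_postprocess(
    prediction: BinaryMask,
    footprint: CropFootprint | None = None,
    config: PipelineConfig | None = None,
) -> tuple[BinaryMask, PointRC]:
    """Restore (if a footprint is given), postprocess, and extract the tip."""
    config = config or PipelineConfig()
    if prediction.is_empty:
        raise EmptyMaskError("empty prediction mask")
    full = restore_to_original(prediction, footprint) if footprint else prediction
    final = apply_method(full, config.postprocess_method, config.bd_params)
    return final, extract_tip(final)


def evaluate_samples(
    samples: list[dict],
    methods: list[str],
    config: PipelineConfig | None = None,
) -> dict:
    """Score every (sample, method) pair against its ground truth.

    Samples are dicts with ``id``, ``gt_mask``, ``prediction`` and
    ``true_tip`` (the format produced by the phantom manifest loader).
    Empty final masks are recorded as failures, never as zero error.
    """
    config = config or PipelineConfig()
    records: list[EvalRecord] = []
    failures: list[dict] = []
    for s in samples:
        gt: BinaryMask = s["gt_mask"]
        true_tip: PointRC = s.get("true_tip") or extract_tip(gt)
        for method in methods:
            try:
                final = apply_method(s["prediction"], method, config.bd_params)
                records.append(
                    EvalRecord(
                        sample_id=s["id"],
                        method_label=method,
                        assd_mm=assd(final, gt),
                        tip_distance_mm=tip_distance(
                            extract_tip(final), true_tip, gt.spacing_mm
                        ),
                        dsc=dsc(final, gt),
                    )
                )
            except CxrlineError as exc:
                failures.append({"id": s["id"], "method": method, "error": str(exc)})
    report = {
        "records": records,
        "failures": failures,
        "summary": summarize(records) if records else {},
    }
    return report


def run_compare(
    n: int = 50,
    seed: int = 0,
    params: PhantomParams | None = None,
    config: PipelineConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> dict:
    """Generate a seeded phantom set and compare the postprocessing variants."""
    base = params or PhantomParams()
    samples = []
    for i in range(n):
        p = PhantomParams(**{**_params_dict(base), "seed": seed + i})
        sample = generate_phantom(p)
        samples.append(
            {
                "id": f"phantom_{i:04d}",
                "gt_mask": sample.gt_mask,
                "prediction": sample.prediction,
                "true_tip": sample.true_tip,
            }
        )
    return evaluate_samples(samples, list(methods), config)


def _params_dict(params: PhantomParams) -> dict:
    from dataclasses import asdict

    d = asdict(params)
    d["shape_px"] = tuple(d["shape_px"])
    d["spacing_mm"] = tuple(d["spacing_mm"])
    d["gap_len_px_range"] = tuple(d["gap_len_px_range"])
    return d


def write_report(report: dict, out_dir: str | Path, stem: str = "evaluation") -> None:
    """Serialize an evaluation report as JSON + CSV (one row per record)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "records": [
            {
                "sample_id": r.sample_id,
                "method": r.method_label,
                "assd_mm": r.assd_mm,
                "tip_distance_mm": r.tip_distance_mm,
                "dsc": r.dsc,
            }
            for r in report["records"]
        ],
        "failures": report["failures"],
        "summary": report["summary"],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    with open(out_dir / f"{stem}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "method", "assd_mm", "tip_distance_mm", "dsc"])
        for r in payload["records"]:
            writer.writerow(
                [r["sample_id"], r["method"], repr(r["assd_mm"]),
                 repr(r["tip_distance_mm"]), repr(r["dsc"])]
            )
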