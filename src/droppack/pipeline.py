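"""End-to-end orchestration: image(s) -> segmentation -> packing -> heatmaps.

``run_pipeline`` drives the whole chain for one or more first-layer images,
writing per-print region and triangle tables, a summary JSON, the resolved
configuration (so every default actually used is auditable) and a one-line-
per-stage log. When several prints and an idealised layout are supplied, the
prints are co-registered and the packing-type heatmap binning runs as well.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import StageError
from .heatmap import (
    HexLayout,
    RigidTransform,
    accumulate,
    bin_hexagonal,
    rasterize_class_map,
    register_to_reference,
)
from .packing import CLASSES, Thresholds, analyze_network
from .segmentation import SegmentationParams, classify_regions, segment_network
from .synthetic import load_image

__all__ = ["RunConfig", "run_pipeline", "load_layout"]

log = logging.getLogger("droppack")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Classifier thresholds default to the standard rule set; overriding them
    marks the summary JSON ``non_standard_thresholds``.
    """

    inputs: list
    output_dir: str
    n_t: int | None = None
    pixel_size_um: float | None = None
    ridge_scale_px: float = 2.0
    gap_close_px: int = 3
    min_region_px2: float = 5.0
    thresholds: Thresholds = field(default_factory=Thresholds)
    reference_layout: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d


def load_layout(path) -> HexLayout:
    """Read an idealised layout JSON: {"centers": [[x, y], ...], "spacing": s}."""
    raw = json.loads(Path(path).read_text())
    return HexLayout(
        centers=np.asarray(raw["centers"], dtype=float),
        spacing=float(raw["spacing"]),
        orientation_deg=float(raw.get("orientation_deg", 0.0)),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run segment -> classify -> summarise (-> heatmap) over all inputs.

    Returns the summary dict that is also written to ``summary.json``.
    A stage failure removes any partial outputs and raises
    :class:`StageError` naming the stage and input.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seg_params = SegmentationParams(
        ridge_scale_px=config.ridge_scale_px,
        gap_close_px=config.gap_close_px,
        min_region_px2=config.min_region_px2,
    )

    def _write_csv(df: pd.DataFrame, path: Path):
        df.to_csv(path, index=False)
        written.append(path)

    log_lines = []

    def _log(line: str):
        log.info(line)
        log_lines.append(line)

    summary = {
        "prints": {},
        "non_standard_thresholds": not config.thresholds.is_standard,
    }
    prints = []
    try:
        for input_path in config.inputs:
            stem = Path(input_path).stem
            try:
                image = load_image(input_path)
            except FileNotFoundError as exc:
                raise StageError("load", str(exc), stem) from exc
            try:
                seg = segment_network(image, seg_params, config.pixel_size_um)
                classify_regions(seg)
            except Exception as exc:
                raise StageError("segment", str(exc), stem) from exc
            try:
                result = analyze_network(seg, N_t=config.n_t, thresholds=config.thresholds)
            except Exception as exc:
                raise StageError("classify", str(exc), stem) from exc

            _write_csv(seg.regions, outdir / f"{stem}_regions.csv")
            _write_csv(result.triangles, outdir / f"{stem}_triangles.csv")
            n_inc = int((seg.regions["class"] == "inclusion").sum())
            per_class = {
                cls: int((result.triangles["packing_class"] == cls).sum())
                for cls in CLASSES
            }
            _log(
                f"{stem}: regions={seg.n_regions} droplets={result.stats.N} "
                f"inclusions={n_inc} triangles={result.n_triangles} "
                + " ".join(f"{c}={n}" for c, n in per_class.items())
            )
            summary["prints"][stem] = {
                "fractions": result.fractions,
                "n_droplets": result.stats.N,
                "n_inclusions": n_inc,
                "n_triangles": result.n_triangles,
                "droplet_excess_pct": result.stats.droplet_excess_pct,
                "size_cv_pct": result.stats.size_cv_pct,
                "oil_fraction": result.stats.oil_fraction,
            }
            prints.append((stem, seg, result))

        if len(prints) > 1 and config.reference_layout:
            try:
                layout = load_layout(config.reference_layout)
                shape = prints[0][1].label_image.shape
                maps = []
                for stem, seg, result in prints:
                    droplets = seg.regions[seg.regions["class"] == "droplet"]
                    centroids = droplets[["x", "y"]].to_numpy()
                    reg = register_to_reference(centroids, layout.centers)
                    maps.append(
                        rasterize_class_map(
                            result.triangles, centroids, reg.transform, shape
                        )
                    )
                    _log(f"{stem}: registered rms={reg.rms:.3f} px")
                H = accumulate(maps)
                hexbins = bin_hexagonal(H, layout)
                _write_csv(hexbins.bins, outdir / "heatmap_bins.csv")
                for cls, arr in H.items():
                    p = outdir / f"heatmap_{cls}.tif"
                    tifffile.imwrite(p, arr.astype(np.uint16))
                    written.append(p)
                summary["heatmap"] = {
                    "n_prints": len(prints),
                    "n_bins_defined": int(hexbins.bins["defined"].sum()),
                }
            except Exception as exc:
                raise StageError("heatmap", str(exc)) from exc
    except StageError:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
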