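"""End-to-end drug-induced-swelling pipeline and its configuration.

``run_pipeline`` executes the DIS analysis chain on a plate directory —
segment (or import masks) -> track -> swelling per organoid -> outlier
exclusion -> per-condition summary — writing every intermediate table
plus a manifest (config echo, seed, versions, per-stage counts) that
suffices to reproduce the run bit-for-bit. All configuration is
validated before any stage executes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .masks_io import extract_instances, read_image, read_label_mask
from .segmentation import SegmentationParams, segment_brightfield
from .tracking import build_trajectories
from .assays import (
    DEFAULT_FENCE_K,
    DEFAULT_MIN_AREA_T0,
    PlateLayout,
    condition_summary,
    exclude_outliers,
    records_to_frame,
    swelling_per_organoid,
)

logger = logging.getLogger("orgaswell")

__all__ = ["RunConfig", "ConfigError", "load_layout", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any stage executes)."""


@dataclass
class RunConfig:
    """Validated parameters for one DIS pipeline run."""

    input_dir: Path
    output_dir: Path
    layout: PlateLayout
    use_masks: bool = True  # import <well>_t{0,1}_mask.tiff instead of segmenting
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    max_displacement: float = 50.0
    min_area_t0: float = DEFAULT_MIN_AREA_T0
    fence_k: float = DEFAULT_FENCE_K
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.input_dir.is_dir():
            raise ConfigError(f"input_dir does not exist: {self.input_dir}")
        if self.max_displacement <= 0:
            raise ConfigError("max_displacement must be > 0")
        if self.min_area_t0 < 0 or self.fence_k < 0:
            raise ConfigError("outlier parameters must be non-negative")
        if not self.layout.wells:
            raise ConfigError("plate layout is empty")


def load_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from YAML.

    Schema::

        plate_id: P1
        conditions: [control, treated]   # optional whitelist
        wells:
          A1: {condition: control, compounds: DMSO}
          A2: {condition: treated, compounds: VX-445/VX-661/VX-770}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "wells" not in doc:
        raise ConfigError(f"layout {path} must contain a 'wells' mapping")
    plate_id = str(doc.get("plate_id", "plate"))
    known = doc.get("conditions")
    wells: dict[str, tuple[str, str, str]] = {}
    for well_id, entry in doc["wells"].items():
        if isinstance(entry, str):
            cond, compounds = entry, ""
        else:
            cond = entry.get("condition")
            compounds = entry.get("compounds", "")
        if cond is None:
            raise ConfigError(f"well {well_id!r} has no condition")
        if known is not None and cond not in known:
            raise ConfigError(
                f"well {well_id!r} uses condition {cond!r} not in the declared conditions {known}"
            )
        wells[str(well_id)] = (str(cond), str(compounds), plate_id)
    return PlateLayout(wells=wells)


def _discover_wells(cfg: RunConfig) -> list[str]:
    found = sorted(
        p.name.removesuffix("_t0.tiff")
        for p in cfg.input_dir.glob("*_t0.tiff")
    )
    wells = [w for w in found if w in cfg.layout.wells]
    missing = [w for w in found if w not in cfg.layout.wells]
    if missing:
        raise ConfigError(f"wells {missing} found in {cfg.input_dir} but absent from the layout")
    if not wells:
        raise ConfigError(f"no <well>_t0.tiff images found in {cfg.input_dir}")
    return wells


def run_pipeline(config: RunConfig) -> dict:
    """Run the full DIS chain; returns the manifest dict.

    Outputs written to ``config.output_dir``: ``records.csv`` (one row
    per tracked organoid with exclusion flags), ``summary.csv`` (one row
    per plate x condition), per-well feature tables and (when
    segmenting) predicted masks, and ``manifest.json``. On a stage
    failure the partial outputs are kept and the manifest carries a
    FAILED marker naming the stage.
    """
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "input_dir": str(config.input_dir),
            "output_dir": str(config.output_dir),
            "use_masks": config.use_masks,
            "segmentation": dataclasses.asdict(config.segmentation),
            "max_displacement": config.max_displacement,
            "min_area_t0": config.min_area_t0,
            "fence_k": config.fence_k,
        },
        "stages": {},
        "status": "FAILED",
    }
    stage = "discover"
    try:
        wells = _discover_wells(config)
        manifest["stages"]["discover"] = {"n_wells": len(wells)}

        records = []
        n_instances = 0
        n_links = 0
        from .masks_io import write_label_mask  # local to keep module load cheap

        for well in wells:
            stage = f"segment:{well}"
            masks = []
            border_sets = []
            for t in (0, 1):
                if config.use_masks:
                    mask = read_label_mask(config.input_dir / f"{well}_t{t}_mask.tiff")
                    border = set()
                else:
                    img = read_image(config.input_dir / f"{well}_t{t}.tiff")
                    mask, border = segment_brightfield(
                        img, config.segmentation, return_border_labels=True
                    )
                    write_label_mask(mask, out / f"{well}_t{t}_pred.tiff")
                masks.append(mask)
                border_sets.append(border)
            sets = [
                extract_instances(masks[0], timepoint=0.0, source_image_id=f"{well}_t0"),
                extract_instances(masks[1], timepoint=24.0, source_image_id=f"{well}_t1"),
            ]
            n_instances += len(sets[0]) + len(sets[1])

            stage = f"track:{well}"
            trajectories = build_trajectories(sets, masks, config.max_displacement)
            complete = [t for t in trajectories if t.complete]
            n_links += len(complete)

            stage = f"swelling:{well}"
            cond = config.layout.condition_of(well)
            for traj in complete:
                rec = swelling_per_organoid(traj, 0.0, 24.0, well_id=well, condition=cond)
                t0_label = traj.points[0][1]
                rec.border_flagged = t0_label in border_sets[0]
                records.append(rec)
        manifest["stages"]["segment"] = {"n_instances": n_instances}
        manifest["stages"]["track"] = {"n_complete_trajectories": n_links}

        stage = "exclude"
        records = exclude_outliers(
            records, min_area_t0=config.min_area_t0, fence_k=config.fence_k, layout=config.layout
        )
        n_excluded = sum(r.excluded for r in records)
        manifest["stages"]["exclude"] = {
            "n_records": len(records),
            "n_excluded": n_excluded,
        }
        logger.info("excluded %d of %d swelling records", n_excluded, len(records))

        stage = "summarize"
        summaries = condition_summary(records, config.layout)
        rec_df = records_to_frame(records)
        rec_df.to_csv(out / "records.csv", index=False, lineterminator="\n", float_format="%.6g")
        sum_df = pd.DataFrame(
            [
                {
                    "plate_id": s.plate_id,
                    "condition": s.condition,
                    "mean_swelling": "" if s.mean_swelling is None else f"{s.mean_swelling:.6g}",
                    "sd_swelling": "" if s.sd_swelling is None else f"{s.sd_swelling:.6g}",
                    "n_included": s.n_included,
                    "n_excluded": s.n_excluded,
                }
                for s in summaries
            ]
        )
        sum_df.to_csv(out / "summary.csv", index=False, lineterminator="\n")
        manifest["stages"]["summarize"] = {"n_conditions": len(summaries)}
        manifest["status"] = "OK"
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        raise
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
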