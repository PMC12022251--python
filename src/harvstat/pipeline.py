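"""Orchestration: QC → standardize → calibrate → validate as one run.

A single structured config (dict or YAML file) names the inputs and
toggles/parameterizes the stages, which always execute in the fixed
order above.  Each run emits the harmonized table plus per-stage reports
and a :class:`RunManifest` recording the config snapshot, input
checksums, per-stage record counts and the package version — identical
inputs and config yield identical outputs and an identical manifest
(timestamp aside).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError
from .io import (
    read_boundaries,
    read_crop_table,
    read_cropland_raster,
    write_crop_table,
)
from .qc import QCParams, apply_qc
from .standardize import (
    CoverageParams,
    SmoothingParams,
    aggregate_admin,
    aggregate_subcrops,
    read_two_column_mapping,
)
from .calibration import calibrate
from .validation import correlate_with_reference, national_annual_production

STAGE_ORDER = ["qc", "standardize", "calibrate", "validate"]


@dataclasses.dataclass
class StageCount:
    stage: str
    records_in: int
    records_out: int
    flagged: int = 0
    missing_created: int = 0


@dataclasses.dataclass
class RunManifest:
    config: dict
    input_checksums: dict
    stages: list[StageCount]
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, outdir) -> RunManifest:
    """Execute the configured stages over the named inputs.

    ``config["inputs"]`` names files (``crop_csv`` required; boundary
    vintages, cropland raster, reference table, crop/unit mappings as the
    enabled stages require); ``config["stages"]`` holds per-stage dicts
    with an ``enabled`` key plus stage parameters.  Outputs are written
    under ``outdir``: ``harmonized.csv``, ``conservation_report.csv``,
    ``validation_report.csv`` and ``manifest.json``.  A stage failure
    aborts with :class:`PipelineStageError` naming the stage; the partial
    manifest (stages completed so far) is still written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    stages_cfg = config.get("stages", {})
    checksums = {
        key: _sha256(path)
        for key, path in inputs.items()
        if path and Path(str(path)).is_file()
    }
    manifest = RunManifest(config=config, input_checksums=checksums, stages=[])

    def stage_enabled(name: str) -> bool:
        entry = stages_cfg.get(name, {})
        if isinstance(entry, bool):
            return entry
        return bool(entry.get("enabled", False))

    def stage_opts(name: str) -> dict:
        entry = stages_cfg.get(name, {})
        return {k: v for k, v in entry.items() if k != "enabled"} if isinstance(entry, dict) else {}

    try:
        records = read_crop_table(inputs["crop_csv"], strict=config.get("strict", True))
    except Exception as exc:  # schema problems are an input failure
        manifest.timestamp = _now()
        manifest.write(outdir / "manifest.json")
        raise PipelineStageError("read", str(exc)) from exc

    for stage in STAGE_ORDER:
        if not stage_enabled(stage):
            continue
        n_in = len(records)
        opts = stage_opts(stage)
        try:
            if stage == "qc":
                params = QCParams(**opts)
                records = apply_qc(records, params)
                count = StageCount(stage, n_in, len(records),
                                   flagged=int((records["qc_flag"] != 0).sum()))
            elif stage == "standardize":
                crop_map = (
                    read_two_column_mapping(inputs["crop_mapping_csv"])
                    if inputs.get("crop_mapping_csv")
                    else {}
                )
                if crop_map:
                    records = aggregate_subcrops(records, crop_map)
                missing_created = 0
                if inputs.get("unit_mapping_csv"):
                    unit_map = read_two_column_mapping(inputs["unit_mapping_csv"])
                    cov = CoverageParams(min_coverage=opts.get("min_coverage", 0.5))
                    smo = SmoothingParams(kernel_sd=opts.get("kernel_sd", 3.0))
                    records, coverage = aggregate_admin(
                        records, unit_map, cov, smo, return_coverage=True
                    )
                    missing_created = int((coverage["coverage"] + 1e-12 < cov.min_coverage).sum())
                count = StageCount(stage, n_in, len(records),
                                   missing_created=missing_created)
            elif stage == "calibrate":
                old_units = read_boundaries(inputs["boundaries_old"])
                new_units = read_boundaries(inputs["boundaries_new"])
                raster = (
                    read_cropland_raster(inputs["cropland_raster"])
                    if inputs.get("cropland_raster")
                    else None
                )
                records, events, plans, reports = calibrate(
                    records, old_units, new_units, raster=raster,
                    area_change_threshold=opts.get("area_change_threshold", 0.10),
                )
                if reports:
                    pd.concat(reports, ignore_index=True).to_csv(
                        outdir / "conservation_report.csv", index=False
                    )
                with open(outdir / "change_log.txt", "w", encoding="utf-8") as fh:
                    for event, plan in zip(events, plans):
                        fh.write(
                            f"case {event.case} {event.kind}: "
                            f"{event.old_fnids} -> {event.new_fnids}\n"
                        )
                        for line in plan.provenance:
                            fh.write(f"  {line}\n")
                count = StageCount(stage, n_in, len(records))
            elif stage == "validate":
                national = national_annual_production(records)
                reference = pd.read_csv(inputs["reference_csv"])
                table, summary = correlate_with_reference(
                    national, reference, min_years=opts.get("min_years", 5),
                    log=opts.get("log", False),
                )
                table.to_csv(outdir / "validation_report.csv", index=False)
                with open(outdir / "validation_summary.json", "w") as fh:
                    json.dump(summary, fh, indent=2)
                count = StageCount(stage, n_in, len(records))
        except Exception as exc:
            manifest.timestamp = _now()
            manifest.write(outdir / "manifest.json")
            raise PipelineStageError(stage, str(exc)) from exc
        manifest.stages.append(count)

    write_crop_table(records, outdir / "harmonized.csv")
    manifest.timestamp = _now()
    manifest.write(outdir / "manifest.json")
    return manifest


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()
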