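"""End-to-end runs: segment -> measure -> classify -> rates -> statistics.

A :class:`RunConfig` names, per condition and replicate, the three channel
TIFFs (or a directory holding them under the ``_dapi``/``_flag``/``_edu``
suffix convention).  ``run_pipeline`` executes the full chain, pooling the
Flag intensities within each condition to select a single transfection
threshold per condition (matching how thresholds are chosen per
experiment), and writes per-cell tables, a counts summary, overlay images,
the statistics report and a manifest of every parameter used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from eduscan.classify import (
    ClassifyParams,
    classify_cells,
    measure_channels,
    overlay_image,
    select_transfection_threshold,
)
from eduscan.segment import DoGParams, SegmentationParams, segment_nuclei
from eduscan.stats import compare_groups, summarize_condition

log = logging.getLogger("eduscan")

CHANNEL_SUFFIXES = {"dapi": "_dapi", "flag": "_flag", "edu": "_edu"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending file."""


@dataclass
class FieldPaths:
    """Channel files for one field (replicate of one condition)."""

    dapi: Path
    flag: Path
    edu: Path

    def validate(self) -> None:
        for name in ("dapi", "flag", "edu"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise PipelineError(f"input: missing {name} channel file: {p}")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    conditions: dict[str, list[FieldPaths]]  # condition -> replicate fields
    control_condition: str
    output_dir: Path
    dog: DoGParams = field(default_factory=DoGParams)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    pixel_size: float = 0.65
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.control_condition not in self.conditions:
            raise ValueError(
                f"control condition {self.control_condition!r} not among conditions"
            )
        for fields in self.conditions.values():
            for fp in fields:
                fp.validate()


def discover_field(directory: str | Path, prefix: str = "") -> FieldPaths:
    """Locate the three channel TIFFs in a directory by suffix convention."""
    d = Path(directory)
    found = {}
    for name, suffix in CHANNEL_SUFFIXES.items():
        matches = sorted(d.glob(f"{prefix}*{suffix}.tif*"))
        if not matches:
            raise PipelineError(f"input: no {suffix}.tif file in {d}")
        found[name] = matches[0]
    return FieldPaths(**found)


def analyze_field(
    fp: FieldPaths,
    dog: DoGParams,
    seg: SegmentationParams,
    flag_dilation_px: int = 0,
    pixel_size: float | None = None,
):
    """Segment one field and measure its channels (no classification yet)."""
    try:
        dapi = tifffile.imread(fp.dapi).astype(np.float64)
        flag = tifffile.imread(fp.flag).astype(np.float64)
        edu = tifffile.imread(fp.edu).astype(np.float64)
    except FileNotFoundError as e:
        raise PipelineError(f"input: cannot read channel file: {e.filename}") from e
    try:
        labels = segment_nuclei(dapi, dog, seg)
    except Exception as e:
        raise PipelineError(f"segmentation: {fp.dapi}: {e}") from e
    try:
        records = measure_channels(
            labels, flag, edu, dog, dapi_image=dapi,
            pixel_size=pixel_size, flag_dilation_px=flag_dilation_px,
        )
    except Exception as e:
        raise PipelineError(f"measurement: {fp.flag}: {e}") from e
    return labels, records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all outputs.

    Returns a report dict with per-condition summaries and the group
    comparison, also serialized under ``output_dir``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    per_field: dict[str, list] = {}
    try:
        for condition, fields in config.conditions.items():
            per_field[condition] = []
            for i, fp in enumerate(fields):
                log.info("analyzing %s replicate %d (%s)", condition, i, fp.dapi)
                labels, records = analyze_field(
                    fp, config.dog, config.seg,
                    config.classify.flag_dilation_px, config.pixel_size,
                )
                records["condition"] = condition
                records["replicate"] = i
                per_field[condition].append((labels, records))

        # one transfection threshold per condition, from pooled intensities
        thresholds: dict[str, float] = {}
        for condition, items in per_field.items():
            pooled = pd.concat([r for _, r in items], ignore_index=True)
            if config.classify.flag_threshold == "auto":
                thr = select_transfection_threshold(
                    pooled["mean_flag"], config.classify.fallback_percentile
                )
            else:
                thr = float(config.classify.flag_threshold)
            thresholds[condition] = thr
            log.info("condition %s: flag threshold %.3f", condition, thr)

        all_cells, summaries, counts_rows = [], [], []
        for condition, items in per_field.items():
            is_control = condition == config.control_condition
            for i, (labels, records) in enumerate(items):
                classified = classify_cells(
                    records, config.classify, flag_threshold=thresholds[condition]
                )
                all_cells.append(classified)
                s = summarize_condition(classified, condition, i, is_control)
                summaries.append(s)
                counts_rows.append(
                    {
                        "condition": condition,
                        "replicate": i,
                        "n_total": s.n_total,
                        "n_transfected": s.n_transfected,
                        "n_proliferating": s.n_proliferating,
                        "n_transfected_proliferating": s.n_transfected_proliferating,
                        "proliferation_rate": s.proliferation_rate,
                    }
                )
                rgb = overlay_image(labels, classified)
                iio.imwrite(out / f"overlay_{condition}_{i}.png", rgb)

        cells_df = pd.concat(all_cells, ignore_index=True)
        cells_df.to_csv(out / "cells.csv", index=False)
        counts_df = pd.DataFrame(counts_rows)
        counts_df.to_csv(out / "counts.csv", index=False)

        rates = {
            c: [s.proliferation_rate for s in summaries if s.condition == c]
            for c in config.conditions
        }
        comparison = None
        if len(rates) >= 2 and all(len(v) >= 2 for v in rates.values()):
            comparison = compare_groups(rates)
            (out / "stats_report.txt").write_text(comparison.report() + "\n")
            comparison.descriptives.to_csv(out / "stats_descriptives.csv", index=False)
            if comparison.pairwise is not None:
                comparison.pairwise.to_csv(out / "stats_pairwise.csv", index=False)
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest = {
        "seed": config.seed,
        "pixel_size": config.pixel_size,
        "control_condition": config.control_condition,
        "dog": dataclasses.asdict(config.dog),
        "seg": dataclasses.asdict(config.seg),
        "classify": dataclasses.asdict(config.classify),
        "flag_thresholds": thresholds,
        "conditions": {
            c: [
                {k: str(getattr(fp, k)) for k in ("dapi", "flag", "edu")}
                for fp in fps
            ]
            for c, fps in config.conditions.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "summaries": summaries,
        "rates": rates,
        "comparison": comparison,
        "thresholds": thresholds,
        "counts": counts_df,
        "cells": cells_df,
    }
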