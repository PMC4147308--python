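"""End-to-end analysis: segment -> intensity -> geometry -> coloc -> report.

Ties the stages together for one scene or a set of scenes grouped by
condition.  All outputs are tidy DataFrames; ``write_outputs`` dumps
them as CSV with a fixed float format so that a fixed seed yields
byte-identical files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coloc import coloc_by_cell, coloc_table
from .geometry import DEFAULT_CONTACT_DISTANCE, contact_morphology
from .image import MultiChannelImage
from .intensity import compartment_profile
from .segmentation import (
    DEFAULT_DAPI_THRESHOLD,
    DEFAULT_RING_WIDTH,
    segment,
)
from .stats import batch_report

__all__ = ["AnalysisConfig", "analyze_scene", "analyze_conditions", "write_outputs"]

_FLOAT_FORMAT = "%.9g"


@dataclass
class AnalysisConfig:
    dapi_channel: str = "DAPI"
    dapi_threshold: float = DEFAULT_DAPI_THRESHOLD
    ring_width: int = DEFAULT_RING_WIDTH
    ring_element: str = "square"
    background_stat: str = "median"
    contact_distance: int = DEFAULT_CONTACT_DISTANCE
    perimeter_estimator: str = "chain"
    coloc_channels: tuple[str, str] | None = ("A488", "A555")
    coloc_region: str = "nucleus"
    channels: list[str] | None = None  # None = all fluorescence channels
    exclude_channels: tuple[str, ...] = ("DIC",)


def analyze_scene(
    image: MultiChannelImage,
    outlines,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full per-cell analysis of one scene.

    Returns ``{"profiles": ..., "morphology": ..., "coloc": ...}`` (the
    coloc table only when a channel pair is configured and present).
    """
    cfg = config or AnalysisConfig()
    corrected, seg = segment(
        image,
        outlines,
        dapi_channel=cfg.dapi_channel,
        dapi_threshold=cfg.dapi_threshold,
        ring_width=cfg.ring_width,
        ring_element=cfg.ring_element,
        background_stat=cfg.background_stat,
    )
    channels = cfg.channels or [c for c in image.channel_names if c not in cfg.exclude_channels]
    profiles = compartment_profile(corrected, seg, channels)
    morphology = contact_morphology(
        seg.cells,
        contact_distance=cfg.contact_distance,
        estimator=cfg.perimeter_estimator,
    )
    out = {"profiles": profiles, "morphology": morphology}
    if cfg.coloc_channels is not None:
        a, b = cfg.coloc_channels
        if a in image and b in image:
            results = coloc_by_cell(corrected, seg, a, b, region=cfg.coloc_region)
            out["coloc"] = coloc_table(results)
    return out


def analyze_conditions(
    scenes: dict[str, tuple[MultiChannelImage, object]],
    conditions: dict[str, str],
    config: AnalysisConfig | None = None,
    report_metrics: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Analyze several scenes and compare conditions.

    ``scenes`` maps a scene id to ``(image, outlines)``; ``conditions``
    maps scene ids to condition labels.  Per-cell tables get ``scene``
    and ``condition`` columns; a merged per-cell metric table and a
    statistics report are appended.
    """
    all_out: dict[str, list[pd.DataFrame]] = {"profiles": [], "morphology": [], "coloc": []}
    for sid, (image, outlines) in sorted(scenes.items()):
        res = analyze_scene(image, outlines, config)
        for key, df in res.items():
            df = df.copy()
            df.insert(0, "scene", sid)
            df.insert(1, "condition", conditions.get(str(sid), "unknown"))
            all_out[key].append(df)
    merged = {k: pd.concat(v, ignore_index=True) for k, v in all_out.items() if v}

    # wide per-cell metric table for the statistics stage
    pieces = []
    if "profiles" in merged:
        wide = merged["profiles"].pivot_table(
            index=["scene", "condition", "cell_id"],
            columns="channel",
            values=["ratio_membrane", "ratio_nucleus", "intensity_per_area"],
        )
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        pieces.append(wide)
    if "morphology" in merged:
        pieces.append(
            merged["morphology"]
            .set_index(["scene", "condition", "cell_id"])[
                ["percent_contact", "total_perimeter", "axis_ratio"]
            ]
        )
    if "coloc" in merged:
        pieces.append(
            merged["coloc"].set_index(["scene", "condition", "cell_id"])[["M1", "M2"]]
        )
    if pieces:
        percell = pd.concat(pieces, axis=1).reset_index()
        merged["per_cell"] = percell
        merged["report"] = batch_report(
            percell.drop(columns=["scene"]), metrics=report_metrics
        )
    return merged


def write_outputs(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """CSV per table, deterministic formatting (fixed float format,
    fixed column order, no index)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = outdir / f"{name}.csv"
        tables[name].to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
        written.append(path)
    return written
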