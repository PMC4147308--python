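"""Reading and writing scenes, masks, outlines and result tables.

Scenes travel as multi-page TIFF (one page per channel, the channel
name in each page's description), label masks as integer TIFF, cell
outlines as JSON or CSV vertex lists (0-based pixel coordinates,
x = column), truth and metric tables as CSV, and condition maps as
YAML.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon

from .image import MultiChannelImage

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "write_polygons",
    "read_polygons",
    "write_scene",
    "read_conditions",
]


def write_image(path: str | Path, image: MultiChannelImage) -> None:
    """Multi-page TIFF, one page per channel, channel name per page."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, arr in image.channels.items():
            tif.write(
                arr.astype(np.float32),
                description=json.dumps({"channel": name, "pixel_size_um": image.pixel_size}),
            )


def read_image(path: str | Path) -> MultiChannelImage:
    path = Path(path)
    channels: dict[str, np.ndarray] = {}
    pixel_size = 0.2
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = f"channel{i}"
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    name = meta.get("channel", name)
                    pixel_size = float(meta.get("pixel_size_um", pixel_size))
                except (json.JSONDecodeError, TypeError):
                    pass
            channels[name] = page.asarray().astype(float)
    return MultiChannelImage(channels, pixel_size=pixel_size, metadata={"source": str(path)})


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_polygons(path: str | Path, polygons: dict[int, Polygon]) -> None:
    """JSON (``.json``) or CSV rows ``cell_id,x,y`` (anything else)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "cells": [
                {"cell_id": int(cid), "vertices": [[float(x), float(y)] for x, y in poly.exterior.coords]}
                for cid, poly in sorted(polygons.items())
            ]
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "x", "y"])
        for cid, poly in sorted(polygons.items()):
            for x, y in poly.exterior.coords:
                writer.writerow([int(cid), float(x), float(y)])


def read_polygons(path: str | Path) -> dict[int, Polygon]:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return {int(c["cell_id"]): Polygon(c["vertices"]) for c in payload["cells"]}
    df = pd.read_csv(path)
    return {
        int(cid): Polygon(grp[["x", "y"]].to_numpy())
        for cid, grp in df.groupby("cell_id", sort=True)
    }


def write_scene(outdir: str | Path, image: MultiChannelImage, truth) -> dict[str, Path]:
    """Scene bundle: image.tif, cells/membrane/nucleus label TIFFs,
    outlines.json, truth.csv.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / "image.tif",
        "cells": outdir / "cells.tif",
        "membrane": outdir / "membrane.tif",
        "nucleus": outdir / "nucleus.tif",
        "outlines": outdir / "outlines.json",
        "truth": outdir / "truth.csv",
    }
    write_image(paths["image"], image)
    write_labels(paths["cells"], truth.cells)
    write_labels(paths["membrane"], truth.membrane)
    write_labels(paths["nucleus"], truth.nucleus)
    write_polygons(paths["outlines"], truth.polygons)
    truth.table.to_csv(paths["truth"], index=False)
    return paths


def read_conditions(path: str | Path) -> dict[str, str]:
    """YAML mapping of scene/image id -> condition label."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("conditions file must be a mapping of id -> condition")
    return {str(k): str(v) for k, v in data.items()}
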