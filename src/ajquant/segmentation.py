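"""Compartment segmentation: the "cell", "membrane" and "nucleus" masks.

Raw channels plus per-cell outlines are turned into three per-cell masks
after per-channel scalar background subtraction:

* **cell** — the pixels of the manually/synthetically outlined cell;
* **membrane** — a ring of configurable width along the cell boundary,
  obtained by subtracting a morphological erosion of the cell mask;
* **nucleus** — the pixels of the cell where the DAPI signal is strictly
  above a threshold (default 60 counts), minus any membrane pixels, then
  reduced to the largest connected component (one nucleus per cell).

Masks are stored as label images (0 = background, k = cell k) so that
cells are disjoint by construction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from scipy.ndimage import binary_erosion
from skimage.measure import label as cc_label
from skimage.morphology import disk, footprint_rectangle

from .image import MultiChannelImage

__all__ = [
    "CellSegmentation",
    "subtract_background",
    "rasterize_polygons",
    "load_cell_outlines",
    "threshold_nucleus",
    "derive_membrane_ring",
    "segment",
    "DEFAULT_DAPI_THRESHOLD",
    "DEFAULT_RING_WIDTH",
]

DEFAULT_DAPI_THRESHOLD = 60.0  # counts, strict '>' rule
DEFAULT_RING_WIDTH = 3         # pixels (~0.6 um at 0.2 um/px)


class PlacementError(ValueError):
    """Raised when outlines overlap or cannot be realized on the grid."""


# ---------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------

def subtract_background(
    image: MultiChannelImage,
    stat: str = "median",
    values: dict[str, float] | None = None,
) -> MultiChannelImage:
    """Subtract a per-channel scalar background, clipping at zero.

    ``stat`` is one of ``"median"`` (default), ``"mode"`` or
    ``"fixed"``; for ``"fixed"`` a non-negative value per channel must
    be supplied in ``values``.  The scalar used for each channel is
    recorded in ``metadata["background"]``.
    """
    if stat not in ("median", "mode", "fixed"):
        raise ValueError(f"unknown background statistic {stat!r}")
    out: dict[str, np.ndarray] = {}
    used: dict[str, float] = {}
    for name, arr in image.channels.items():
        if arr.size == 0:
            raise ValueError(f"channel {name!r} is empty")
        if stat == "median":
            bg = float(np.median(arr))
        elif stat == "mode":
            # mode of rounded counts; detector counts are quantized
            vals, counts = np.unique(np.round(arr).astype(np.int64), return_counts=True)
            bg = float(vals[np.argmax(counts)])
        else:
            if values is None or name not in values:
                raise ValueError(f"fixed background requires a value for channel {name!r}")
            bg = float(values[name])
            if bg < 0:
                raise ValueError(f"fixed background for {name!r} must be >= 0, got {bg}")
        out[name] = np.clip(arr - bg, 0.0, None)
        used[name] = bg
    return image.with_channels(out, background=used, background_stat=stat)


# ---------------------------------------------------------------------
# outlines -> label mask
# ---------------------------------------------------------------------

def rasterize_polygons(
    polygons: dict[int, Polygon], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize cell polygons to a label mask by center sampling.

    A pixel (r, c) belongs to a polygon iff its center (c + 0.5, r + 0.5)
    lies strictly inside it (x = column, 0-based).  Pixels claimed by an
    earlier (lower id) cell are never reassigned, so labels are disjoint
    even when polygons share boundary edges.
    """
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    for cid in sorted(polygons):
        poly = polygons[cid]
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor(minx - 0.5)), 0)
        c1 = min(int(np.ceil(maxx + 0.5)), w - 1)
        r0 = max(int(np.floor(miny - 0.5)), 0)
        r1 = min(int(np.ceil(maxy + 0.5)), h - 1)
        if c1 < c0 or r1 < r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = shapely.contains_xy(poly, cols + 0.5, rows + 0.5)
        window = labels[r0 : r1 + 1, c0 : c1 + 1]
        claim = inside & (window == 0)
        window[claim] = cid
    return labels


def load_cell_outlines(
    source: np.ndarray | dict[int, Polygon] | list,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Build the cell label mask from a label image or polygon outlines.

    ``source`` may be an integer label mask (returned unchanged after
    validation), a mapping ``{cell_id: shapely Polygon}``, or a list of
    ``(cell_id, [(x, y), ...])`` vertex tuples.  Polygons must be simple
    (non-self-intersecting), pairwise non-overlapping (shared edges are
    allowed), and must each rasterize to at least one pixel.
    """
    if isinstance(source, np.ndarray):
        if not np.issubdtype(source.dtype, np.integer):
            raise ValueError("label mask must be integer-valued")
        if source.min() < 0:
            raise ValueError("label mask contains negative labels")
        return source.astype(np.int32, copy=True)

    if isinstance(source, list):
        source = {int(cid): Polygon(verts) for cid, verts in source}
    polys: dict[int, Polygon] = {int(k): v for k, v in source.items()}
    if shape is None:
        raise ValueError("shape is required when rasterizing polygons")
    for cid, poly in polys.items():
        if cid <= 0:
            raise ValueError(f"cell ids must be positive, got {cid}")
        if not poly.is_valid:
            raise PlacementError(f"cell {cid}: polygon is invalid (self-intersecting?)")
    ids = sorted(polys)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            inter = polys[a].intersection(polys[b])
            if inter.area > 1e-9:
                raise PlacementError(f"cells {a} and {b} overlap (area {inter.area:.3g})")
    labels = rasterize_polygons(polys, shape)
    for cid in ids:
        if not np.any(labels == cid):
            raise PlacementError(f"cell {cid} rasterizes to 0 pixels")
    return labels


# ---------------------------------------------------------------------
# membrane ring and nucleus
# ---------------------------------------------------------------------

def _ring_footprint(ring_width: int, element: str) -> np.ndarray:
    if element == "disk":
        return disk(ring_width)
    if element == "square":
        side = 2 * ring_width + 1
        return footprint_rectangle((side, side))
    raise ValueError(f"unknown structuring element {element!r}")


def derive_membrane_ring(
    cell_labels: np.ndarray, ring_width: int = DEFAULT_RING_WIDTH, element: str = "square"
) -> np.ndarray:
    """Membrane ring per cell: cell mask minus its morphological erosion.

    For cells thinner than twice the ring width the erosion is empty and
    the whole cell becomes membrane (the nucleus mask is then forced
    empty downstream).  Returns a label mask.
    """
    if ring_width < 1:
        raise ValueError(f"ring_width must be >= 1, got {ring_width}")
    fp = _ring_footprint(int(ring_width), element)
    rings = np.zeros_like(cell_labels, dtype=np.int32)
    for cid in np.unique(cell_labels):
        if cid == 0:
            continue
        cell = cell_labels == cid
        # border_value=0: outside the frame counts as outside the cell
        interior = binary_erosion(cell, structure=fp, border_value=0)
        rings[cell & ~interior] = cid
    return rings


def _largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Largest connected component of a boolean mask (8-connected)."""
    lab = cc_label(mask, connectivity=connectivity)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == np.argmax(sizes)


def threshold_nucleus(
    dapi: np.ndarray,
    cell_labels: np.ndarray,
    threshold: float = DEFAULT_DAPI_THRESHOLD,
    membrane_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Nucleus mask per cell: DAPI strictly above ``threshold``.

    Per cell, the pixels with DAPI > threshold are taken, membrane-ring
    pixels removed (masks must be disjoint), and the largest 8-connected
    component kept (one nucleus per cell).  Cells with an empty result
    are flagged (returned in the second element) with a warning rather
    than raising; their nucleus metrics are reported as missing.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dapi = np.asarray(dapi, dtype=float)
    if dapi.shape != cell_labels.shape:
        raise ValueError("DAPI channel and label mask shapes differ")
    nuclei = np.zeros_like(cell_labels, dtype=np.int32)
    missing: list[int] = []
    supra = dapi > threshold
    for cid in np.unique(cell_labels):
        if cid == 0:
            continue
        cand = supra & (cell_labels == cid)
        if membrane_labels is not None:
            cand &= membrane_labels != cid
        comp = _largest_component(cand)
        if not comp.any():
            missing.append(int(cid))
            continue
        nuclei[comp] = cid
    if missing:
        warnings.warn(f"cells with empty nucleus mask: {missing}", stacklevel=2)
    return nuclei, missing


# ---------------------------------------------------------------------
# the combined segmentation object
# ---------------------------------------------------------------------

@dataclass
class CellSegmentation:
    """Per-cell cell/membrane/nucleus label masks plus provenance."""

    cells: np.ndarray
    membrane: np.ndarray
    nucleus: np.ndarray
    ring_width: int = DEFAULT_RING_WIDTH
    ring_element: str = "square"
    dapi_threshold: float | None = DEFAULT_DAPI_THRESHOLD
    missing_nucleus: tuple[int, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def labels(self) -> list[int]:
        ids = np.unique(self.cells)
        return [int(i) for i in ids if i != 0]

    def cell_mask(self, cid: int) -> np.ndarray:
        return self.cells == cid

    def membrane_mask(self, cid: int) -> np.ndarray:
        return self.membrane == cid

    def nucleus_mask(self, cid: int) -> np.ndarray:
        return self.nucleus == cid

    def validate(self) -> None:
        """Assert membrane ⊆ cell, nucleus ⊆ cell, membrane ∩ nucleus = ∅."""
        if not (self.cells.shape == self.membrane.shape == self.nucleus.shape):
            raise ValueError("mask shapes differ")
        if np.any((self.membrane != 0) & (self.membrane != self.cells)):
            raise ValueError("membrane mask escapes its cell mask")
        if np.any((self.nucleus != 0) & (self.nucleus != self.cells)):
            raise ValueError("nucleus mask escapes its cell mask")
        if np.any((self.membrane != 0) & (self.nucleus != 0)):
            raise ValueError("membrane and nucleus masks intersect")


def segment(
    image: MultiChannelImage,
    outlines: np.ndarray | dict[int, Polygon] | list,
    dapi_channel: str = "DAPI",
    dapi_threshold: float = DEFAULT_DAPI_THRESHOLD,
    ring_width: int = DEFAULT_RING_WIDTH,
    ring_element: str = "square",
    background_stat: str = "median",
    threshold_after_subtraction: bool = True,
) -> tuple[MultiChannelImage, CellSegmentation]:
    """Full segmentation stage: background subtraction + three masks.

    Returns the background-subtracted image and the segmentation.  The
    DAPI threshold is applied after subtraction by default (configurable
    and recorded in provenance, since thresholding raw counts is equally
    defensible).
    """
    corrected = subtract_background(image, stat=background_stat)
    cells = load_cell_outlines(outlines, shape=image.shape)
    membrane = derive_membrane_ring(cells, ring_width=ring_width, element=ring_element)
    dapi_img = corrected if threshold_after_subtraction else image
    if dapi_channel in dapi_img:
        nucleus, missing = threshold_nucleus(
            dapi_img[dapi_channel], cells, threshold=dapi_threshold, membrane_labels=membrane
        )
    else:
        nucleus, missing = np.zeros_like(cells), [int(c) for c in np.unique(cells) if c]
    seg = CellSegmentation(
        cells=cells,
        membrane=membrane,
        nucleus=nucleus,
        ring_width=ring_width,
        ring_element=ring_element,
        dapi_threshold=dapi_threshold,
        missing_nucleus=tuple(missing),
        provenance={
            "outlines": "label-mask" if isinstance(outlines, np.ndarray) else "polygons",
            "background_stat": background_stat,
            "threshold_after_subtraction": threshold_after_subtraction,
        },
    )
    return corrected, seg
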