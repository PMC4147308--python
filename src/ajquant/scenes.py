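"""Synthetic confocal scenes with planted ground truth.

Generates multi-channel 2D scenes of sparse adherent cells — elliptical
to cuboidal cell bodies with an elliptical nucleus, a thin membrane
ring, uniform background and shot/read noise — in which every quantity
the analysis pipeline measures is planted and therefore known exactly:

* the fraction of each channel's per-cell signal in the membrane ring
  (``f_m``) and in the nucleus (``f_n``);
* the co-localization level ``rho`` between two designated marker
  channels;
* cell adjacency: isolated cells, a closed chain in which every cell
  shares a known fraction of its boundary with its two neighbors, or
  staggered clusters.

The generator reproduces the *statistical structure* the metrics assume
(compartmentalized signal, shared polygon edges, Poisson + Gaussian
noise), not optical realism: no point-spread function, 3D structure or
organelle texture.

Geometry is polygonal and pixelized by center sampling (a pixel belongs
to a mask iff its center lies inside the polygon), the same rule the
segmentation stage uses, so planted truth and measurement share one
convention.  Signal is budgeted: each compartment's pixel values are a
random texture renormalized to sum exactly to its planted share of
``cell_amplitude x cell_area`` counts, so the clean-image compartment
ratios equal the planted fractions to floating-point precision
(QUANTIZATION_TOL) and total cell signal is conserved exactly.

Co-localization planting: within each compartment, each pixel of
channel B copies channel A's texture with probability ``rho`` and
otherwise draws an independent texture with the same marginal.  This
maps rho monotonically onto Manders-type overlap (at rho=1 the two
channels are proportional within each compartment; at rho=0 they are
independent, so the expected PDM is zero).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Polygon, box

from .image import MultiChannelImage
from .segmentation import (
    DEFAULT_RING_WIDTH,
    PlacementError,
    derive_membrane_ring,
    rasterize_polygons,
    _largest_component,
)

__all__ = [
    "ChannelParams",
    "NoiseParams",
    "SceneSpec",
    "SceneTruth",
    "generate_scene",
    "apply_noise",
    "default_channels",
    "QUANTIZATION_TOL",
]

QUANTIZATION_TOL = 1e-9   # planted vs clean-image fraction agreement
_GAP = 8.0                # px clearance between non-touching cells
_DIC_AMPLITUDE = 50.0
_DIC_BACKGROUND = 10.0


@dataclass(frozen=True)
class ChannelParams:
    """Planted intensity model of one fluorescence channel.

    ``membrane_fraction`` + ``nucleus_fraction`` of the cell's total
    signal go to the ring and nucleus; the remainder is cytoplasmic.
    ``smooth`` channels (DAPI) use a flat within-compartment texture;
    punctate channels draw a sparse gamma texture with ``zero_fraction``
    empty pixels.
    """

    background_level: float = 20.0
    cell_amplitude: float = 100.0
    membrane_fraction: float = 0.3
    nucleus_fraction: float = 0.1
    smooth: bool = False
    zero_fraction: float = 0.3
    texture_shape: float = 2.0

    def validate(self, name: str = "") -> None:
        fm, fn = self.membrane_fraction, self.nucleus_fraction
        if not (0 <= fm <= 1 and 0 <= fn <= 1):
            raise ValueError(f"channel {name}: fractions must lie in [0, 1]")
        if fm + fn > 1 + 1e-12:
            raise ValueError(f"channel {name}: membrane + nucleus fraction {fm + fn} > 1")
        if self.background_level < 0 or self.cell_amplitude < 0:
            raise ValueError(f"channel {name}: negative intensity parameter")
        if not (0 <= self.zero_fraction < 1):
            raise ValueError(f"channel {name}: zero_fraction must be in [0, 1)")


@dataclass(frozen=True)
class NoiseParams:
    poisson: bool = True
    gaussian_sd: float = 2.0

    def validate(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


def default_channels() -> dict[str, ChannelParams]:
    """DAPI (nuclear stain) plus two punctate marker channels."""
    return {
        "DAPI": ChannelParams(background_level=5.0, cell_amplitude=50.0,
                              membrane_fraction=0.0, nucleus_fraction=1.0, smooth=True),
        "A488": ChannelParams(),
        "A555": ChannelParams(),
    }


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic scene.

    ``image_size`` may be None, in which case the canvas is sized to fit
    the requested cells with clearance.  ``cell_size`` is the minor cell
    extent in pixels; the major extent is ``axis_ratio`` times larger.
    """

    image_size: tuple[int, int] | None = None     # (H, W) pixels
    pixel_size: float = 0.2                       # um / px (60x confocal convention)
    n_cells: int = 12
    adjacency_mode: str = "isolated"              # isolated | chained | clustered
    target_contact_fraction: float = 0.0
    cell_shape: str = "cuboidal"                  # cuboidal | elongated
    axis_ratio: float = 1.0
    cell_size: float = 40.0
    nucleus_axis_fraction: float = 0.5
    membrane_ring_width: int = DEFAULT_RING_WIDTH
    channels: dict[str, ChannelParams] = field(default_factory=default_channels)
    coloc_channels: tuple[str, str] = ("A488", "A555")
    coloc_rho: float = 0.0
    include_dic: bool = True
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.adjacency_mode not in ("isolated", "chained", "clustered"):
            raise ValueError(f"unknown adjacency_mode {self.adjacency_mode!r}")
        if self.cell_shape not in ("cuboidal", "elongated"):
            raise ValueError(f"unknown cell_shape {self.cell_shape!r}")
        if not (0 <= self.target_contact_fraction <= 1):
            raise ValueError("target_contact_fraction must lie in [0, 1]")
        if not (0 <= self.coloc_rho <= 1):
            raise ValueError("coloc_rho must lie in [0, 1]")
        if not (0 < self.nucleus_axis_fraction < 1):
            raise ValueError("nucleus_axis_fraction must lie in (0, 1)")
        if self.membrane_ring_width < 1:
            raise ValueError("membrane_ring_width must be >= 1")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1 (major/minor)")
        for name, ch in self.channels.items():
            ch.validate(name)
        self.noise.validate()
        a, b = self.coloc_channels
        if self.coloc_rho > 0 and not (a in self.channels and b in self.channels):
            raise ValueError(f"coloc channels {self.coloc_channels} not both present")


@dataclass
class SceneTruth:
    """Planted ground truth of one generated scene."""

    spec: SceneSpec
    polygons: dict[int, Polygon]
    cells: np.ndarray            # label masks (0 = background)
    membrane: np.ndarray
    nucleus: np.ndarray
    table: pd.DataFrame          # one row per cell: geometry + planted fractions
    clean: dict[str, np.ndarray]  # pre-noise channels

    def cell_mask(self, cid: int) -> np.ndarray:
        return self.cells == cid


# ---------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------

def _superellipse(cx: float, cy: float, a: float, b: float, p: float,
                  angle: float, n: int = 96) -> Polygon:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    x = a * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / p)
    y = b * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / p)
    ca, sa = np.cos(angle), np.sin(angle)
    return Polygon(np.c_[cx + ca * x - sa * y, cy + sa * x + ca * y])


def _layout_isolated(spec: SceneSpec, rng: np.random.Generator):
    minor = spec.cell_size / 2.0
    major = minor * spec.axis_ratio
    p = 5.0 if spec.cell_shape == "cuboidal" else 2.0
    rmax = max(major, minor)
    pitch = 2 * rmax + _GAP
    ncol = int(np.ceil(np.sqrt(spec.n_cells)))
    nrow = int(np.ceil(spec.n_cells / ncol))
    size = spec.image_size or (int(nrow * pitch + _GAP), int(ncol * pitch + _GAP))
    h, w = size
    if ncol * pitch + _GAP > w + 1e-9 or nrow * pitch + _GAP > h + 1e-9:
        raise PlacementError(
            f"cannot place {spec.n_cells} isolated cells of extent {2 * rmax:.0f}px "
            f"with {_GAP:.0f}px clearance on a {h}x{w} canvas"
        )
    polys: dict[int, Polygon] = {}
    for k in range(spec.n_cells):
        r, c = divmod(k, ncol)
        jitter = rng.uniform(-_GAP / 4, _GAP / 4, size=2)
        cx = _GAP + rmax + c * pitch + jitter[0]
        cy = _GAP + rmax + r * pitch + jitter[1]
        angle = rng.uniform(0, np.pi) if spec.cell_shape == "elongated" else 0.0
        polys[k + 1] = _superellipse(cx, cy, major, minor, p, angle)
    return polys, size


def _layout_chained(spec: SceneSpec, rng: np.random.Generator):
    """Closed chain: annulus sectors, every cell two neighbors.

    The radial (shared) edge length dr is set from the target contact
    fraction c and the arc width s: c = 2 dr / (2 dr + 2 s) so
    dr = c s / (1 - c); every interior fraction is exactly c in
    continuous geometry.  c = 0 degenerates to arc-separated sectors.
    """
    n = spec.n_cells
    c = spec.target_contact_fraction
    if c >= 0.95:
        raise PlacementError("target_contact_fraction too close to 1 for a chained layout")
    s = spec.cell_size * max(spec.axis_ratio, 1.0)  # arc width
    theta = 2 * np.pi / n
    rm = s / theta
    dr = spec.cell_size if c == 0 else c * s / (1 - c)
    if dr < 2 * spec.membrane_ring_width + 4:
        dr = 2 * spec.membrane_ring_width + 4  # keep room for a nucleus
    r0, r1 = rm - dr / 2, rm + dr / 2
    if r0 <= 2:
        raise PlacementError(
            f"chained layout infeasible: inner radius {r0:.1f}px <= 2 "
            f"(n_cells={n}, cell_size={spec.cell_size}, contact={c})"
        )
    rout = r1 + _GAP
    size = spec.image_size or (int(2 * rout + 2), int(2 * rout + 2))
    h, w = size
    if 2 * rout > min(h, w):
        raise PlacementError(
            f"chained ring of outer radius {r1:.0f}px does not fit a {h}x{w} canvas"
        )
    cx, cy = w / 2.0, h / 2.0
    phi0 = rng.uniform(0, 2 * np.pi)
    gap_half = (_GAP / 2) / r0 if c == 0 else 0.0
    polys: dict[int, Polygon] = {}
    bounds = phi0 + theta * np.arange(n + 1)
    # one radial edge per boundary, reused by both neighbors (and across
    # the seam) so that shared edges are bitwise coincident
    p_in = np.c_[cx + r0 * np.cos(bounds[:n]), cy + r0 * np.sin(bounds[:n])]
    p_out = np.c_[cx + r1 * np.cos(bounds[:n]), cy + r1 * np.sin(bounds[:n])]
    for k in range(n):
        lo, hi = bounds[k] + gap_half, bounds[k + 1] - gap_half
        narc = max(int((hi - lo) * r1 / 2.0), 4)
        ang = np.linspace(lo, hi, narc + 1)
        inner = np.c_[cx + r0 * np.cos(ang), cy + r0 * np.sin(ang)]
        outer = np.c_[cx + r1 * np.cos(ang[::-1]), cy + r1 * np.sin(ang[::-1])]
        if gap_half == 0.0:
            nxt = (k + 1) % n
            inner[0], inner[-1] = p_in[k], p_in[nxt]
            outer[0], outer[-1] = p_out[nxt], p_out[k]
        polys[k + 1] = Polygon(np.vstack([inner, outer]))
    return polys, size


def _layout_clustered(spec: SceneSpec, rng: np.random.Generator):
    """Staggered mini-chains of 4 rectangular cells per cluster.

    Consecutive cells share a vertical edge of length h - dy where the
    stagger dy is chosen so an interior cell's contact fraction
    2(h - dy) / (2(w + h)) equals the target (clamped at the geometric
    maximum h / (w + h))."""
    w_cell = spec.cell_size
    h_cell = spec.cell_size * max(spec.axis_ratio, 1.0)
    c = spec.target_contact_fraction
    dy = h_cell - c * (w_cell + h_cell)
    dy = float(np.clip(dy, 0.0, h_cell))
    per_cluster = 4
    n_clusters = int(np.ceil(spec.n_cells / per_cluster))
    bbox_w = per_cluster * w_cell
    bbox_h = h_cell + dy
    ncol = int(np.ceil(np.sqrt(n_clusters)))
    nrow = int(np.ceil(n_clusters / ncol))
    size = spec.image_size or (
        int(nrow * (bbox_h + _GAP) + _GAP),
        int(ncol * (bbox_w + _GAP) + _GAP),
    )
    h, w = size
    if ncol * (bbox_w + _GAP) + _GAP > w + 1e-9 or nrow * (bbox_h + _GAP) + _GAP > h + 1e-9:
        raise PlacementError(
            f"cannot place {n_clusters} clusters of footprint "
            f"{bbox_w:.0f}x{bbox_h:.0f}px on a {h}x{w} canvas"
        )
    polys: dict[int, Polygon] = {}
    cid = 1
    for g in range(n_clusters):
        r, col = divmod(g, ncol)
        x0 = _GAP + col * (bbox_w + _GAP)
        y0 = _GAP + r * (bbox_h + _GAP)
        for j in range(per_cluster):
            if cid > spec.n_cells:
                break
            yj = y0 + (dy if j % 2 else 0.0)
            xj = x0 + j * w_cell
            polys[cid] = box(xj, yj, xj + w_cell, yj + h_cell)
            cid += 1
    return polys, size


def _true_geometry(polys: dict[int, Polygon]) -> pd.DataFrame:
    """Continuous-geometry truth: perimeter, shared length, axis extents."""
    ids = sorted(polys)
    rows = []
    for cid in ids:
        poly = polys[cid]
        shared = 0.0
        for other in ids:
            if other == cid:
                continue
            if polys[other].distance(poly) > 1e-6:
                continue
            inter = poly.boundary.intersection(polys[other].boundary)
            shared += inter.length
        mrr = poly.minimum_rotated_rectangle
        xs, ys = mrr.exterior.coords.xy
        e1 = float(np.hypot(xs[1] - xs[0], ys[1] - ys[0]))
        e2 = float(np.hypot(xs[2] - xs[1], ys[2] - ys[1]))
        major, minor = max(e1, e2), min(e1, e2)
        perim = poly.exterior.length
        rows.append(
            {
                "cell_id": cid,
                "centroid_x": poly.centroid.x,
                "centroid_y": poly.centroid.y,
                "true_perimeter": perim,
                "true_shared_length": shared,
                "true_contact_fraction": shared / perim,
                "true_major_axis": major,
                "true_minor_axis": minor,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# intensity rendering
# ---------------------------------------------------------------------

def _texture(rng: np.random.Generator, n: int, ch: ChannelParams) -> np.ndarray:
    if ch.smooth:
        return np.ones(n)
    keep = rng.random(n) >= ch.zero_fraction
    return keep * rng.gamma(ch.texture_shape, 1.0, n)


def _render_clean(
    spec: SceneSpec,
    cells: np.ndarray,
    membrane: np.ndarray,
    nucleus: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Budgeted clean channels + realized per-cell fractions table."""
    shape = cells.shape
    names = list(spec.channels)
    clean = {nm: np.full(shape, spec.channels[nm].background_level, dtype=float)
             for nm in names}
    ca, cb = spec.coloc_channels
    pair = ca in names and cb in names
    frac_rows = []
    ids = [int(i) for i in np.unique(cells) if i != 0]
    for cid in ids:
        cell = cells == cid
        comp_idx = {
            "membrane": np.nonzero(membrane == cid),
            "nucleus": np.nonzero(nucleus == cid),
            "cytoplasm": np.nonzero(cell & (membrane != cid) & (nucleus != cid)),
        }
        sizes = {k: len(v[0]) for k, v in comp_idx.items()}
        area = int(cell.sum())
        # raw textures, fixed draw order for determinism
        tex: dict[tuple[str, str], np.ndarray] = {}
        for nm in names:
            for comp in ("membrane", "nucleus", "cytoplasm"):
                tex[(nm, comp)] = _texture(rng, sizes[comp], spec.channels[nm])
        if pair:
            for comp in ("membrane", "nucleus", "cytoplasm"):
                copy = rng.random(sizes[comp]) < spec.coloc_rho
                tex[(cb, comp)] = np.where(copy, tex[(ca, comp)], tex[(cb, comp)])
        row = {"cell_id": cid, "area_px": area}
        for nm in names:
            ch = spec.channels[nm]
            total = ch.cell_amplitude * area
            budget = {
                "membrane": ch.membrane_fraction * total,
                "nucleus": ch.nucleus_fraction * total,
            }
            budget["cytoplasm"] = total - budget["membrane"] - budget["nucleus"]
            # degenerate compartments: reroute their budget, record realized
            if sizes["nucleus"] == 0:
                budget["cytoplasm"] += budget.pop("nucleus")
                budget["nucleus"] = 0.0
            if sizes["cytoplasm"] == 0:
                budget["membrane"] += budget.pop("cytoplasm")
                budget["cytoplasm"] = 0.0
            for comp in ("membrane", "nucleus", "cytoplasm"):
                if sizes[comp] == 0 or budget[comp] == 0:
                    continue
                t = tex[(nm, comp)]
                if t.sum() <= 0:
                    t = np.ones_like(t)
                clean[nm][comp_idx[comp]] += budget[comp] * t / t.sum()
            row[f"f_m_{nm}"] = budget["membrane"] / total if total > 0 else 0.0
            row[f"f_n_{nm}"] = budget["nucleus"] / total if total > 0 else 0.0
        frac_rows.append(row)
    return clean, pd.DataFrame(frac_rows)


def apply_noise(
    channels: dict[str, np.ndarray],
    noise: NoiseParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Shot (Poisson) then read (Gaussian) noise, clipped at zero counts."""
    out = {}
    for nm, clean in channels.items():
        img = rng.poisson(clean).astype(float) if noise.poisson else clean.astype(float)
        if noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, noise.gaussian_sd, clean.shape)
        out[nm] = np.clip(img, 0.0, None)
    return out


# ---------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------

_LAYOUTS = {
    "isolated": _layout_isolated,
    "chained": _layout_chained,
    "clustered": _layout_clustered,
}


def generate_scene(spec: SceneSpec) -> tuple[MultiChannelImage, SceneTruth]:
    """Render one seeded scene and its ground truth.

    Fixing ``spec.seed`` fixes the emitted image and truth bit-for-bit.
    Raises :class:`~ajquant.segmentation.PlacementError` when the
    requested cells cannot be placed without overlap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    polys, size = _LAYOUTS[spec.adjacency_mode](spec, rng)
    cells = rasterize_polygons(polys, size)
    for cid in polys:
        if not np.any(cells == cid):
            raise PlacementError(f"cell {cid} rasterized to 0 pixels (cells too small?)")
    membrane = derive_membrane_ring(cells, ring_width=spec.membrane_ring_width)

    # true nuclei: cell polygon scaled about its centroid, kept strictly
    # off the membrane ring, one 8-connected component
    nuc_polys = {
        cid: affinity.scale(p, spec.nucleus_axis_fraction, spec.nucleus_axis_fraction,
                            origin="centroid")
        for cid, p in polys.items()
    }
    nuc_raster = rasterize_polygons(nuc_polys, size)
    nucleus = np.zeros_like(cells)
    for cid in polys:
        cand = (nuc_raster == cid) & (cells == cid) & (membrane != cid)
        comp = _largest_component(cand)
        nucleus[comp] = cid

    clean, fracs = _render_clean(spec, cells, membrane, nucleus, rng)
    if spec.include_dic:
        boundary = (cells > 0) & (derive_membrane_ring(cells, ring_width=1) > 0)
        clean["DIC"] = np.where(boundary, _DIC_AMPLITUDE, 0.0) + _DIC_BACKGROUND

    noisy = apply_noise(clean, spec.noise, rng)
    image = MultiChannelImage(
        noisy,
        pixel_size=spec.pixel_size,
        metadata={"seed": spec.seed, "adjacency_mode": spec.adjacency_mode,
                  "synthetic": True},
    )
    table = _true_geometry(polys).merge(fracs, on="cell_id")
    table["coloc_rho"] = spec.coloc_rho
    table["target_contact_fraction"] = spec.target_contact_fraction
    truth = SceneTruth(
        spec=spec, polygons=polys, cells=cells, membrane=membrane,
        nucleus=nucleus, table=table, clean=clean,
    )
    return image, truth


def scene_for_contact(spec: SceneSpec, contact: float) -> SceneSpec:
    """Convenience: same scene family at another planted contact level."""
    mode = "isolated" if contact == 0 and spec.adjacency_mode == "isolated" else spec.adjacency_mode
    return replace(spec, target_contact_fraction=contact, adjacency_mode=mode)
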