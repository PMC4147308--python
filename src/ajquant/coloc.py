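"""Mask-restricted co-localization between two channels.

Implements the split Manders coefficients

    M1 = sum_{i in mask, B_i > t} A_i / sum_{i in mask} A_i
    M2 = sum_{i in mask, A_i > t} B_i / sum_{i in mask} B_i

with co-occurrence threshold t = 0 on background-subtracted images
(configurable), the per-pixel product of the differences from the mean
(PDM)

    pdm_i = (A_i - mean A)(B_i - mean B),

and the 2D frequency scatter histogram of (A_i, B_i) over the region.
The region (nucleus, membrane ring, or whole cell) is always an
explicit argument: co-localization is computed inside segmented
compartments of individual cells, never on the whole image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import MultiChannelImage
from .segmentation import CellSegmentation

__all__ = ["ColocResult", "manders", "pdm", "coloc_by_cell", "nuclear_membrane_shift"]


@dataclass
class ColocResult:
    """Co-localization summary over one region of one cell."""

    cell_id: int
    region: str
    M1: float
    M2: float
    pdm_map: np.ndarray          # full-frame, NaN outside the region
    scatter_hist: np.ndarray     # (bins, bins) counts, A on axis 0
    scatter_edges: tuple[np.ndarray, np.ndarray]
    pdm_positive_fraction: float
    n_pixels: int
    flags: str = ""


def manders(
    imageA: np.ndarray,
    imageB: np.ndarray,
    region_mask: np.ndarray,
    threshold: float = 0.0,
) -> tuple[float, float]:
    """Split Manders coefficients of A and B restricted to a mask.

    Inputs must be background-subtracted.  Channels that are all zero
    inside the mask give a NaN coefficient (missing, not 0/0).
    """
    a = np.asarray(imageA, dtype=float)[region_mask]
    b = np.asarray(imageB, dtype=float)[region_mask]
    if a.size == 0:
        raise ValueError("region mask is empty")
    sum_a, sum_b = a.sum(), b.sum()
    m1 = float(a[b > threshold].sum() / sum_a) if sum_a > 0 else np.nan
    m2 = float(b[a > threshold].sum() / sum_b) if sum_b > 0 else np.nan
    return m1, m2


def pdm(
    imageA: np.ndarray,
    imageB: np.ndarray,
    region_mask: np.ndarray,
    bins: int = 64,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """PDM map and frequency scatter histogram over a region.

    Returns ``(pdm_map, scatter_hist, (edges_a, edges_b))`` where
    ``pdm_map`` is NaN outside the region and the histogram spans each
    channel's in-region range with ``bins`` linear bins.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    a = np.asarray(imageA, dtype=float)
    b = np.asarray(imageB, dtype=float)
    av, bv = a[region_mask], b[region_mask]
    pdm_map = np.full(a.shape, np.nan)
    pdm_map[region_mask] = (av - av.mean()) * (bv - bv.mean())

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:  # constant channel: widen so the mass lands in one bin
            hi = lo + 1.0
        return np.linspace(lo, hi, bins + 1)
    ea, eb = _edges(av), _edges(bv)
    hist, _, _ = np.histogram2d(av, bv, bins=(ea, eb))
    return pdm_map, hist, (ea, eb)


def _region_mask(seg: CellSegmentation, cid: int, region: str) -> np.ndarray:
    if region == "nucleus":
        return seg.nucleus_mask(cid)
    if region == "membrane":
        return seg.membrane_mask(cid)
    if region == "cell":
        return seg.cell_mask(cid)
    raise ValueError(f"unknown region {region!r}; use nucleus, membrane or cell")


def coloc_by_cell(
    image: MultiChannelImage,
    seg: CellSegmentation,
    channel_a: str,
    channel_b: str,
    region: str = "nucleus",
    threshold: float = 0.0,
    bins: int = 64,
) -> list[ColocResult]:
    """ColocResult per cell for one region; empty regions are flagged."""
    a, b = image[channel_a], image[channel_b]
    results = []
    for cid in seg.labels:
        mask = _region_mask(seg, cid, region)
        n = int(mask.sum())
        if n == 0:
            results.append(
                ColocResult(cid, region, np.nan, np.nan, np.full(a.shape, np.nan),
                            np.zeros((bins, bins)), (np.array([]), np.array([])),
                            np.nan, 0, flags="empty_region")
            )
            continue
        m1, m2 = manders(a, b, mask, threshold=threshold)
        pdm_map, hist, edges = pdm(a, b, mask, bins=bins)
        vals = pdm_map[mask]
        flags = []
        if np.isnan(m1) or np.isnan(m2):
            flags.append("zero_channel")
        assert hist.sum() == n, "scatter histogram lost pixels"
        results.append(
            ColocResult(
                cell_id=cid, region=region, M1=m1, M2=m2, pdm_map=pdm_map,
                scatter_hist=hist, scatter_edges=edges,
                pdm_positive_fraction=float(np.mean(vals > 0)), n_pixels=n,
                flags=";".join(flags),
            )
        )
    return results


def coloc_table(results: list[ColocResult]) -> pd.DataFrame:
    """Tidy summary (drops the per-pixel maps)."""
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "region": r.region,
                "M1": r.M1,
                "M2": r.M2,
                "pdm_positive_fraction": r.pdm_positive_fraction,
                "n_pixels": r.n_pixels,
                "flags": r.flags,
            }
            for r in results
        ]
    )


def nuclear_membrane_shift(
    profiles: pd.DataFrame,
    condition_col: str = "condition",
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition summary of membrane/total and nucleus/total ratios.

    Aggregates CompartmentProfile rows (which must carry a condition
    label column) into group mean ± SEM per channel and compartment —
    the markers' relocation summary fed to the statistics stage.  A
    single-condition table is summarized with a warning; conditions
    with fewer than two cells are flagged and excluded.
    """
    import warnings

    if condition_col not in profiles.columns:
        raise ValueError(f"profiles lack a {condition_col!r} column")
    df = profiles if channels is None else profiles[profiles["channel"].isin(channels)]
    conds = df[condition_col].unique()
    if len(conds) < 2:
        warnings.warn("only one condition present; comparison skipped", stacklevel=2)
    rows = []
    for (cond, ch), grp in df.groupby([condition_col, "channel"], sort=True):
        for col, name in (("ratio_membrane", "membrane_over_total"),
                          ("ratio_nucleus", "nucleus_over_total")):
            vals = grp[col].dropna().to_numpy(float)
            flag = "too_few_cells" if len(vals) < 2 else ""
            rows.append(
                {
                    condition_col: cond,
                    "channel": ch,
                    "metric": name,
                    "n_cells": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                    "flags": flag,
                }
            )
    return pd.DataFrame(rows)
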