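"""Per-cell fluorescence-distribution statistics.

For each cell and channel, fluorescence is *summed* over the cell,
membrane-ring and nucleus masks, and the distribution of signal is
expressed as the ratios membrane/cell and nucleus/cell.  Because both
the numerator and denominator come from the same acquisition, the
ratios are invariant to the amplifier gain and zoom factor (an
"internal calibration"), so cells imaged under different settings are
comparable.  A size-normalized total (counts per pixel of cell area) is
reported as well.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .image import MultiChannelImage
from .segmentation import CellSegmentation

__all__ = ["compartment_profile", "validate_profiles", "gain_invariance_check", "PROFILE_COLUMNS"]

PROFILE_COLUMNS = [
    "cell_id",
    "channel",
    "I_total",
    "I_membrane",
    "I_nucleus",
    "ratio_membrane",
    "ratio_nucleus",
    "intensity_per_area",
    "cell_area",
    "flags",
]


def _label_sums(labels: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    return np.bincount(labels.ravel(), weights=weights.ravel(), minlength=n + 1)


def compartment_profile(
    image: MultiChannelImage,
    seg: CellSegmentation,
    channel: str | list[str] | None = None,
) -> pd.DataFrame:
    """Integrated intensities and distribution ratios per cell x channel.

    ``image`` must already be background-subtracted.  Cells with zero
    total intensity get missing (NaN) ratios flagged ``zero_total``
    rather than 0/0; cells without a nucleus mask get a NaN nucleus
    ratio flagged ``no_nucleus``.
    """
    if channel is None:
        channels = image.channel_names
    elif isinstance(channel, str):
        channels = [channel]
    else:
        channels = list(channel)
    for ch in channels:
        if ch not in image:
            raise KeyError(f"channel {ch!r} not in image; have {image.channel_names}")
    if image.shape != seg.cells.shape:
        raise ValueError(f"image shape {image.shape} != segmentation shape {seg.cells.shape}")
    seg.validate()

    ids = seg.labels
    n = max(ids, default=0)
    areas = np.bincount(seg.cells.ravel(), minlength=n + 1)
    rows = []
    for ch in channels:
        arr = image[ch]
        tot = _label_sums(seg.cells, arr, n)
        mem = _label_sums(seg.membrane, arr, n)
        nuc = _label_sums(seg.nucleus, arr, n)
        for cid in ids:
            flags = []
            i_tot, i_mem, i_nuc = tot[cid], mem[cid], nuc[cid]
            if i_tot > 0:
                r_mem = i_mem / i_tot
                r_nuc = i_nuc / i_tot
            else:
                r_mem = r_nuc = np.nan
                flags.append("zero_total")
            if cid in seg.missing_nucleus:
                r_nuc = np.nan
                flags.append("no_nucleus")
            rows.append(
                {
                    "cell_id": cid,
                    "channel": ch,
                    "I_total": i_tot,
                    "I_membrane": i_mem,
                    "I_nucleus": i_nuc,
                    "ratio_membrane": r_mem,
                    "ratio_nucleus": r_nuc,
                    "intensity_per_area": i_tot / areas[cid],
                    "cell_area": int(areas[cid]),
                    "flags": ";".join(flags),
                }
            )
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    validate_profiles(df)
    return df


def validate_profiles(df: pd.DataFrame, atol: float = 1e-9) -> None:
    """Assert the ratio-bound and additivity invariants of a profile table."""
    rm = df["ratio_membrane"].to_numpy(float)
    rn = df["ratio_nucleus"].to_numpy(float)
    ok_m = np.isnan(rm) | ((rm >= -atol) & (rm <= 1 + atol))
    ok_n = np.isnan(rn) | ((rn >= -atol) & (rn <= 1 + atol))
    both = rm + rn
    ok_sum = np.isnan(both) | (both <= 1 + atol)
    if not (ok_m.all() and ok_n.all() and ok_sum.all()):
        raise AssertionError("compartment ratios out of [0, 1] bounds")
    slack = df["I_total"].to_numpy(float) - df["I_membrane"].to_numpy(float) - df["I_nucleus"].to_numpy(float)
    if not np.all(slack >= -atol * np.maximum(df["I_total"].to_numpy(float), 1.0)):
        raise AssertionError("I_total < I_membrane + I_nucleus: masks not disjoint?")


def gain_invariance_check(
    image: MultiChannelImage,
    seg: CellSegmentation,
    channel: str,
    gain: float,
    rtol: float = 1e-9,
) -> bool:
    """True iff multiplying the channel by ``gain`` leaves both ratios
    unchanged (within ``rtol``) and scales intensity_per_area by exactly
    the gain — the internal-calibration contract."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    base = compartment_profile(image, seg, channel)
    scaled_img = image.with_channels({**image.channels, channel: image[channel] * gain})
    scaled = compartment_profile(scaled_img, seg, channel)
    for col in ("ratio_membrane", "ratio_nucleus"):
        a = base[col].to_numpy(float)
        b = scaled[col].to_numpy(float)
        same_nan = np.isnan(a) == np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=rtol, equal_nan=True)
        if not np.all(same_nan & close):
            return False
    return bool(
        np.allclose(
            scaled["intensity_per_area"].to_numpy(float),
            gain * base["intensity_per_area"].to_numpy(float),
            rtol=rtol,
        )
    )
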