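"""Multi-channel fluorescence image container.

A scene is a set of named 2D intensity grids ("channels", e.g. DAPI,
A488, A555, DIC) sharing one pixel geometry, in raw detector counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["MultiChannelImage"]


@dataclass
class MultiChannelImage:
    """Named 2D intensity grids (counts) sharing one pixel geometry.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2D float array of non-negative
        intensities in detector counts.
    pixel_size
        Physical pixel size in micrometers per pixel.
    metadata
        Free-form provenance (background scalars used, seeds, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validate()

    # -- contracts -----------------------------------------------------
    def validate(self) -> None:
        if not self.channels:
            raise ValueError("image must contain at least one channel")
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels do not share one pixel geometry: {shapes}")
        (shape,) = shapes
        if len(shape) != 2 or min(shape) == 0:
            raise ValueError(f"channels must be non-empty 2D grids, got shape {shape}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    # -- convenience ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def with_channels(self, channels: Mapping[str, np.ndarray], **meta) -> "MultiChannelImage":
        """Return a copy holding ``channels`` and merged metadata."""
        md = dict(self.metadata)
        md.update(meta)
        return MultiChannelImage(dict(channels), pixel_size=self.pixel_size, metadata=md)
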