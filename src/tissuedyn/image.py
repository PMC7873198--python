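"""Core raster containers shared by every pipeline stage.

A :class:`ChannelImage` wraps one 2-D fluorescence raster together with its
*role* in the staining scheme: the DAPI nuclear counterstain, the stained
signal of interest (e.g. p53), an optional co-stain (e.g. Ki67 or
gamma-H2AX), and an unstained *control* channel used for illumination
compensation and autofluorescence exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: The four channel roles the pipeline understands.
CHANNEL_ROLES = ("dapi", "signal", "costain", "control")


@dataclass
class ChannelImage:
    """One 2-D fluorescence intensity raster with its staining role.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities (float64 internally).
    channel_role
        One of ``dapi``, ``signal``, ``costain``, ``control``.
    name
        Free-text channel name (e.g. the fluorophore or antibody).
    pixel_size
        Physical edge length of a pixel (optional, micrometres by
        convention); carried as metadata only.
    """

    pixels: np.ndarray
    channel_role: str
    name: str = ""
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"channel_role must be one of {CHANNEL_ROLES}, got {self.channel_role!r}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Return a copy of this channel carrying new pixel data."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class Tile:
    """One crop of a parent raster, addressed by grid position and offset.

    ``row_index``/``col_index`` locate the tile in the acquisition grid;
    ``y0``/``x0`` are the pixel offsets of the tile's top-left corner in the
    parent image, which is all the stitcher needs to reassemble it.
    """

    row_index: int
    col_index: int
    y0: int
    x0: int
    pixels: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
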