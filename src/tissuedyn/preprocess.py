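"""Image I/O, background and flat-field correction, and tile stitching.

Per-frame correction follows the conventional acquisition order: subtract
the additive background first, then divide by the (mean-normalized)
illumination field, then stitch frames into a tissue-level view.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .image import CHANNEL_ROLES, ChannelImage, Tile

# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------


def write_channels(path: str | Path, channels: Dict[str, ChannelImage]) -> None:
    """Write channels as a multi-page float32 TIFF, one page per channel.

    Channel roles/names go into the TIFF image description as JSON so the
    file is self-describing; a role->page mapping can override on read.
    """
    path = Path(path)
    roles = [r for r in CHANNEL_ROLES if r in channels]
    stack = np.stack([channels[r].pixels for r in roles]).astype(np.float32)
    meta = {
        "channel_roles": roles,
        "channel_names": [channels[r].name for r in roles],
        "pixel_size": channels[roles[0]].pixel_size,
    }
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )


def read_channels(
    path: str | Path, channel_map: Optional[Dict[str, int]] = None
) -> Dict[str, ChannelImage]:
    """Read a multi-page TIFF into role-keyed channels.

    ``channel_map`` (role -> page index) overrides embedded metadata and is
    required for files written by other software.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        roles = meta.get("channel_roles")
        if not roles:
            raise ValueError(
                f"{path} carries no channel-role metadata; pass channel_map"
            )
        channel_map = {role: i for i, role in enumerate(roles)}
    names = meta.get("channel_names", [])
    out = {}
    for role, idx in channel_map.items():
        name = names[idx] if idx < len(names) else role
        out[role] = ChannelImage(
            np.clip(stack[idx].astype(np.float64), 0.0, None),
            channel_role=role,
            name=name,
            pixel_size=meta.get("pixel_size"),
        )
    return out


def write_truth(dir_path: str | Path, truth) -> None:
    """Write ground truth as a label-map TIFF + illumination TIFF + JSON."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(dir_path / "labels.tif", truth.label_map.astype(np.int32))
    tifffile.imwrite(
        dir_path / "illumination.tif", truth.illumination_field.astype(np.float32)
    )
    sidecar = {
        "nucleus_centers": truth.nucleus_centers.tolist(),
        "radii": truth.radii.tolist(),
        "positive_labels": [int(x) for x in truth.positive_labels],
        "autofluor_labels": [int(x) for x in truth.autofluor_labels],
        "crypt_assignments": {
            str(k): [int(v[0]), int(v[1])] for k, v in truth.crypt_assignments.items()
        },
        "background_level": truth.background_level,
    }
    (dir_path / "truth.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def read_truth(dir_path: str | Path):
    """Read ground truth written by :func:`write_truth`."""
    from .synthetic import GroundTruth, SyntheticImageParams

    dir_path = Path(dir_path)
    sidecar = json.loads((dir_path / "truth.json").read_text())
    return GroundTruth(
        nucleus_centers=np.asarray(sidecar["nucleus_centers"], dtype=np.float64),
        radii=np.asarray(sidecar["radii"], dtype=np.float64),
        label_map=tifffile.imread(dir_path / "labels.tif").astype(np.int32),
        positive_labels=np.asarray(sidecar["positive_labels"], dtype=int),
        autofluor_labels=np.asarray(sidecar["autofluor_labels"], dtype=int),
        illumination_field=tifffile.imread(dir_path / "illumination.tif").astype(
            np.float64
        ),
        crypt_assignments={
            int(k): (int(v[0]), int(v[1]))
            for k, v in sidecar["crypt_assignments"].items()
        },
        background_level=float(sidecar["background_level"]),
        params=SyntheticImageParams(),  # original params are not persisted
    )


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------


def background_subtract(
    image: ChannelImage, background: float | np.ndarray
) -> ChannelImage:
    """Subtract an additive background (scalar or raster), clamping at 0."""
    bg = np.asarray(background, dtype=np.float64)
    if not np.all(np.isfinite(bg)):
        raise ValueError("background must be finite")
    if bg.ndim not in (0, 2):
        raise ValueError("background must be a scalar or a 2-D raster")
    if bg.ndim == 2 and bg.shape != image.shape:
        raise ValueError(f"background shape {bg.shape} != image shape {image.shape}")
    return image.with_pixels(np.clip(image.pixels - bg, 0.0, None))


def flatfield_correct(image: ChannelImage, field: np.ndarray) -> ChannelImage:
    """Divide by the illumination field, rescaled so the field has mean 1.

    The mean-1 rescaling preserves the overall intensity scale of the
    image; a field identically 1 is the identity.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.shape != image.shape:
        raise ValueError(f"field shape {field.shape} != image shape {image.shape}")
    if not np.all(np.isfinite(field)) or field.min() <= 0:
        raise ValueError("field must be finite and strictly positive")
    norm = field / field.mean()
    return image.with_pixels(image.pixels / norm)


def estimate_flatfield(image: ChannelImage, sigma: float = 50.0) -> np.ndarray:
    """Retrospective flat-field estimate: large-kernel Gaussian smoothing.

    Standard when no reference (blank-slide) field is available; the
    control channel is the usual input because it carries no biological
    structure.  Returned field has mean 1.
    """
    smooth = ndi.gaussian_filter(image.pixels, sigma=sigma, mode="nearest")
    floor = max(smooth.max() * 1e-6, 1e-12)
    smooth = np.clip(smooth, floor, None)
    return smooth / smooth.mean()


def estimate_background(
    image: ChannelImage,
    nucleus_mask: Optional[np.ndarray] = None,
    percentile: float = 1.0,
) -> float:
    """Robust additive-background floor: a low percentile of the
    non-nucleus pixels (all pixels when no mask is given)."""
    pixels = image.pixels
    if nucleus_mask is not None:
        pixels = pixels[np.asarray(nucleus_mask) == 0]
    if pixels.size == 0:
        return 0.0
    return float(np.percentile(pixels, percentile))


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------


def stitch_tiles(tiles: Sequence[Tile]) -> np.ndarray:
    """Reassemble a tile grid into one raster, averaging overlap regions.

    The average blend is symmetric and order-independent; on tiles whose
    overlap strips agree exactly (e.g. the output of the tiler) stitching
    reproduces the parent image exactly.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    rows = {t.row_index for t in tiles}
    cols = {t.col_index for t in tiles}
    if rows != set(range(max(rows) + 1)) or cols != set(range(max(cols) + 1)):
        raise ValueError("tiles do not form a complete rectangular grid")
    if len(tiles) != (max(rows) + 1) * (max(cols) + 1):
        raise ValueError("duplicate or missing tiles in grid")
    H = max(t.y0 + t.shape[0] for t in tiles)
    W = max(t.x0 + t.shape[1] for t in tiles)
    acc = np.zeros((H, W), dtype=np.float64)
    cnt = np.zeros((H, W), dtype=np.int64)
    for t in tiles:
        h, w = t.shape
        acc[t.y0 : t.y0 + h, t.x0 : t.x0 + w] += t.pixels
        cnt[t.y0 : t.y0 + h, t.x0 : t.x0 + w] += 1
    if (cnt == 0).any():
        raise ValueError("tile grid does not cover the full output raster")
    return acc / cnt
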