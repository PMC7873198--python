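"""Nuclear segmentation from the DAPI channel.

Minimal standard realization: Gaussian smoothing, Otsu threshold,
distance-transform watershed to split touching nuclei, and an area
filter.  Deterministic for fixed input and parameters; the Otsu
threshold is relative, so the mask is invariant under multiplying the
DAPI image by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .image import ChannelImage


@dataclass
class NucleusMask:
    """Labeled nuclei: 0 = background, labels contiguous 1..n_nuclei."""

    label_map: np.ndarray
    n_nuclei: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape  # type: ignore[return-value]


def segment_nuclei(
    dapi: ChannelImage,
    min_area: float = 20.0,
    max_area: float = 2000.0,
    smoothing_sigma: float = 1.0,
    seed_min_distance: int = 5,
) -> NucleusMask:
    """Segment nuclei from a (corrected) DAPI image.

    Pipeline: Gaussian smoothing (``smoothing_sigma`` px), Otsu threshold,
    Euclidean distance transform, one watershed seed per distance plateau
    (local maxima closer than ``seed_min_distance`` merge), watershed split
    of touching nuclei, then removal of components outside
    [``min_area``, ``max_area``] pixels.  Watershed boundary pixels go to
    the basin of the nearer seed; exact ties resolve by lower label index
    (the watershed's deterministic processing order).

    A blank (constant) image yields an empty mask, not an error.
    """
    if not (0 < min_area < max_area):
        raise ValueError("require 0 < min_area < max_area")
    if dapi.channel_role != "dapi":
        warnings.warn(
            f"segmenting on channel role {dapi.channel_role!r}, not 'dapi'",
            stacklevel=2,
        )
    img = ndi.gaussian_filter(dapi.pixels, sigma=smoothing_sigma)
    if img.max() == img.min():
        return NucleusMask(np.zeros(dapi.shape, dtype=np.int32), 0)
    thr = threshold_otsu(img)
    binary = img > thr
    if not binary.any():
        return NucleusMask(np.zeros(dapi.shape, dtype=np.int32), 0)

    distance = ndi.distance_transform_edt(binary)
    peak_coords = peak_local_max(
        distance,
        min_distance=seed_min_distance,
        labels=binary,
        exclude_border=False,
    )
    peak_mask = np.zeros(binary.shape, dtype=bool)
    peak_mask[tuple(peak_coords.T)] = True
    markers, _ = ndi.label(peak_mask)
    if markers.max() == 0:
        markers, _ = ndi.label(binary)
    labels = watershed(-distance, markers, mask=binary)

    # area filter
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero((counts < min_area) | (counts > max_area))
    bad = bad[bad != 0]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    labels, _, _ = relabel_sequential(labels)
    return NucleusMask(labels.astype(np.int32), int(labels.max()))


def apply_mask(mask: NucleusMask, channel: ChannelImage) -> Dict[int, np.ndarray]:
    """Per-label pixel intensity sets of ``channel`` under the mask.

    Returns label -> 1-D array of intensities; the total number of values
    across labels equals the number of labeled pixels.
    """
    if channel.shape != mask.shape:
        raise ValueError(
            f"channel shape {channel.shape} != mask shape {mask.shape}"
        )
    flat_labels = mask.label_map.ravel()
    flat_values = channel.pixels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    sorted_values = flat_values[order]
    # bounds[i] = first index whose label is >= i + 1
    bounds = np.searchsorted(sorted_labels, np.arange(1, mask.n_nuclei + 2))
    out: Dict[int, np.ndarray] = {}
    for lab in range(1, mask.n_nuclei + 1):
        out[lab] = sorted_values[bounds[lab - 1] : bounds[lab]]
    return out


@dataclass
class LabelMatchResult:
    """Outcome of matching segmented labels to ground-truth labels."""

    matches: List[Tuple[int, int]]  # (segmented label, truth label)
    n_pred: int
    n_truth: int

    @property
    def precision(self) -> float:
        return len(self.matches) / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return len(self.matches) / self.n_truth if self.n_truth else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_labels(
    pred_map: np.ndarray, truth_map: np.ndarray, iou_threshold: float = 0.5
) -> LabelMatchResult:
    """Greedy one-to-one IoU matching of predicted vs. truth labels.

    Candidate pairs with IoU > ``iou_threshold`` are accepted in order of
    decreasing IoU, each label used at most once.
    """
    pred_map = np.asarray(pred_map)
    truth_map = np.asarray(truth_map)
    if pred_map.shape != truth_map.shape:
        raise ValueError("label maps must have the same shape")
    n_pred = int(pred_map.max())
    n_truth = int(truth_map.max())
    if n_pred == 0 or n_truth == 0:
        return LabelMatchResult([], n_pred, n_truth)
    # joint histogram of (pred, truth) label pairs
    joint = (
        pred_map.astype(np.int64) * (n_truth + 1) + truth_map.astype(np.int64)
    ).ravel()
    counts = np.bincount(joint, minlength=(n_pred + 1) * (n_truth + 1))
    inter = counts.reshape(n_pred + 1, n_truth + 1)
    area_pred = inter.sum(axis=1)
    area_truth = inter.sum(axis=0)
    pairs = []
    ps, ts = np.nonzero(inter[1:, 1:])
    for p, t in zip(ps + 1, ts + 1):
        i = inter[p, t]
        union = area_pred[p] + area_truth[t] - i
        iou = i / union if union else 0.0
        if iou > iou_threshold:
            pairs.append((iou, int(p), int(t)))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p, used_t = set(), set()
    matches = []
    for iou, p, t in pairs:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        matches.append((p, t))
    return LabelMatchResult(sorted(matches), n_pred, n_truth)
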