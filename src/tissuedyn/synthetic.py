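"""Synthetic multi-channel tissue images and qPCR tables with ground truth.

The generator emulates the statistical structure of immunofluorescence
sections of crypt-bearing epithelium: roughly disc-shaped, non-overlapping
nuclei arranged in columns ("crypts") rising from the bottom of the frame,
a basal-to-apical multiplicative decay of the stained signal along each
crypt axis, a designated fraction of signal-positive cells, a disjoint
fraction of autofluorescent contaminants that are bright in every
non-DAPI channel, a smooth multiplicative illumination field, an additive
background offset, and Poisson (photon-counting) or Gaussian noise.

Every image comes with a :class:`GroundTruth` exporting the label map,
class memberships, crypt assignments and the true illumination field, so
each downstream stage can be validated against known truth.

Also provided: tiling of a parent image into an overlapping acquisition
grid, synthetic qPCR Ct tables with known fold changes, and
summary-level signal time courses following transient ("intestine-like")
or sustained ("spleen-like") induction schedules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .image import CHANNEL_ROLES, ChannelImage, Tile

NOISE_MODELS = ("poisson", "gaussian", "none")

# Fractional center jitter relative to the lattice spacing; kept small so
# the non-overlap guarantee below stays provable.
_JITTER_FRAC = 0.10


@dataclass(frozen=True)
class SyntheticImageParams:
    """Parameters of one synthetic tissue image.

    Defaults describe a small-intestine-like section: 10 crypts of 30 cells
    (within the 20-70 cells-per-crypt range typical of crypt-to-villus
    columns), a 10% signal-positive population with a 5x gain, 5%
    autofluorescent contaminants bright (10x) in all non-DAPI channels, a
    0.9 per-position signal decay along the crypt axis, a smooth
    illumination field with 1.5x peak-to-trough ratio, and Poisson noise.
    """

    image_height: int = 600
    image_width: int = 800
    n_crypts: int = 10
    cells_per_crypt: int = 30
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.8
    positive_fraction: float = 0.10
    positive_gain: float = 5.0
    autofluor_fraction: float = 0.05
    autofluor_gain: float = 10.0
    gradient_decay: float = 0.9
    illumination_amplitude: float = 1.5
    background_level: float = 10.0
    dapi_level: float = 400.0
    signal_level: float = 200.0
    costain_level: float = 150.0
    control_level: float = 100.0
    noise_model: str = "poisson"
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        p = self
        for name in ("positive_fraction", "autofluor_fraction"):
            v = getattr(p, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if p.positive_fraction + p.autofluor_fraction > 1.0 + 1e-12:
            raise ValueError(
                "positive_fraction + autofluor_fraction must be <= 1 "
                "(classes are disjoint)"
            )
        if p.n_crypts < 1 or p.cells_per_crypt < 1:
            raise ValueError("n_crypts and cells_per_crypt must be >= 1")
        if not (0.0 < p.gradient_decay <= 1.0):
            raise ValueError("gradient_decay must be in (0, 1]")
        if p.illumination_amplitude < 1.0:
            raise ValueError("illumination_amplitude must be >= 1")
        if p.positive_gain < 1.0:
            raise ValueError("positive_gain must be >= 1")
        if p.autofluor_gain < 1.0:
            raise ValueError("autofluor_gain must be >= 1")
        for name in (
            "nucleus_radius_mean",
            "dapi_level",
            "signal_level",
            "costain_level",
            "control_level",
        ):
            if getattr(p, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nucleus_radius_sd", "background_level", "noise_sd"):
            v = getattr(p, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if p.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        # Geometry: the lattice spacing (minus jitter) must leave room for
        # two maximal nuclei between neighboring centers.
        _layout_spacings(p)  # raises if the image is too small

    @property
    def n_cells(self) -> int:
        return self.n_crypts * self.cells_per_crypt


@dataclass
class GroundTruth:
    """Exported truth for one synthetic image.

    ``crypt_assignments`` maps nucleus label -> (crypt id, position index),
    with position 0 at the crypt-base cell and strictly increasing upward.
    """

    nucleus_centers: np.ndarray  # (N, 2) array of (row, col)
    radii: np.ndarray  # (N,)
    label_map: np.ndarray  # int32 raster, 0 = background
    positive_labels: np.ndarray  # sorted int labels
    autofluor_labels: np.ndarray  # sorted int labels
    illumination_field: np.ndarray  # float raster, mean 1
    crypt_assignments: Dict[int, Tuple[int, int]]
    background_level: float
    params: SyntheticImageParams

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_centers)

    def crypt_ordered_labels(self) -> Dict[int, List[int]]:
        """Labels of each crypt ordered by position index from the base."""
        out: Dict[int, List[Tuple[int, int]]] = {}
        for label, (crypt, pos) in self.crypt_assignments.items():
            out.setdefault(crypt, []).append((pos, label))
        return {c: [lab for _, lab in sorted(v)] for c, v in sorted(out.items())}


def _radius_cap(p: SyntheticImageParams) -> float:
    return p.nucleus_radius_mean + 2.0 * p.nucleus_radius_sd


def _layout_spacings(p: SyntheticImageParams) -> Tuple[float, float, float]:
    """(margin, cell_spacing, col_spacing) of the crypt lattice.

    Raises ValueError if nuclei of the maximal radius could overlap.
    """
    r_max = _radius_cap(p)
    margin = 2.0 * r_max + 2.0
    h_avail = p.image_height - 2.0 * margin
    w_avail = p.image_width - 2.0 * margin
    if h_avail <= 0 or w_avail <= 0:
        raise ValueError("image too small for the requested nucleus size")
    cell_spacing = h_avail / max(p.cells_per_crypt - 1, 1)
    col_spacing = w_avail / max(p.n_crypts - 1, 1)
    spacing = min(
        cell_spacing if p.cells_per_crypt > 1 else np.inf,
        col_spacing if p.n_crypts > 1 else np.inf,
    )
    if spacing is not np.inf:
        min_gap = spacing * (1.0 - 2.0 * _JITTER_FRAC)
        if min_gap <= 2.0 * r_max:
            raise ValueError(
                "image too small: crypt lattice spacing "
                f"{spacing:.1f}px cannot guarantee non-overlap of nuclei "
                f"with radius up to {r_max:.1f}px"
            )
    return margin, cell_spacing, col_spacing


def generate_tissue_image(
    params: SyntheticImageParams,
) -> Tuple[Dict[str, ChannelImage], GroundTruth]:
    """Generate one four-channel tissue image plus its ground truth.

    Channel model, per nucleus pixel (before noise)::

        intensity = base_level * class_gain * field(x, y) + background

    where for the ``signal`` channel ``base_level`` additionally carries the
    per-position crypt-axis decay ``gradient_decay ** position`` and the
    ``positive_gain`` for signal-positive cells, and autofluorescent cells
    multiply every non-DAPI channel by ``autofluor_gain``.  DAPI is
    independent of the positive class.  The illumination field has mean 1,
    so ``background_level`` is the expected off-tissue intensity.

    Determinism: the same params (including ``seed``) reproduce the same
    rasters and truth bit for bit.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.image_height, p.image_width
    margin, cell_spacing, col_spacing = _layout_spacings(p)
    n = p.n_cells

    # --- nucleus centers on a jittered crypt lattice (crypt-major order) ---
    centers = np.empty((n, 2), dtype=np.float64)
    crypt_assignments: Dict[int, Tuple[int, int]] = {}
    jit_r = _JITTER_FRAC * (cell_spacing if p.cells_per_crypt > 1 else margin)
    jit_c = _JITTER_FRAC * (col_spacing if p.n_crypts > 1 else margin)
    i = 0
    for crypt in range(p.n_crypts):
        x = margin + crypt * col_spacing if p.n_crypts > 1 else W / 2.0
        for pos in range(p.cells_per_crypt):
            # position 0 = crypt base = bottom of the frame
            y = (
                H - margin - pos * cell_spacing
                if p.cells_per_crypt > 1
                else H / 2.0
            )
            centers[i, 0] = y + rng.uniform(-jit_r, jit_r)
            centers[i, 1] = x + rng.uniform(-jit_c, jit_c)
            crypt_assignments[i + 1] = (crypt, pos)
            i += 1

    radii = rng.normal(p.nucleus_radius_mean, p.nucleus_radius_sd, size=n)
    radii = np.clip(radii, 1.5, _radius_cap(p))

    # --- class memberships: round(fraction * n), disjoint, no replacement ---
    n_pos = int(round(p.positive_fraction * n))
    n_auto = int(round(p.autofluor_fraction * n))
    perm = rng.permutation(n)
    positive_labels = np.sort(perm[:n_pos] + 1)
    autofluor_labels = np.sort(perm[n_pos : n_pos + n_auto] + 1)

    # --- paint the label map ---
    label_map = np.zeros((H, W), dtype=np.int32)
    yy = np.arange(H)
    xx = np.arange(W)
    for lab in range(1, n + 1):
        cy, cx = centers[lab - 1]
        r = radii[lab - 1]
        y0, y1 = int(max(0, cy - r - 1)), int(min(H, cy + r + 2))
        x0, x1 = int(max(0, cx - r - 1)), int(min(W, cx + r + 2))
        sub_y = yy[y0:y1, None] - cy
        sub_x = xx[None, x0:x1] - cx
        disc = sub_y**2 + sub_x**2 <= r**2
        label_map[y0:y1, x0:x1][disc] = lab

    field = _illumination_field(H, W, p.illumination_amplitude)

    # --- per-label base levels per channel ---
    positions = np.array([crypt_assignments[lab][1] for lab in range(1, n + 1)])
    is_pos = np.isin(np.arange(1, n + 1), positive_labels)
    is_auto = np.isin(np.arange(1, n + 1), autofluor_labels)

    level = {
        "dapi": np.full(n, p.dapi_level),
        "signal": p.signal_level
        * (p.gradient_decay**positions)
        * np.where(is_pos, p.positive_gain, 1.0),
        "costain": np.full(n, p.costain_level),
        "control": np.full(n, p.control_level),
    }
    for role in ("signal", "costain", "control"):
        level[role] = level[role] * np.where(is_auto, p.autofluor_gain, 1.0)

    channels: Dict[str, ChannelImage] = {}
    for role in CHANNEL_ROLES:
        lut = np.concatenate([[0.0], level[role]])
        raster = lut[label_map] * field + p.background_level
        raster = _apply_noise(raster, p, rng)
        channels[role] = ChannelImage(raster, channel_role=role, name=role)

    truth = GroundTruth(
        nucleus_centers=centers,
        radii=radii,
        label_map=label_map,
        positive_labels=positive_labels.astype(int),
        autofluor_labels=autofluor_labels.astype(int),
        illumination_field=field,
        crypt_assignments=crypt_assignments,
        background_level=p.background_level,
        params=p,
    )
    return channels, truth


def _illumination_field(H: int, W: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field, mean 1, peak-to-trough ratio ``amplitude``.

    An off-center Gaussian bump — the standard low-order model of vignetting
    and uneven epi-illumination.
    """
    if amplitude == 1.0:
        return np.ones((H, W), dtype=np.float64)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = 0.40 * H, 0.35 * W
    s = 0.6 * max(H, W)
    bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s**2))
    bump = (bump - bump.min()) / (bump.max() - bump.min())  # -> [0, 1]
    field = 1.0 + (amplitude - 1.0) * bump  # trough 1, peak = amplitude
    return field / field.mean()


def _apply_noise(
    raster: np.ndarray, p: SyntheticImageParams, rng: np.random.Generator
) -> np.ndarray:
    if p.noise_model == "none":
        return raster
    if p.noise_model == "poisson":
        return rng.poisson(raster).astype(np.float64)
    noisy = raster + rng.normal(0.0, p.noise_sd, size=raster.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# Crypt annotations derived from truth
# ---------------------------------------------------------------------------


def annotations_from_truth(truth: GroundTruth, label_map: Optional[np.ndarray] = None):
    """Build crypt annotations (base point + ordered labels) from truth.

    With ``label_map=None`` the annotations refer to the truth's own label
    map.  Passing a *segmented* label map re-expresses each annotation in
    the segmentation's labels by matching nuclei to truth (IoU > 0.5);
    unmatched cells are dropped from the ordered sequence.
    """
    from .spatial import CryptAnnotation  # local import; no cycle

    mapping: Optional[Dict[int, int]] = None
    if label_map is not None:
        from .segment import match_labels

        result = match_labels(label_map, truth.label_map, iou_threshold=0.5)
        mapping = {t: s for s, t in result.matches}  # truth -> segmented

    annotations = []
    for crypt, labels in truth.crypt_ordered_labels().items():
        base = truth.nucleus_centers[labels[0] - 1]
        if mapping is not None:
            labels = [mapping[lab] for lab in labels if lab in mapping]
        if not labels:
            continue
        annotations.append(
            CryptAnnotation(
                crypt_id=crypt,
                base_point=(float(base[0]), float(base[1])),
                ordered_cells=list(labels),
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


def generate_tiles(
    image: ChannelImage | np.ndarray,
    grid_rows: int,
    grid_cols: int,
    overlap_px: int = 0,
) -> List[Tile]:
    """Split an image into a complete rectangular tile grid with overlap.

    Tile (i, j) covers the half-open core block of the regular grid plus
    ``overlap_px`` extra pixels extending into the next tile down/right
    (clipped at the image border), so neighboring tiles share strips that
    are pixel-identical by construction.
    """
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    H, W = pixels.shape
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid must have at least one row and one column")
    if overlap_px < 0:
        raise ValueError("overlap_px must be >= 0")
    if overlap_px >= H // grid_rows or overlap_px >= W // grid_cols:
        raise ValueError("overlap_px exceeds the tile core size")
    ys = [round(i * H / grid_rows) for i in range(grid_rows + 1)]
    xs = [round(j * W / grid_cols) for j in range(grid_cols + 1)]
    tiles = []
    for i in range(grid_rows):
        for j in range(grid_cols):
            y0, y1 = ys[i], min(ys[i + 1] + overlap_px, H)
            x0, x1 = xs[j], min(xs[j + 1] + overlap_px, W)
            tiles.append(
                Tile(
                    row_index=i,
                    col_index=j,
                    y0=y0,
                    x0=x0,
                    pixels=pixels[y0:y1, x0:x1].copy(),
                )
            )
    return tiles


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_qpcr_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_fold_changes: Mapping[str, Mapping[str, float]],
    control_condition: str,
    reference_gene: str = "ACTB",
    ct_ref_base: float = 16.0,
    delta_ct_baseline: float = 5.0,
    noise_sd: float = 0.2,
    replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with known fold changes.

    Model: the reference gene amplifies at ``ct_ref_base``; each target
    gene sits ``delta_ct_baseline`` cycles above it in the control
    condition, and a true fold change ``f`` in condition ``c`` lowers the
    target's Ct by ``log2(f)`` cycles.  Gaussian noise of ``noise_sd``
    cycles is added independently to every replicate well.  The reference
    gene's fold change is fixed at 1 in every condition.

    Returns a tidy table with columns sample, condition, gene, replicate, ct.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if control_condition not in conditions:
        raise ValueError(f"control_condition {control_condition!r} not in conditions")
    for gene, per_cond in true_fold_changes.items():
        for cond, fc in per_cond.items():
            if not (np.isfinite(fc) and fc > 0):
                raise ValueError(f"fold change for {gene}/{cond} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        sample = f"{cond}"
        for gene in genes:
            if gene == reference_gene:
                base = ct_ref_base
            else:
                fc = true_fold_changes.get(gene, {}).get(cond, 1.0)
                if cond == control_condition:
                    fc = 1.0
                base = ct_ref_base + delta_ct_baseline - math.log2(fc)
            for rep in range(1, replicates + 1):
                ct = base + rng.normal(0.0, noise_sd) if noise_sd > 0 else base
                rows.append((sample, cond, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# Induction schedules and summary-level time courses
# ---------------------------------------------------------------------------


def transient_schedule(
    t: float, baseline: float = 1.0, amplitude: float = 4.0,
    peak_time: float = 2.0, width: float = 0.9,
) -> float:
    """Intestine-like induction: a pulse peaking at ``peak_time`` hours that
    has decayed close to baseline by ~5 h."""
    return baseline + amplitude * math.exp(-((t - peak_time) ** 2) / (2.0 * width**2))


def sustained_schedule(
    t: float, baseline: float = 1.0, amplitude: float = 4.0, rise_time: float = 0.8,
) -> float:
    """Spleen-like induction: rises by ~2 h and stays elevated through 7 h."""
    return baseline + amplitude * (1.0 - math.exp(-t / rise_time))


SCHEDULES: Dict[str, Callable[..., float]] = {
    "transient": transient_schedule,
    "sustained": sustained_schedule,
}


def simulate_timecourse_summaries(
    schedule: Callable[[float], float] | str,
    timepoints: Sequence[float],
    tissue: str,
    treatment: str = "IR",
    n_samples: int = 3,
    noise_sd: float = 0.2,
    n_cells: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample summarized signal over a time course.

    Emulates the per-sample tissue summary (one number per stained section)
    that the imaging pipeline produces, without rendering images: value =
    schedule(t) + Gaussian noise per sample.  Returns a tidy table with
    columns tissue, treatment, time_h, sample, summary, n_cells.
    """
    if isinstance(schedule, str):
        schedule = SCHEDULES[schedule]
    rng = np.random.default_rng(seed)
    rows = []
    for t in timepoints:
        mu = schedule(float(t))
        for s in range(n_samples):
            val = mu + rng.normal(0.0, noise_sd)
            rows.append((tissue, treatment, float(t), f"s{s}", max(val, 0.0), n_cells))
    return pd.DataFrame(
        rows, columns=["tissue", "treatment", "time_h", "sample", "summary", "n_cells"]
    )


def params_at_time(
    base: SyntheticImageParams,
    t: float,
    schedule: Callable[[float], float] | str,
    seed: int,
) -> SyntheticImageParams:
    """Image parameters for timepoint ``t``: the signal level is scaled by
    the induction schedule (relative to its t->baseline value of 1)."""
    if isinstance(schedule, str):
        schedule = SCHEDULES[schedule]
    rel = schedule(float(t)) / schedule(0.0) if schedule(0.0) > 0 else schedule(float(t))
    return dataclasses.replace(base, signal_level=base.signal_level * rel, seed=seed)
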