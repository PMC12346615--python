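"""Attention heatmaps, binarized masks, and biomarker-overlap statistics.

Attention weights are spatialized onto the patch grid (min-max scaled per
slide), binarized either at the per-bag median or as the top-k% hotspot
set, and compared against binary biomarker grids (PD-L1, CD8+, CD163+).

The overlap statistic is a *coverage fraction*: the overlap area between
the marker mask and the binarized attention map divided by the marker
mask area.  Though often reported under the name IoU in this literature,
it is asymmetric; a true symmetric Jaccard index is provided separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import BiomarkerMaskSet, FeatureBag


@dataclass
class AttentionMap:
    """Per-patch attention weights in spatial form.

    ``heatmap`` holds the min-max scaled weight of the patch occupying
    each grid cell; ``populated`` flags cells actually covered by a patch
    (background cells hold 0 in ``heatmap`` and False in ``populated``).
    """

    slide_id: str
    alpha: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int]
    heatmap: np.ndarray
    populated: np.ndarray


@dataclass
class BinaryAttentionMask:
    slide_id: str
    grid: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)


def build_heatmap(bag: FeatureBag, alpha: np.ndarray, grid_shape: tuple[int, int]) -> AttentionMap:
    """Place each patch's attention weight at its grid cell, min-max
    scaled over the bag; a constant bag (including N=1) maps to all 1."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (bag.n_patches,):
        raise ValidationError(f"alpha length {alpha.shape} does not match bag N={bag.n_patches}")
    coords = bag.coords
    if coords[:, 0].min() < 0 or coords[:, 1].min() < 0 or \
       coords[:, 0].max() >= grid_shape[0] or coords[:, 1].max() >= grid_shape[1]:
        raise ValidationError(f"patch coordinates fall outside grid {grid_shape}")
    lo, hi = float(alpha.min()), float(alpha.max())
    scaled = np.ones_like(alpha) if hi == lo else (alpha - lo) / (hi - lo)
    heatmap = np.zeros(grid_shape, dtype=float)
    populated = np.zeros(grid_shape, dtype=bool)
    heatmap[coords[:, 0], coords[:, 1]] = scaled
    populated[coords[:, 0], coords[:, 1]] = True
    return AttentionMap(
        slide_id=bag.slide_id, alpha=alpha, coords=coords,
        grid_shape=tuple(grid_shape), heatmap=heatmap, populated=populated,
    )


def median_mask(amap: AttentionMap) -> BinaryAttentionMask:
    """Cell on iff its patch's attention weight is >= the median weight of
    the bag's patches (median over patches, not grid cells); so the mask
    always covers at least half the patches."""
    thr = float(np.median(amap.alpha))
    on = amap.alpha >= thr
    grid = np.zeros(amap.grid_shape, dtype=bool)
    grid[amap.coords[on, 0], amap.coords[on, 1]] = True
    return BinaryAttentionMask(slide_id=amap.slide_id, grid=grid, rule="median")


def topk_mask(amap: AttentionMap, fraction: float) -> BinaryAttentionMask:
    """Hotspot mask: the ceil(fraction * N) patches with largest attention;
    ties at the cutoff go to the lower patch index."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    n = len(amap.alpha)
    m = math.ceil(fraction * n)
    order = np.argsort(-amap.alpha, kind="stable")[:m]
    grid = np.zeros(amap.grid_shape, dtype=bool)
    grid[amap.coords[order, 0], amap.coords[order, 1]] = True
    return BinaryAttentionMask(slide_id=amap.slide_id, grid=grid, rule=f"top_fraction {fraction}")


def biomarker_overlap(mask_attn: BinaryAttentionMask, marker: np.ndarray) -> float | None:
    """Coverage fraction |marker ∧ attention| / |marker|.

    Implements the printed asymmetric form with the marker area as
    denominator.  Returns None (undefined) for an empty marker mask;
    callers exclude those slides from per-marker means.
    """
    marker = np.asarray(marker).astype(bool)
    if marker.shape != mask_attn.grid.shape:
        raise ValidationError(
            f"marker grid {marker.shape} and attention grid {mask_attn.grid.shape} differ in shape"
        )
    area = int(marker.sum())
    if area == 0:
        return None
    return float((marker & mask_attn.grid).sum() / area)


def jaccard_overlap(mask_attn: BinaryAttentionMask, marker: np.ndarray) -> float | None:
    """Symmetric Jaccard index |A ∧ B| / |A ∨ B|; optional companion to
    the asymmetric coverage fraction."""
    marker = np.asarray(marker).astype(bool)
    union = int((marker | mask_attn.grid).sum())
    if union == 0:
        return None
    return float((marker & mask_attn.grid).sum() / union)


@dataclass
class OverlapReport:
    """Per-slide, per-marker coverage values plus per-marker mean ± std
    over slides where the statistic is defined."""

    per_slide: dict[str, dict[str, float | None]]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)
    n_defined: dict[str, int] = field(default_factory=dict)


def overlap_report(
    attention_masks: Mapping[str, BinaryAttentionMask],
    mask_sets: Sequence[BiomarkerMaskSet],
) -> OverlapReport:
    """Coverage statistics for every (slide, marker) pair present in both
    collections; slides with an empty marker mask are excluded from that
    marker's mean."""
    by_slide = {ms.slide_id: ms for ms in mask_sets}
    shared = [sid for sid in attention_masks if sid in by_slide]
    if not shared:
        raise ValidationError("no slide ids shared between attention masks and biomarker masks")
    per_slide: dict[str, dict[str, float | None]] = {}
    values: dict[str, list[float]] = {}
    for sid in shared:
        attn = attention_masks[sid]
        per_slide[sid] = {}
        for marker, grid in by_slide[sid].masks.items():
            iou = biomarker_overlap(attn, grid)
            per_slide[sid][marker] = iou
            if iou is not None:
                values.setdefault(marker, []).append(iou)
    mean, std, n_defined = {}, {}, {}
    for marker, vals in values.items():
        arr = np.asarray(vals)
        mean[marker] = float(arr.mean())
        std[marker] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        n_defined[marker] = len(arr)
    return OverlapReport(per_slide=per_slide, mean=mean, std=std, n_defined=n_defined)
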