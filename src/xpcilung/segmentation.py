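"""Multi-stage segmentation of the reconstructed lung volume.

The chain mirrors how edge-enhanced lung CT is segmented in practice:

1. ribs by a high gray-value threshold (bone is far brighter than tissue);
2. an automatic air/tissue threshold at the bottom of the valley between
   the two dominant histogram peaks (Otsu's criterion as the logged
   fallback when no interior valley exists);
3. background suppression: sub-threshold voxels zeroed, survivors affinely
   rescaled to [0, 1];
4. whole airways: voxels at or below a (manually chosen) gray threshold,
   keeping only components that do not touch the volume border — in this
   reconstruction air is *low*-valued, so airway thresholds point downward
   (polarity is a flag);
5. bronchial tree: seeded 3D region growing — the maximal connected set of
   voxels satisfying the intensity predicate that contains the seed.

All operations are deterministic and idempotent; connectivity (6 or 26) is
configurable and defaults to 26.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .reconstruction import CTVolume

__all__ = [
    "HistogramModel",
    "GrowParams",
    "LabelVolume",
    "valley_threshold",
    "zero_below_and_rescale",
    "segment_bone",
    "segment_airways",
    "region_grow_3d",
]

log = logging.getLogger(__name__)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


@dataclass
class HistogramModel:
    """Gray-value histogram with detected peaks and the selected valley."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peak_values: Tuple[float, float]   # gray values of the two highest peaks
    valley_value: float                # the threshold
    used_otsu_fallback: bool = False

    def __post_init__(self) -> None:
        if not self.used_otsu_fallback:
            lo, hi = sorted(self.peak_values)
            if not (lo < self.valley_value < hi):
                raise ValueError("valley must lie strictly between the peaks")


@dataclass(frozen=True)
class GrowParams:
    """Seed voxel, intensity threshold and connectivity for region growing."""

    seed_voxel: Tuple[int, int, int]
    threshold: float
    connectivity: int = 26
    below: bool = True      # True: grow through voxels <= threshold (air)


@dataclass
class LabelVolume:
    """Integer-labeled volume; 0 is background."""

    labels: np.ndarray
    legend: Dict[int, str]
    pitch_um: float
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    def mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.legend.items() if v == name]
        return np.isin(self.labels, ids)


# ---------------------------------------------------------------------------


def valley_threshold(
    ct: CTVolume,
    bins: int = 256,
    clip_percentiles: Tuple[float, float] = (0.1, 99.9),
    allow_otsu_fallback: bool = True,
    mode: str = "two_highest",
) -> Tuple[HistogramModel, float]:
    """Automatic threshold at the bottom of the histogram valley.

    The histogram is taken over a percentile-clipped gray range (extreme
    propagation fringes would otherwise crush the interesting modes into a
    few bins), smoothed with a fixed-width moving average (bins/64), and
    the threshold is the gray value of the minimum smoothed count strictly
    between the two selected peaks; ties break toward the peak midpoint.
    Falls back to Otsu's criterion (logged) if fewer than two peaks emerge.

    ``mode`` selects the peak pair: ``"two_highest"`` takes the two highest
    smoothed peaks; ``"dark"`` pairs the dominant peak with the highest
    peak at lower gray value — the air/tissue valley in an edge-enhanced
    reconstruction, where a bone mode can outrank the air mode.
    """
    values = np.asarray(ct.values, dtype=float).ravel()
    lo, hi = np.percentile(values, clip_percentiles)
    if not hi > lo:
        raise ValueError("degenerate gray-value range")
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    width = max(bins // 64, 3)
    kernel = np.ones(width) / width
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])

    interior = np.arange(1, bins - 1)
    is_peak = (smoothed[interior] >= smoothed[interior - 1]) & (
        smoothed[interior] > smoothed[interior + 1]
    )
    if mode not in ("two_highest", "dark"):
        raise ValueError("mode must be 'two_highest' or 'dark'")
    peak_idx = interior[is_peak]
    peak_idx = peak_idx[np.argsort(smoothed[peak_idx])[::-1]]
    # peaks separated by at least two smoothing widths
    chosen = []
    for p in peak_idx:
        if len(chosen) == 1 and mode == "dark" and p >= chosen[0] - 2 * width:
            continue  # dark mode: second peak must sit at lower gray value
        if all(abs(p - q) > 2 * width for q in chosen):
            chosen.append(p)
        if len(chosen) == 2:
            break

    def _otsu_fallback(peaks=(float("nan"), float("nan"))):
        if not allow_otsu_fallback:
            raise ValueError(
                "histogram is unimodal and the Otsu fallback is disabled"
            )
        log.warning("no interior histogram valley found; falling back to Otsu")
        thr = float(threshold_otsu(values))
        model = HistogramModel(
            bin_edges=edges, counts=counts, smoothed=smoothed,
            peak_values=peaks, valley_value=thr, used_otsu_fallback=True,
        )
        return model, thr

    if len(chosen) < 2:
        return _otsu_fallback()

    p_lo, p_hi = sorted(chosen)
    between = smoothed[p_lo + 1 : p_hi]
    vmin = between.min()
    if vmin > 0.95 * min(smoothed[p_lo], smoothed[p_hi]):
        # the dip between the candidate peaks is shallow noise, not a
        # clear valley; report the peaks but threshold by Otsu's criterion
        return _otsu_fallback((float(centers[p_lo]), float(centers[p_hi])))
    candidates = np.flatnonzero(between == vmin) + p_lo + 1
    midpoint = (p_lo + p_hi) / 2.0
    valley = int(candidates[np.argmin(np.abs(candidates - midpoint))])
    thr = float(centers[valley])
    model = HistogramModel(
        bin_edges=edges, counts=counts, smoothed=smoothed,
        peak_values=(float(centers[p_lo]), float(centers[p_hi])),
        valley_value=thr,
    )
    return model, thr


def zero_below_and_rescale(ct: CTVolume, threshold: float) -> CTVolume:
    """Zero sub-threshold voxels, then min-max rescale survivors to [0, 1]."""
    v = np.asarray(ct.values, dtype=np.float32)
    if threshold > v.max():
        raise ValueError("threshold exceeds the gray-value maximum: "
                         "every voxel would be zeroed")
    keep = v >= threshold
    out = np.zeros_like(v)
    vmax = v[keep].max()
    vmin = v[keep].min()
    if vmax > vmin:
        out[keep] = (v[keep] - vmin) / (vmax - vmin)
    else:
        out[keep] = 1.0
    return CTVolume(values=out, pitch_um=ct.pitch_um,
                    meta={**ct.meta, "rescaled": True, "threshold": threshold})


def segment_bone(
    ct: CTVolume,
    bone_threshold: float,
    min_voxels: int = 10,
    connectivity: int = 26,
    open_iterations: int = 0,
    exclude_mask: Optional[np.ndarray] = None,
) -> LabelVolume:
    """Threshold-based rib extraction: voxels at or above ``bone_threshold``,
    with components smaller than ``min_voxels`` discarded.

    Edge enhancement paints bright fringe shells around air cavities that
    can reach bone-like gray values; pass the (dilated) airway mask as
    ``exclude_mask`` to remove that band, and/or set ``open_iterations``
    > 0 to open away one-voxel-thick shells.
    """
    mask = ct.values >= bone_threshold
    if exclude_mask is not None:
        mask &= ~np.asarray(exclude_mask, bool)
    if open_iterations > 0 and mask.any():
        mask = ndi.binary_opening(
            mask, ndi.generate_binary_structure(3, 1),
            iterations=open_iterations,
        )
    struct = _structure(connectivity)
    lab, n = ndi.label(mask, structure=struct)
    if n and min_voxels > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_voxels) + 1
        mask &= ~np.isin(lab, small)
    if not mask.any():
        log.warning("bone mask is empty at threshold %g", bone_threshold)
    labels = mask.astype(np.uint32)
    return LabelVolume(labels=labels, legend={1: "bone"}, pitch_um=ct.pitch_um,
                       meta={"threshold": bone_threshold})


def segment_airways(
    ct: CTVolume,
    airway_threshold: float,
    connectivity: int = 26,
    fill_holes: bool = True,
) -> LabelVolume:
    """Whole-airway mask: low-valued voxels not connected to the border.

    Air reconstructs dark, so the mask is ``values <= threshold``; every
    connected component touching the volume border (the air surrounding the
    body) is removed, leaving the lung-interior air: bronchial tree plus
    alveoli.

    ``fill_holes`` (default) fills enclosed cavities in the retained mask:
    Fresnel fringes oscillate *inside* air lumina, so a bare threshold
    yields hollow shells; air spaces are solid cavities, and filling them
    restores their volume.
    """
    mask = ct.values <= airway_threshold
    if not mask.any():
        raise ValueError(
            f"no voxel at or below {airway_threshold!r}; raise the threshold"
        )
    struct = _structure(connectivity)
    lab, n = ndi.label(mask, structure=struct)
    border_labels = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ]))
    border_labels = border_labels[border_labels > 0]
    keep = mask & ~np.isin(lab, border_labels)
    if not keep.any():
        raise ValueError(
            "every low-intensity component touches the border; the airway "
            "threshold is probably too low (or polarity is inverted)"
        )
    if fill_holes:
        keep = ndi.binary_fill_holes(keep)
    return LabelVolume(labels=keep.astype(np.uint32), legend={1: "airways"},
                       pitch_um=ct.pitch_um,
                       meta={"threshold": airway_threshold,
                             "connectivity": connectivity,
                             "fill_holes": fill_holes})


def region_grow_3d(ct: CTVolume, params: GrowParams) -> LabelVolume:
    """Seeded 3D region growing under an intensity predicate.

    Returns the maximal connected set (at the chosen connectivity)
    containing the seed in which every voxel satisfies the predicate
    (``<= threshold`` for air by default).  Being set-valued it is
    order-independent and deterministic.
    """
    seed = tuple(int(i) for i in params.seed_voxel)
    v = ct.values
    if any(not 0 <= s < n for s, n in zip(seed, v.shape)):
        raise ValueError(f"seed voxel {seed} outside the volume {v.shape}")
    seed_value = float(v[seed])
    ok = seed_value <= params.threshold if params.below else seed_value >= params.threshold
    if not ok:
        raise ValueError(
            f"seed voxel {seed} (gray {seed_value:.4g}) does not satisfy the "
            f"{'<=' if params.below else '>='} {params.threshold:.4g} predicate"
        )
    mask = v <= params.threshold if params.below else v >= params.threshold
    lab, _ = ndi.label(mask, structure=_structure(params.connectivity))
    region = lab == lab[seed]
    return LabelVolume(labels=region.astype(np.uint32),
                       legend={1: "bronchial_tree"}, pitch_um=ct.pitch_um,
                       meta={"seed_voxel": list(seed),
                             "threshold": params.threshold,
                             "connectivity": params.connectivity,
                             "below": params.below})
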