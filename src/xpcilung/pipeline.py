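"""End-to-end pipeline: phantom -> projections -> CT -> labels -> table.

``run_all`` chains every stage on the synthetic phantom with one seed and
records every parameter in a run manifest, so a run is reproducible from
the manifest alone.  Individual stage functions are importable for partial
runs and for tests.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as xio
from .config import (
    beam_geometry_from_config, merge_config, phantom_spec_from_config,
)
from .forward_model import ProjectionSet, acquire_ct
from .morphometry import label_components, measure_all
from .phantom import PhantomVolume, RefractiveVolume, rasterize
from .reconstruction import CTVolume, reconstruct_volume
from .segmentation import (
    GrowParams, LabelVolume, region_grow_3d, segment_airways, segment_bone,
    valley_threshold, zero_below_and_rescale,
)

log = logging.getLogger(__name__)

__all__ = ["run_all", "recon_index_of_world", "world_of_recon_index",
           "auto_seed_voxel", "mask_on_recon_grid"]


def mask_on_recon_grid(
    mask: np.ndarray,
    phantom_pitch_um: float,
    ct: CTVolume,
    extent_um: Tuple[float, float, float],
    detector_offset_um: Tuple[float, float],
) -> np.ndarray:
    """Nearest-neighbor resampling of a phantom-grid mask onto the CT grid.

    Used to compare segmentations against planted ground truth."""
    import scipy.ndimage as ndi

    nz, ny, nx = ct.values.shape
    z_w = detector_offset_um[0] + (np.arange(nz) + 0.5) * ct.pitch_um
    y_w = (np.arange(ny) - (ny - 1) / 2.0) * ct.pitch_um + extent_um[1] / 2.0
    x_w = (np.arange(nx) - (nx - 1) / 2.0) * ct.pitch_um + extent_um[2] / 2.0
    zi = z_w / phantom_pitch_um - 0.5
    yi = y_w / phantom_pitch_um - 0.5
    xi = x_w / phantom_pitch_um - 0.5
    grids = np.meshgrid(zi, yi, xi, indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    out = ndi.map_coordinates(mask.astype(np.uint8), coords, order=0,
                              mode="constant", cval=0)
    return out.reshape(nz, ny, nx).astype(bool)


def recon_index_of_world(
    world_um: np.ndarray,
    ct: CTVolume,
    extent_um: Tuple[float, float, float],
    detector_offset_um: Tuple[float, float],
) -> Tuple[int, int, int]:
    """Map a phantom world point (z, y, x µm) to reconstruction indices.

    Rows follow the binned detector grid (offset ``detector_offset_um``);
    in-plane the rotation axis (the volume center) sits at pixel
    ``(n - 1) / 2``.
    """
    pitch = ct.pitch_um
    nz, ny, nx = ct.values.shape
    iz = int(round((world_um[0] - detector_offset_um[0]) / pitch - 0.5))
    iy = int(round((world_um[1] - extent_um[1] / 2.0) / pitch + (ny - 1) / 2.0))
    ix = int(round((world_um[2] - extent_um[2] / 2.0) / pitch + (nx - 1) / 2.0))
    return iz, iy, ix


def world_of_recon_index(
    index: Tuple[int, int, int],
    ct: CTVolume,
    extent_um: Tuple[float, float, float],
    detector_offset_um: Tuple[float, float],
) -> np.ndarray:
    pitch = ct.pitch_um
    nz, ny, nx = ct.values.shape
    z = detector_offset_um[0] + (index[0] + 0.5) * pitch
    y = (index[1] - (ny - 1) / 2.0) * pitch + extent_um[1] / 2.0
    x = (index[2] - (nx - 1) / 2.0) * pitch + extent_um[2] / 2.0
    return np.array([z, y, x])


def auto_seed_voxel(
    phantom: PhantomVolume,
    ct: CTVolume,
    detector_offset_um: Tuple[float, float],
    mask: Optional[np.ndarray] = None,
) -> Tuple[int, int, int]:
    """Pick a region-growing seed inside the trachea lumen.

    Maps a point 60% down the root branch into the reconstruction and
    refines to the darkest voxel in a 5³ neighborhood (the lumen center);
    with ``mask`` given, refines instead to the nearest mask voxel within
    that neighborhood."""
    root = phantom.branches[0]
    point = root.start_um + root.direction * 0.6 * np.linalg.norm(
        root.end_um - root.start_um
    )
    iz, iy, ix = recon_index_of_world(point, ct, phantom.spec.extent_um,
                                      detector_offset_um)
    v = ct.values
    lo = np.maximum([iz - 4, iy - 4, ix - 4], 0)
    hi = np.minimum([iz + 5, iy + 5, ix + 5], v.shape)
    if mask is not None:
        window = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        hits = np.argwhere(window)
        if len(hits) == 0:
            raise ValueError(
                "no airway-mask voxel near the trachea; cannot place the "
                "region-growing seed automatically"
            )
        center = np.array([iz, iy, ix]) - lo
        rel = hits[np.argmin(np.linalg.norm(hits - center, axis=1))]
    else:
        window = v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        rel = np.unravel_index(np.argmin(window), window.shape)
    return tuple(int(l + r) for l, r in zip(lo, rel))


def run_all(
    overrides: Optional[Dict[str, Any]] = None,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
    progress: bool = False,
) -> Dict[str, Any]:
    """Run phantom generation through morphometry; return all artifacts.

    Returns a dict with the phantom (and its ground truth), the projection
    set, the CT volume, the segmentation label volumes, the morphometry
    table and the manifest.  With ``out_dir`` set, every artifact is also
    written to disk (TIFF/CSV/JSON).
    """
    cfg = merge_config(overrides)
    if seed is not None:
        cfg["seed"] = int(seed)
    base_seed = int(cfg["seed"])

    spec = phantom_spec_from_config(cfg)
    geometry = beam_geometry_from_config(cfg)

    log.info("rasterizing phantom (%s voxels)", spec.shape)
    phantom, refractive = rasterize(spec, energy_keV=geometry.energy_keV)

    log.info("acquiring %d projections", geometry.n_angles)
    projections = acquire_ct(
        refractive, geometry, seed=base_seed + 1,
        propagator=cfg["propagator"], progress=progress,
    )

    log.info("reconstructing")
    ct = reconstruct_volume(projections, cfg["reconstruction"]["filter"],
                            progress=progress)
    offset = projections.meta["detector_offset_um"]

    seg_cfg = cfg["segmentation"]
    # air reconstructs dark; pair the dominant (tissue) mode with the dark
    # (air) mode so a bone mode cannot hijack the valley
    hist_model, valley = valley_threshold(ct, mode="dark")
    airway_thr = seg_cfg["airway_threshold"]
    if airway_thr is None:
        # the valley keeps the mask conservative: a milder (midpoint)
        # threshold thickens the fringe-ring network until lung air
        # percolates to the border air and is discarded with it.  The
        # volume the deep threshold shaves off is restored by hole
        # filling in segment_airways.
        if not hist_model.used_otsu_fallback:
            airway_thr = valley
        elif np.all(np.isfinite(hist_model.peak_values)):
            air_peak, tissue_peak = sorted(hist_model.peak_values)
            airway_thr = air_peak + 0.4 * (tissue_peak - air_peak)
        else:
            airway_thr = valley
    rescaled = zero_below_and_rescale(ct, valley)

    connectivity = int(seg_cfg["connectivity"])
    airways = segment_airways(ct, airway_thr, connectivity=connectivity,
                              fill_holes=True)

    bone_thr = seg_cfg["bone_threshold"]
    if bone_thr is None:
        # bone interiors reconstruct only moderately above tissue (the
        # bright values sit in the rim fringes), so the automatic cut is
        # a robust three-sigma excursion above the tissue mode
        if np.all(np.isfinite(hist_model.peak_values)):
            p_hi = max(hist_model.peak_values)
        else:
            p_hi = float(np.median(ct.values[ct.values > airway_thr]))
        # noise scale from the left (air-side) flank of the tissue mode,
        # which the bone tail cannot contaminate
        left = ct.values[(ct.values > airway_thr) & (ct.values < p_hi)]
        if left.size == 0:
            left = ct.values[ct.values <= p_hi]
        sigma = 1.4826 * float(np.median(p_hi - left))
        bone_thr = p_hi + 3.0 * sigma
    bone = segment_bone(ct, bone_thr, connectivity=connectivity,
                        open_iterations=1, min_voxels=50)

    seed_voxel = seg_cfg["seed_voxel"]
    if seed_voxel is None:
        seed_voxel = auto_seed_voxel(phantom, ct, offset,
                                     mask=airways.mask("airways"))
    # grow the bronchial tree on the hole-filled airway mask: internal
    # fringes make the raw gray predicate hollow and fragment thin branches
    airway_binary = CTVolume(
        values=airways.mask("airways").astype(np.float32),
        pitch_um=ct.pitch_um, meta={"derived_from": "airways"},
    )
    grow = GrowParams(seed_voxel=tuple(seed_voxel), threshold=0.5,
                      connectivity=connectivity, below=False)
    tree = region_grow_3d(airway_binary, grow)

    alveolar_mask = airways.mask("airways") & ~tree.mask("bronchial_tree")
    min_vox = max(
        int(round(cfg["morphometry"]["min_component_volume_um3"] / ct.pitch_um**3)),
        1,
    )
    alveoli = label_components(alveolar_mask, connectivity=connectivity,
                               pitch_um=ct.pitch_um, min_voxels=min_vox)
    stats = measure_all(alveoli)
    # alveoli are near-spheroidal; elongated leftovers (fringe rings around
    # ribs, unresolved duct fragments) are not alveoli
    max_ratio = float(cfg["morphometry"]["max_aspect_ratio"])
    if len(stats):
        rejected = stats[stats["ratio"] > max_ratio]["id"].tolist()
        if rejected:
            alveoli.labels[np.isin(alveoli.labels, rejected)] = 0
            for rid in rejected:
                alveoli.legend.pop(int(rid), None)
            stats = stats[stats["ratio"] <= max_ratio].reset_index(drop=True)

    manifest = {
        "config": cfg,
        "seed": base_seed,
        "valley_threshold": float(valley),
        "airway_threshold": float(airway_thr),
        "bone_threshold": float(bone_thr),
        "seed_voxel": list(seed_voxel),
        "detector_offset_um": list(offset),
        "sim_pitch_um": projections.meta["sim_pitch_um"],
        "recon_shape": list(ct.values.shape),
        "n_alveoli_measured": int(len(stats)),
        "units": {"mesh_and_tables": "um"},
        "ground_truth": [
            {"id": a.id, "center_um": a.center_um.tolist(),
             "diameter_um": a.diameter_um}
            for a in phantom.alveoli
        ],
    }

    result = {
        "config": cfg,
        "phantom": phantom,
        "refractive": refractive,
        "projections": projections,
        "ct": ct,
        "histogram": hist_model,
        "rescaled": rescaled,
        "bone": bone,
        "airways": airways,
        "tree": tree,
        "alveoli": alveoli,
        "stats": stats,
        "manifest": manifest,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        xio.write_volume(out / "phantom_labels.tif",
                         phantom.structure.astype(np.uint32), spec.pitch_um)
        pd.DataFrame(
            [{"id": a.id, "cx_um": a.center_um[2], "cy_um": a.center_um[1],
              "cz_um": a.center_um[0], "diameter_um": a.diameter_um}
             for a in phantom.alveoli]
        ).to_csv(out / "ground_truth.csv", index=False)
        xio.write_volume(out / "projections.tif", projections.images,
                         geometry.detector_pitch_um, projections.meta)
        xio.write_volume(out / "flat.tif", projections.flat,
                         geometry.detector_pitch_um)
        xio.write_ct(out / "ct.tif", ct)
        xio.write_labels(out / "bone.tif", bone)
        xio.write_labels(out / "airways.tif", airways)
        xio.write_labels(out / "tree.tif", tree)
        xio.write_labels(out / "alveoli.tif", alveoli)
        xio.write_stats(out / "alveolus_stats.csv", stats)
        xio.write_manifest(out / "manifest.json", manifest)
        result["out_dir"] = out
    return result
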