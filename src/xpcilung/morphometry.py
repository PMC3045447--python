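"""Per-alveolus 3D morphometry.

For every labeled component the module reports volume, equivalent diameter
(the diameter of the sphere with the same volume), 3D maximum and minimum
Feret (caliper) diameters and their ratio (a shape index: ~1 for
spheroids), centroid, and iso-surface area — the quantities used to
characterize alveoli in micro-CT work.

Conventions:

* Feret diameters are measured between parallel planes over surface-voxel
  centers, plus one voxel pitch so that a single voxel has diameter
  ``pitch`` rather than zero.  ``d_max`` is the exact maximum pairwise
  distance (with a convex-hull pre-reduction for large components);
  ``d_min`` is the minimal projected caliper width over a 3-degree
  orientation grid.
* Surface area comes from a marching-cubes iso-surface at level 0.5 after
  a mild Gaussian smoothing (sigma 0.5 voxel) of the binary grid, which
  removes the voxelization staircase with little erosion even for coarsely
  resolved bodies; plain voxel-face counting is the fallback for components
  too small to smooth (and the exact answer for cubes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area

from .segmentation import LabelVolume, _structure

__all__ = [
    "AlveolusStats",
    "label_components",
    "equivalent_diameter",
    "feret_diameters",
    "surface_area",
    "measure_all",
]

log = logging.getLogger(__name__)

STATS_COLUMNS = [
    "id", "volume_um3", "eq_diam_um", "dmax_um", "dmin_um", "ratio",
    "surface_area_um2", "cx_um", "cy_um", "cz_um",
]


@dataclass(frozen=True)
class AlveolusStats:
    id: int
    volume_um3: float
    eq_diam_um: float
    dmax_um: float
    dmin_um: float
    ratio: float
    surface_area_um2: float
    centroid_um: Tuple[float, float, float]   # (z, y, x)


def label_components(
    mask: np.ndarray,
    connectivity: int = 26,
    pitch_um: float = 1.0,
    min_voxels: int = 1,
) -> LabelVolume:
    """Label connected components, ordered by minimum linear voxel index.

    Components smaller than ``min_voxels`` are dropped (label 0).
    """
    lab, n = ndi.label(np.asarray(mask, bool), structure=_structure(connectivity))
    if n and min_voxels > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_voxels) + 1
        lab[np.isin(lab, small)] = 0
    # relabel 1..k by first (raster-order) occurrence == minimum linear index
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    order = flat[nz]
    _, first_pos = np.unique(order, return_index=True)
    old_ids = order[np.sort(first_pos)]
    remap = np.zeros(int(lab.max()) + 1, dtype=np.uint32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1, dtype=np.uint32)
    labels = remap[lab]
    legend = {int(i): f"alveolus_{i}" for i in range(1, len(old_ids) + 1)}
    return LabelVolume(labels=labels, legend=legend, pitch_um=pitch_um,
                       meta={"connectivity": connectivity,
                             "min_voxels": min_voxels})


def equivalent_diameter(component: np.ndarray, pitch_um: float) -> float:
    """Diameter of the equal-volume sphere: (6 V / pi)^(1/3)."""
    n = int(np.count_nonzero(component))
    if n == 0:
        raise ValueError("empty component")
    volume = n * pitch_um**3
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def _surface_voxel_centers(component: np.ndarray, pitch_um: float) -> np.ndarray:
    comp = np.asarray(component, bool)
    eroded = ndi.binary_erosion(comp, ndi.generate_binary_structure(3, 1),
                                border_value=0)
    surf = comp & ~eroded
    return np.argwhere(surf).astype(float) * pitch_um


_ORIENTATION_STEP_DEG = 3.0


def _orientation_grid(step_deg: float = _ORIENTATION_STEP_DEG) -> np.ndarray:
    """Unit directions covering a hemisphere on a (polar, azimuth) grid."""
    thetas = np.deg2rad(np.arange(0.0, 90.0 + step_deg, step_deg))
    phis = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs = [np.array([1.0, 0.0, 0.0])]
    for t in thetas[1:]:
        for p in phis:
            dirs.append(np.array([
                np.cos(t), np.sin(t) * np.cos(p), np.sin(t) * np.sin(p)
            ]))
    return np.array(dirs)


def feret_diameters(component: np.ndarray, pitch_um: float) -> Tuple[float, float]:
    """3D maximum and minimum Feret (caliper) diameters in micrometres.

    Measured over surface-voxel centers and corrected by +1 pitch for the
    voxel extent.  ``d_max`` is exact (pairwise distances, convex-hull
    pre-reduction above 400 surface points); ``d_min`` scans projected
    widths over a 3-degree orientation hemisphere.
    """
    if not np.count_nonzero(component):
        raise ValueError("empty component")
    pts = _surface_voxel_centers(component, pitch_um)
    if len(pts) > 400:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:   # degenerate (flat/collinear) point sets
            pass
    if len(pts) == 1:
        return pitch_um, pitch_um
    d_max = float(pdist(pts).max()) + pitch_um
    dirs = _orientation_grid()
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0) + pitch_um
    d_min = float(widths.min())
    return d_max, d_min


def surface_area(
    component: np.ndarray,
    pitch_um: float,
    method: str = "mesh",
    smooth: bool = True,
) -> float:
    """Surface area of a binary component in square micrometres.

    ``method='mesh'``: marching-cubes iso-surface at level 0.5, after a
    Gaussian smoothing pass (sigma 0.5 voxel) when ``smooth`` (the default;
    staircase suppression with negligible erosion).  For well-resolved
    components (>= 16 voxels across) three volume-preserving Taubin passes
    on the mesh additionally remove the residual voxel-scale ripple, so
    the estimate converges to the analytic area as the pitch shrinks; for
    coarser components the passes are skipped, where their erosion would
    exceed the ripple they remove.  Falls back to voxel-face counting
    (with a log notice) when the component is too small for a level-0.5
    crossing to survive smoothing.  ``method='voxel'``: exact exposed
    voxel-face area.
    """
    comp = np.asarray(component, bool)
    if not comp.any():
        raise ValueError("empty component")
    if method not in ("mesh", "voxel"):
        raise ValueError("method must be 'mesh' or 'voxel'")
    if method == "voxel":
        return _voxel_face_area(comp, pitch_um)
    padded = np.pad(comp, 2).astype(float)
    if smooth:
        padded = ndi.gaussian_filter(padded, sigma=0.5)
    if padded.max() <= 0.5:
        log.warning("component too small for iso-surface extraction; "
                    "using voxel-face area")
        return _voxel_face_area(comp, pitch_um)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=(pitch_um,) * 3
    )
    extents = [int(s.stop - s.start)
               for s in ndi.find_objects(comp.astype(np.uint8))[0]]
    if smooth and min(extents) >= 16:
        import trimesh

        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=-0.53, iterations=3)
        return float(tm.area)
    return float(mesh_surface_area(verts, faces))


def _voxel_face_area(comp: np.ndarray, pitch_um: float) -> float:
    comp = np.pad(comp, 1)
    faces = 0
    for axis in range(3):
        diff = np.diff(comp.astype(np.int8), axis=axis)
        faces += int(np.count_nonzero(diff))
    return faces * pitch_um**2


def measure_all(label_volume: LabelVolume) -> pd.DataFrame:
    """One morphometric record per label, sorted by id.

    Columns: id, volume_um3, eq_diam_um, dmax_um, dmin_um, ratio,
    surface_area_um2, cx_um, cy_um, cz_um (centroid; c_z is the axial /
    slice coordinate).
    """
    lab = label_volume.labels
    pitch = label_volume.pitch_um
    ids = np.unique(lab)
    ids = ids[ids > 0]
    records = []
    for i in ids:
        comp = lab == i
        # crop for speed
        sl = ndi.find_objects(comp.astype(np.uint8))[0]
        comp = comp[sl]
        eq_d = equivalent_diameter(comp, pitch)
        d_max, d_min = feret_diameters(comp, pitch)
        area = surface_area(comp, pitch)
        n = int(np.count_nonzero(comp))
        cz, cy, cx = (
            (np.array(ndi.center_of_mass(comp))
             + np.array([s.start for s in sl]) + 0.5) * pitch
        )
        records.append({
            "id": int(i),
            "volume_um3": n * pitch**3,
            "eq_diam_um": eq_d,
            "dmax_um": d_max,
            "dmin_um": d_min,
            "ratio": d_max / d_min,
            "surface_area_um2": area,
            "cx_um": float(cx),
            "cy_um": float(cy),
            "cz_um": float(cz),
        })
    return pd.DataFrame.from_records(records, columns=STATS_COLUMNS)
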