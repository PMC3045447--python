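"""Iso-surface extraction, plane clipping and mesh export.

Surface rendering of the segmented structures (ribs, airways, bronchial
tree, single alveoli) works on triangulated level-set surfaces; meshes are
in world micrometres and exported to STL/PLY/OBJ via trimesh.  STL carries
no units by format, so the micrometre convention is recorded in the run
manifest rather than the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
from skimage.measure import marching_cubes

__all__ = ["SurfaceMesh", "extract_isosurface", "export_mesh", "read_mesh",
           "clip_mesh"]

_FORMATS = ("stl", "ply", "obj")


@dataclass
class SurfaceMesh:
    """Triangle mesh in world micrometres."""

    vertices: np.ndarray       # (n, 3) float, (z, y, x) µm
    faces: np.ndarray          # (m, 3) int vertex indices
    name: Optional[str] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)


def extract_isosurface(
    volume: np.ndarray,
    iso_level: float,
    pitch_um: float = 1.0,
    name: Optional[str] = None,
) -> SurfaceMesh:
    """Marching-cubes triangulation of the ``iso_level`` level set.

    Vertices are scaled to micrometres; closed binary components yield
    watertight sphere-topology meshes (Euler characteristic 2).
    """
    v = np.asarray(volume, dtype=float)
    if not (v.min() < iso_level < v.max()):
        raise ValueError(
            f"iso level {iso_level} outside the value range "
            f"[{v.min():.4g}, {v.max():.4g}]"
        )
    padded = np.pad(v, 1, mode="constant", constant_values=v.min())
    verts, faces, _, _ = marching_cubes(padded, level=iso_level,
                                        spacing=(pitch_um,) * 3)
    verts = verts - pitch_um  # undo the pad offset
    return SurfaceMesh(vertices=verts, faces=faces, name=name)


def export_mesh(mesh: SurfaceMesh, path: str | Path, fmt: Optional[str] = None) -> Path:
    """Write the mesh to STL, PLY or OBJ (format from ``fmt`` or the suffix)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}")
    if mesh.n_vertices == 0 or len(mesh.faces) == 0:
        raise ValueError("refusing to export an empty mesh")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(path, file_type=fmt)
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), force="mesh", process=False)
    return SurfaceMesh(vertices=np.asarray(tm.vertices),
                       faces=np.asarray(tm.faces),
                       name=Path(path).stem)


def clip_mesh(
    mesh: SurfaceMesh,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
) -> SurfaceMesh:
    """Keep the half-space the normal points into, splitting crossing faces.

    The cut is left open (no cap), matching the cut-away views used to
    expose the inside of rendered airway models.
    """
    normal = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValueError("plane normal must be non-degenerate")
    tm = mesh.to_trimesh()
    clipped = trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=normal / norm, plane_origin=np.asarray(plane_point, float),
        cap=False,
    )
    if clipped is None:
        return SurfaceMesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int),
                           name=mesh.name)
    return SurfaceMesh(vertices=np.asarray(clipped.vertices),
                       faces=np.asarray(clipped.faces), name=mesh.name)
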