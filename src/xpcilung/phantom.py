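"""Digital mouse-lung phantom with analytic ground truth.

The phantom is deliberately minimal anatomy: a soft-tissue body cylinder,
bone rib arcs near its surface, an air-filled binary airway tree descending
from a trachea, and spherical air alveoli attached near the terminal
branches.  Spheres-on-a-binary-tree is the simplest geometry that exercises
every downstream stage — edge enhancement at air/tissue interfaces, tree
segmentation by region growing, and per-alveolus morphometry — while every
planted structure has an analytic volume, surface area and diameter to
recover.

Coordinates: world positions are (z, y, x) in micrometres, matching array
index order; the origin sits at the volume corner and voxel ``i`` is sampled
at its center ``(i + 0.5) * pitch``.  The z axis is vertical (the CT
rotation axis); the trachea descends along +z.

Alveoli are placed with a small tissue gap between sphere and parent branch
(default 26 µm, two detector pixels) so that each alveolus is a separate
air component both in the label volume and in the blurred reconstruction;
rejection sampling enforces pairwise clearance as well.  Real alveolar sacs
open into their ducts and share walls — separability is traded for
per-object ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .materials import MaterialTable, build_material_table

__all__ = [
    "AirwayTreeParams",
    "AlveolarParams",
    "RibParams",
    "LungPhantomSpec",
    "Branch",
    "AlveolusTruth",
    "PhantomVolume",
    "RefractiveVolume",
    "build_geometry",
    "generate_airway_tree",
    "populate_alveoli",
    "rasterize",
    "default_phantom_spec",
]

# structure codes in PhantomVolume.structure
BACKGROUND_AIR = 0
SOFT_TISSUE = 1
BONE = 2
TREE_AIR = 3
ALVEOLUS_BASE = 10  # alveolus id k -> code ALVEOLUS_BASE + k - 1


@dataclass(frozen=True)
class AirwayTreeParams:
    depth: int = 5                      # bifurcation generations (>=1)
    root_radius_um: float = 50.0
    radius_ratio: float = 0.85          # child radius / parent radius
    branch_angle_deg: Tuple[float, float] = (30.0, 55.0)
    root_length_um: float = 200.0
    length_ratio: float = 0.82
    root_start_um: Tuple[float, float, float] = (90.0, 512.0, 512.0)  # (z,y,x)


@dataclass(frozen=True)
class AlveolarParams:
    count: int = 21
    d_range_um: Tuple[float, float] = (100.0, 150.0)  # immature-mouse range
    gap_um: float = 26.0        # tissue gap branch tip -> sphere surface
    jitter_deg: float = 130.0   # attachment direction cone half-angle
    max_tries_per_alveolus: int = 800


@dataclass(frozen=True)
class RibParams:
    count: int = 3
    tube_radius_um: float = 60.0
    arc_radius_um: float = 410.0
    arc_span_deg: float = 110.0


@dataclass(frozen=True)
class LungPhantomSpec:
    extent_um: Tuple[float, float, float] = (1024.0, 1024.0, 1024.0)  # (z,y,x)
    pitch_um: float = 4.0
    body_radius_um: float = 480.0
    tree: AirwayTreeParams = field(default_factory=AirwayTreeParams)
    alveoli: AlveolarParams = field(default_factory=AlveolarParams)
    ribs: RibParams = field(default_factory=RibParams)
    seed: int = 0
    # minimum tissue clearance between lung air and ribs / the body wall.
    # Edge enhancement paints dark fringe rings a couple of detector pixels
    # wide around every interface; air structures closer than two ring
    # widths plus a gap would have their rings merge with the rib/body ring
    # system and leak out of the lung segmentation.
    fringe_clearance_um: float = 80.0
    # minimum tissue clearance between any two air lumina (branch/alveolus
    # and alveolus/alveolus): two fringe-ring widths plus one voxel so the
    # rings of neighbouring cavities never merge into one component
    lumen_clearance_um: float = 65.0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_um) or self.pitch_um <= 0:
            raise ValueError("extent and pitch must be positive")
        lo, hi = self.alveoli.d_range_um
        if lo > hi:
            raise ValueError("alveolar diameter range must satisfy d_lo <= d_hi")
        min_radius = min(
            self.tree.root_radius_um
            * self.tree.radius_ratio ** max(self.tree.depth - 1, 0),
            lo / 2.0,
            self.ribs.tube_radius_um if self.ribs.count else np.inf,
        )
        if min_radius <= 2.0 * self.pitch_um:
            raise ValueError(
                f"smallest structure radius {min_radius:.1f} µm must exceed "
                f"2x voxel pitch ({2 * self.pitch_um:.1f} µm) to be resolvable"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(e / self.pitch_um)) for e in self.extent_um)


@dataclass(frozen=True)
class Branch:
    start_um: np.ndarray       # (z,y,x)
    end_um: np.ndarray
    radius_um: float
    generation: int            # 0 = trachea

    @property
    def direction(self) -> np.ndarray:
        v = self.end_um - self.start_um
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class AlveolusTruth:
    id: int
    center_um: np.ndarray      # (z,y,x)
    diameter_um: float


@dataclass
class PhantomVolume:
    """Labeled voxel phantom plus per-alveolus ground truth."""

    structure: np.ndarray      # uint16 structure codes
    pitch_um: float
    alveoli: List[AlveolusTruth]
    branches: List[Branch]
    spec: LungPhantomSpec

    def material_labels(self) -> np.ndarray:
        """Material id grid: 0 = air, 1 = soft tissue, 2 = bone."""
        mat = np.zeros_like(self.structure, dtype=np.uint8)
        mat[self.structure == SOFT_TISSUE] = 1
        mat[self.structure == BONE] = 2
        return mat

    @property
    def air_mask(self) -> np.ndarray:
        return self.material_labels() == 0

    @property
    def lung_air_mask(self) -> np.ndarray:
        """Air inside the body: airway tree plus alveoli."""
        return (self.structure == TREE_AIR) | (self.structure >= ALVEOLUS_BASE)

    @property
    def tree_mask(self) -> np.ndarray:
        return self.structure == TREE_AIR

    @property
    def rib_mask(self) -> np.ndarray:
        return self.structure == BONE

    def alveolus_mask(self, alveolus_id: int) -> np.ndarray:
        return self.structure == ALVEOLUS_BASE + alveolus_id - 1


@dataclass
class RefractiveVolume:
    """delta/beta voxel grids the beam traverses."""

    delta: np.ndarray          # float32
    beta: np.ndarray
    pitch_um: float
    energy_keV: float

    def __post_init__(self) -> None:
        if self.delta.shape != self.beta.shape:
            raise ValueError("delta and beta grids must share a shape")


# ---------------------------------------------------------------------------
# airway tree


def _orthonormal_frame(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``direction``."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_airway_tree(
    spec: LungPhantomSpec, seed: Optional[int] = None
) -> List[Branch]:
    """Grow the binary airway tree described by ``spec.tree``.

    Returns a list of ``2**depth - 1`` branches in breadth-first order.
    Child radii shrink by the configured ratio; branch azimuths are random
    (seeded) while polar angles are drawn from the configured range, the two
    children of a node pointing to roughly opposite azimuths.

    Raises
    ------
    ValueError
        If any branch (including its radius) leaves the volume, naming the
        offending generation.
    """
    p = spec.tree
    if p.depth < 1:
        raise ValueError("tree depth must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    extent = np.asarray(spec.extent_um)

    def check_inside(point: np.ndarray, radius: float, generation: int) -> None:
        if np.any(point - radius < 0) or np.any(point + radius > extent):
            raise ValueError(
                f"airway branch of generation {generation} leaves the volume "
                f"at {np.round(point, 1).tolist()} µm (radius {radius:.1f} µm)"
            )

    root_start = np.asarray(p.root_start_um, dtype=float)
    root_dir = np.array([1.0, 0.0, 0.0])  # descending +z
    root_end = root_start + root_dir * p.root_length_um
    check_inside(root_start, p.root_radius_um, 0)
    check_inside(root_end, p.root_radius_um, 0)
    branches = [Branch(root_start, root_end, p.root_radius_um, 0)]

    frontier = [branches[0]]
    for gen in range(1, p.depth):
        length = p.root_length_um * p.length_ratio ** gen
        radius = p.root_radius_um * p.radius_ratio ** gen
        next_frontier = []
        # hard limit: the branch must stay inside the box and the body
        # cylinder; soft budget: prefer endpoints that leave room for the
        # remaining subtree and the attached alveoli
        remaining = sum(
            p.root_length_um * p.length_ratio**g for g in range(gen + 1, p.depth)
        )
        hard_margin = radius + 6.0
        radial_hard = radius + spec.fringe_clearance_um
        soft_margin = hard_margin + 0.55 * remaining + (
            40.0 if gen == p.depth - 1 else 0.0
        )
        yc_xc = np.array([spec.extent_um[1] / 2.0, spec.extent_um[2] / 2.0])
        for parent in frontier:
            u, v = _orthonormal_frame(parent.direction)
            phi0 = rng.uniform(0.0, 2.0 * np.pi)
            for k in range(2):
                # steer: resample until the endpoint stays inside the volume
                # and the body cylinder (bounded retries, still seeded)
                end = None
                best_fallback = None
                best_radial = np.inf
                for attempt in range(40):
                    alpha = np.deg2rad(rng.uniform(*p.branch_angle_deg))
                    phi = phi0 + k * np.pi + rng.uniform(-0.35, 0.35)
                    if attempt >= 8:
                        phi = rng.uniform(0.0, 2.0 * np.pi)
                    d = (
                        np.cos(alpha) * parent.direction
                        + np.sin(alpha) * (np.cos(phi) * u + np.sin(phi) * v)
                    )
                    d /= np.linalg.norm(d)
                    cand = parent.end_um + d * length
                    radial = float(np.linalg.norm(cand[1:] - yc_xc))
                    samples = parent.end_um + np.outer(
                        np.linspace(0.25, 1.0, 4), d * length
                    )
                    hard_ok = (
                        np.all(cand - hard_margin >= 0)
                        and np.all(cand + hard_margin <= extent)
                        and radial <= spec.body_radius_um - radial_hard
                        and _clear_of_ribs(samples, radius, spec)
                    )
                    if not hard_ok:
                        continue
                    soft_ok = (
                        np.all(cand - soft_margin >= 0)
                        and np.all(cand + soft_margin <= extent)
                        and radial <= spec.body_radius_um - soft_margin
                    )
                    if soft_ok:
                        end = cand
                        break
                    if radial < best_radial:
                        best_radial, best_fallback = radial, cand
                if end is None:
                    end = best_fallback
                if end is None:
                    raise ValueError(
                        f"airway branch of generation {gen} cannot be kept "
                        f"inside the volume (last candidate "
                        f"{np.round(cand, 1).tolist()} µm, radius {radius:.1f} µm)"
                    )
                child = Branch(parent.end_um.copy(), end, radius, gen)
                branches.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return branches


def _rib_arc_distance(points: np.ndarray, arc, spec: LungPhantomSpec
                      ) -> np.ndarray:
    """Distance from points (n, 3) to a rib arc centerline (exact arc,
    not the full torus)."""
    zc, arc_r, _, phi0, span = arc
    yc_xc = np.array([spec.extent_um[1] / 2.0, spec.extent_um[2] / 2.0])
    dy = points[:, 1] - yc_xc[0]
    dx = points[:, 2] - yc_xc[1]
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    dphi = np.angle(np.exp(1j * (phi - phi0)))
    on_arc = np.abs(dphi) <= span / 2.0
    d = np.full(len(points), np.inf)
    d[on_arc] = np.hypot(rho[on_arc] - arc_r, points[on_arc, 0] - zc)
    if np.any(~on_arc):
        for sign in (-1.0, 1.0):
            ang = phi0 + sign * span / 2.0
            end = np.array([zc, yc_xc[0] + arc_r * np.sin(ang),
                            yc_xc[1] + arc_r * np.cos(ang)])
            d_end = np.linalg.norm(points[~on_arc] - end, axis=1)
            d[~on_arc] = np.minimum(d[~on_arc], d_end)
    return d


def _clear_of_ribs(points: np.ndarray, radius: float,
                   spec: LungPhantomSpec) -> bool:
    """True if every point keeps the fringe clearance from all rib arcs."""
    for arc in _rib_arcs(spec):
        d = _rib_arc_distance(points, arc, spec)
        if np.any(d < radius + arc[2] + spec.fringe_clearance_um):
            return False
    return True


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distance from points (..., 3) to segment a-b."""
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = np.clip(np.tensordot(points - a, ab, axes=([-1], [0])) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


# ---------------------------------------------------------------------------
# alveoli


def populate_alveoli(
    tree: Sequence[Branch],
    spec: LungPhantomSpec,
    seed: Optional[int] = None,
) -> List[AlveolusTruth]:
    """Attach non-overlapping spherical alveoli near terminal branch tips.

    Diameters are uniform on the configured range.  A candidate center is
    the terminal tip displaced along a jittered continuation of the branch
    direction by (branch radius + gap + sphere radius); it is accepted only
    if the sphere stays inside the volume and the body cylinder, keeps the
    configured clearance from every branch and every rib arc, and keeps
    clearance from previously placed spheres (rejection sampling).

    Raises
    ------
    RuntimeError
        If the requested count cannot be placed within the retry budget;
        the message reports how many were placed.
    """
    ap = spec.alveoli
    if ap.count < 1:
        raise ValueError("alveolus count must be >= 1")
    terminals = [b for b in tree if b.generation == max(b2.generation for b2 in tree)]
    if not terminals:
        raise ValueError("tree has no terminal segments")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    extent = np.asarray(spec.extent_um)
    center_yx = np.array([spec.extent_um[1] / 2.0, spec.extent_um[2] / 2.0])
    cone = np.deg2rad(ap.jitter_deg)

    ribs = _rib_arcs(spec)
    # a failed draw sequence is retried from scratch (seeded, bounded)
    best = 0
    for _restart in range(6):
        placed = _try_place(spec, terminals, tree, ribs, rng, center_yx, cone, extent)
        if len(placed) == ap.count:
            return placed
        best = max(best, len(placed))
    raise RuntimeError(
        f"could not place {ap.count} non-overlapping alveoli within the retry "
        f"budget; best attempt placed {best}"
    )


def _try_place(spec, terminals, tree, ribs, rng, center_yx, cone, extent):
    ap = spec.alveoli
    placed: List[AlveolusTruth] = []
    for k in range(ap.count):
        diameter = rng.uniform(*ap.d_range_um)
        r = diameter / 2.0
        ok = False
        for _ in range(ap.max_tries_per_alveolus):
            t = terminals[rng.integers(len(terminals))]
            u, v = _orthonormal_frame(t.direction)
            alpha = cone * np.sqrt(rng.uniform())          # area-uniform in cone
            phi = rng.uniform(0.0, 2.0 * np.pi)
            d = (
                np.cos(alpha) * t.direction
                + np.sin(alpha) * (np.cos(phi) * u + np.sin(phi) * v)
            )
            offset = t.radius_um + spec.lumen_clearance_um + r \
                + rng.uniform(0.0, 160.0)
            c = t.end_um + d * offset
            if np.any(c - r < 0) or np.any(c + r > extent):
                continue
            if (np.linalg.norm(c[1:] - center_yx) + r
                    > spec.body_radius_um - spec.fringe_clearance_um):
                continue
            clear = True
            for b in tree:
                dist = _point_segment_distance(c[None, :], b.start_um, b.end_um)[0]
                if dist < b.radius_um + r + spec.lumen_clearance_um:
                    clear = False
                    break
            if clear:
                for arc in ribs:
                    d_arc = _rib_arc_distance(c[None, :], arc, spec)[0]
                    if d_arc < arc[2] + r + spec.fringe_clearance_um:
                        clear = False
                        break
            if clear:
                for prev in placed:
                    if (
                        np.linalg.norm(c - prev.center_um)
                        < r + prev.diameter_um / 2.0 + spec.lumen_clearance_um
                    ):
                        clear = False
                        break
            if clear:
                placed.append(AlveolusTruth(id=k + 1, center_um=c, diameter_um=diameter))
                ok = True
                break
        if not ok:
            break
    return placed


# ---------------------------------------------------------------------------
# rasterization


def _rib_arcs(spec: LungPhantomSpec):
    """Rib arc descriptors: (z_center, arc_radius, tube_radius, phi0, span)."""
    rp = spec.ribs
    arcs = []
    if rp.count == 0:
        return arcs
    z_lo, z_hi = 0.18 * spec.extent_um[0], 0.82 * spec.extent_um[0]
    zs = np.linspace(z_lo, z_hi, rp.count)
    span = np.deg2rad(rp.arc_span_deg)
    for i, zc in enumerate(zs):
        phi0 = np.deg2rad(25.0 * i)  # stagger arcs azimuthally
        arcs.append((float(zc), rp.arc_radius_um, rp.tube_radius_um, phi0, span))
    return arcs


def _crop_slices(center, reach, shape, pitch):
    sl = []
    for c, n in zip(center, shape):
        lo = max(int(np.floor((c - reach) / pitch)) - 1, 0)
        hi = min(int(np.ceil((c + reach) / pitch)) + 2, n)
        sl.append(slice(lo, hi))
    return tuple(sl)


def _voxel_centers(slices, pitch):
    grids = [
        (np.arange(s.start, s.stop, dtype=np.float32) + 0.5) * pitch for s in slices
    ]
    return np.meshgrid(*grids, indexing="ij")


def rasterize(
    spec: LungPhantomSpec,
    table: Optional[MaterialTable] = None,
    energy_keV: float = 18.0,
    tree: Optional[Sequence[Branch]] = None,
    alveoli: Optional[Sequence[AlveolusTruth]] = None,
) -> Tuple[PhantomVolume, RefractiveVolume]:
    """Voxelize the phantom and populate delta/beta grids from the table.

    Each voxel takes the material of the structure covering its center
    (later structures overwrite earlier ones: body, ribs, tree, alveoli).
    The airway lumina and alveolar interiors are air.  Ground truth (per
    alveolus id, center and diameter) rides along on the PhantomVolume.
    """
    if table is None:
        table = build_material_table(energy_keV)
    shape = spec.shape
    if any(n == 0 for n in shape):
        raise ValueError("zero-extent volume")
    pitch = spec.pitch_um
    lo_d = spec.alveoli.d_range_um[0]
    smallest = min(
        lo_d / 2.0,
        spec.tree.root_radius_um * spec.tree.radius_ratio ** (spec.tree.depth - 1),
    )
    if pitch > smallest:
        warnings.warn(
            f"voxel pitch {pitch} µm exceeds smallest structure radius "
            f"{smallest:.1f} µm; structures will be unresolved"
        )

    if tree is None and alveoli is None:
        tree, alveoli = build_geometry(spec)
    elif tree is None:
        tree = generate_airway_tree(spec)
    elif alveoli is None:
        alveoli = populate_alveoli(tree, spec)

    structure = np.zeros(shape, dtype=np.uint16)

    # body cylinder (axis = z through volume center, full height)
    yc, xc = spec.extent_um[1] / 2.0, spec.extent_um[2] / 2.0
    y = (np.arange(shape[1], dtype=np.float32) + 0.5) * pitch
    x = (np.arange(shape[2], dtype=np.float32) + 0.5) * pitch
    rho2 = (y[:, None] - yc) ** 2 + (x[None, :] - xc) ** 2
    body2d = rho2 <= spec.body_radius_um**2
    structure[:, body2d] = SOFT_TISSUE

    # rib arcs (bone)
    for (zc, arc_r, tube_r, phi0, span) in _rib_arcs(spec):
        reach = tube_r + 1.0
        zsl = _crop_slices((zc,), reach, (shape[0],), pitch)[0]
        z = (np.arange(zsl.start, zsl.stop, dtype=np.float32) + 0.5) * pitch
        rho = np.sqrt(rho2)
        d_arc2d = (rho - arc_r) ** 2
        phi = np.arctan2(y[:, None] - yc, x[None, :] - xc)
        dphi = np.angle(np.exp(1j * (phi - phi0)))
        in_arc = np.abs(dphi) <= span / 2.0
        for iz, zv in zip(range(zsl.start, zsl.stop), z):
            mask = (d_arc2d + (zv - zc) ** 2 <= tube_r**2) & in_arc & body2d
            structure[iz][mask] = BONE

    # airway tree lumina (air)
    for b in tree:
        reach = b.radius_um + np.linalg.norm(b.end_um - b.start_um)
        mid = (b.start_um + b.end_um) / 2.0
        sl = _crop_slices(mid, reach / 2.0 + b.radius_um + 1, shape, pitch)
        zz, yy, xx = _voxel_centers(sl, pitch)
        pts = np.stack([zz, yy, xx], axis=-1)
        dist = _point_segment_distance(pts, b.start_um, b.end_um)
        structure[sl][dist <= b.radius_um] = TREE_AIR

    # alveoli (air, individually coded)
    for a in alveoli:
        r = a.diameter_um / 2.0
        if np.any(a.center_um - r < 0) or np.any(
            a.center_um + r > np.asarray(spec.extent_um)
        ):
            raise ValueError(f"alveolus {a.id} ground-truth sphere leaves the volume")
        sl = _crop_slices(a.center_um, r + 1, shape, pitch)
        zz, yy, xx = _voxel_centers(sl, pitch)
        d2 = (
            (zz - a.center_um[0]) ** 2
            + (yy - a.center_um[1]) ** 2
            + (xx - a.center_um[2]) ** 2
        )
        structure[sl][d2 <= r**2] = ALVEOLUS_BASE + a.id - 1

    phantom = PhantomVolume(
        structure=structure,
        pitch_um=pitch,
        alveoli=list(alveoli),
        branches=list(tree),
        spec=spec,
    )

    mat = phantom.material_labels()
    delta = np.empty(shape, dtype=np.float32)
    beta = np.empty(shape, dtype=np.float32)
    for code, name in ((0, "air"), (1, "soft_tissue"), (2, "bone")):
        m = mat == code
        delta[m] = table.delta(name)
        beta[m] = table.beta(name)
    refr = RefractiveVolume(
        delta=delta, beta=beta, pitch_um=pitch, energy_keV=table.energy_keV
    )
    return phantom, refr


def build_geometry(
    spec: LungPhantomSpec,
) -> Tuple[List[Branch], List[AlveolusTruth]]:
    """Grow a tree and seat the alveoli, regrowing the tree on crowding.

    An unlucky tree draw can leave too little room to seat all alveoli;
    in that case the whole geometry is re-drawn from a deterministically
    derived seed (bounded attempts), so every spec seed yields a complete
    phantom or a hard failure.
    """
    last_error: Exception | None = None
    for attempt in range(24):
        tree_seed = spec.seed + 7919 * attempt
        try:
            tree = generate_airway_tree(spec, seed=tree_seed)
            alveoli = populate_alveoli(tree, spec, seed=tree_seed + 1)
            return tree, alveoli
        except (ValueError, RuntimeError) as exc:
            last_error = exc
    raise RuntimeError(
        f"phantom geometry failed for seed {spec.seed} after 24 re-draws"
    ) from last_error


def default_phantom_spec(seed: int = 0, **overrides) -> LungPhantomSpec:
    """The package's default study phantom: 256³ voxels at 4 µm pitch,
    a depth-4 airway tree and 21 alveoli with diameters uniform on the
    immature-mouse 100–150 µm range."""
    return LungPhantomSpec(seed=seed, **overrides)
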