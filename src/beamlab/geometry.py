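"""Scene construction and ray queries for the collimator/filter/phantom setups.

Coordinate convention: z is the beam axis, z = 0 at the phantom entry face,
the beam travels toward +z, the source plane sits at negative z.  Geometry is
a prioritized union of axis-aligned boxes, z-cylinders and z-annuli, with an
optional voxel lattice (used by the patient-phantom stage) that overrides the
analytic regions inside its bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_NUDGE = 1e-6  # cm, surface-coincidence push
ESCAPE = "<escape>"

BOX, CYLINDER, ANNULUS = 0, 1, 2
_SHAPE_CODES = {"box": BOX, "cylinder": CYLINDER, "annulus": ANNULUS}


@dataclass
class Region:
    """One primitive region.

    params by shape (all cm):
      box:      (x0, x1, y0, y1, z0, z1)
      cylinder: (radius, z0, z1)            centered on the z axis
      annulus:  (r_in, r_out, z0, z1)       centered on the z axis
    Higher priority wins where regions overlap.
    """

    shape: str
    params: tuple
    material: str
    priority: int

    def __post_init__(self) -> None:
        if self.shape not in _SHAPE_CODES:
            raise ValueError(f"unknown shape {self.shape}")
        p = self.params
        if self.shape == "box":
            if not (p[0] < p[1] and p[2] < p[3] and p[4] < p[5]):
                raise ValueError("box extents must be positive")
        elif self.shape == "cylinder":
            if not (p[0] > 0 and p[1] < p[2]):
                raise ValueError("cylinder extents must be positive")
        else:
            if not (0 <= p[0] < p[1] and p[2] < p[3]):
                raise ValueError("annulus radii/extents invalid")

    def contains(self, point) -> bool:
        x, y, z = point
        p = self.params
        if self.shape == "box":
            return p[0] <= x <= p[1] and p[2] <= y <= p[3] and p[4] <= z <= p[5]
        r2 = x * x + y * y
        if self.shape == "cylinder":
            return r2 <= p[0] ** 2 and p[1] <= z <= p[2]
        return p[0] ** 2 <= r2 <= p[1] ** 2 and p[2] <= z <= p[3]


@dataclass
class FilterDesign:
    """Filter configurations: A = full disc, B = central square, C = both."""

    design: str  # "A" | "B" | "C" | "none"
    disc_diameter: float = 12.0   # cm
    disc_thickness: float = 5.0   # mm
    square_side: float = 8.0      # cm (4 or 8 in the studied designs)
    square_thickness: float = 5.0  # mm

    def __post_init__(self) -> None:
        d = self.design.upper()
        if d not in ("A", "B", "C", "NONE"):
            raise ValueError(f"unknown design {self.design}")
        self.design = "none" if d == "NONE" else d
        if self.has_disc and (self.disc_diameter <= 0 or self.disc_thickness <= 0):
            raise ValueError("disc extents must be positive")
        if self.has_square and (self.square_side <= 0 or self.square_thickness <= 0):
            raise ValueError("square extents must be positive")

    @property
    def has_disc(self) -> bool:
        return self.design in ("A", "C")

    @property
    def has_square(self) -> bool:
        return self.design in ("B", "C")


@dataclass
class Scene:
    regions: list[Region]
    bbox: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    lattice: "object | None" = None  # VoxelLattice, set by patient stage
    phantom_region: Region | None = None
    description: dict = field(default_factory=dict)

    def locate(self, point) -> str:
        return locate(self, point)

    def distance_to_boundary(self, position, direction) -> float:
        return distance_to_boundary(self, position, direction)

    def material_names(self) -> list[str]:
        names = {r.material for r in self.regions}
        if self.lattice is not None:
            names.update(self.lattice.materials)
        return sorted(names)


@dataclass
class VoxelLattice:
    """Voxelized material override (label grid + per-voxel density scale)."""

    origin: np.ndarray           # (3,) cm, lower corner
    spacing: np.ndarray          # (3,) cm
    material_index: np.ndarray   # (nx,ny,nz) int16 indices into `materials`
    materials: list[str]
    density_scale: np.ndarray | None = None  # (nx,ny,nz), rho_vox / rho_material

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.material_index = np.ascontiguousarray(self.material_index, dtype=np.int16)
        if self.density_scale is None:
            self.density_scale = np.ones(self.material_index.shape, dtype=np.float64)
        self.density_scale = np.ascontiguousarray(self.density_scale, dtype=np.float64)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.spacing * np.array(self.material_index.shape)

    def contains(self, point) -> bool:
        p = np.asarray(point, float)
        return bool(np.all(p >= self.origin) and np.all(p <= self.upper))

    def lookup(self, point) -> str:
        idx = np.minimum(
            ((np.asarray(point, float) - self.origin) / self.spacing).astype(int),
            np.array(self.material_index.shape) - 1,
        )
        return self.materials[int(self.material_index[tuple(idx)])]


def build_scene(
    filter_design: FilterDesign | None = None,
    phantom_material: str = "water",
    collimator_diameter: float = 12.0,
    collimator_length: float = 10.0,
    collimator_outer_radius: float = 20.0,
    phantom_size: float = 20.0,
    air_gap: float = 0.0,
    filter_material: str = "lif_enriched",
    collimator_material: str = "lif_polyethylene",
) -> Scene:
    """Standard scene: collimator bore + filter stack + phantom cube.

    The phantom entry face is at z = 0 (offset by ``air_gap`` if nonzero);
    filters sit inside the bore, flush against the bore exit plane.
    """
    fd = filter_design or FilterDesign("none")
    bore_r = collimator_diameter / 2.0
    if fd.has_square and fd.square_side / 2.0 > bore_r:
        raise ValueError("square plate larger than the collimator bore")

    hp = phantom_size / 2.0
    z_phantom = air_gap
    regions: list[Region] = []

    # surrounding air over the whole bounding box (lowest priority)
    half_xy = max(collimator_outer_radius, hp) + 2.0
    z_lo = -(collimator_length + 2.0)
    z_hi = z_phantom + phantom_size + 2.0
    regions.append(Region("box", (-half_xy, half_xy, -half_xy, half_xy, z_lo, z_hi), "air", 0))

    regions.append(
        Region("annulus", (bore_r, collimator_outer_radius, -collimator_length, 0.0),
               collimator_material, 3)
    )
    regions.append(Region("cylinder", (bore_r, -collimator_length, 0.0), "air", 4))

    # filter stack flush with the bore exit: disc downstream, square upstream
    z_cursor = 0.0
    if fd.has_disc:
        t = fd.disc_thickness / 10.0  # mm -> cm
        regions.append(
            Region("cylinder", (fd.disc_diameter / 2.0, z_cursor - t, z_cursor),
                   filter_material, 10)
        )
        z_cursor -= t
    if fd.has_square:
        t = fd.square_thickness / 10.0
        h = fd.square_side / 2.0
        regions.append(
            Region("box", (-h, h, -h, h, z_cursor - t, z_cursor), filter_material, 10)
        )

    phantom = Region(
        "box", (-hp, hp, -hp, hp, z_phantom, z_phantom + phantom_size),
        phantom_material, 5,
    )
    regions.append(phantom)

    bbox = ((-half_xy, half_xy), (-half_xy, half_xy), (z_lo, z_hi))
    return Scene(
        regions=regions,
        bbox=bbox,
        phantom_region=phantom,
        description={
            "design": fd.design,
            "phantom_material": phantom_material,
            "collimator_diameter": collimator_diameter,
            "filter": fd,
        },
    )


def locate(scene: Scene, point) -> str:
    """Material at a point: highest-priority containing region (lattice wins)."""
    p = np.asarray(point, float)
    for axis in range(3):
        lo, hi = scene.bbox[axis]
        if p[axis] < lo or p[axis] > hi:
            return ESCAPE
    if scene.lattice is not None and scene.lattice.contains(p):
        return scene.lattice.lookup(p)
    best = None
    best_prio = -1
    for reg in scene.regions:
        if reg.priority > best_prio and reg.contains(p):
            best, best_prio = reg.material, reg.priority
    return best if best is not None else ESCAPE


def _ray_surface_distances(region: Region, pos, direction) -> list[float]:
    """All positive parametric distances to the region's bounding surfaces."""
    x, y, z = pos
    dx, dy, dz = direction
    out = []
    p = region.params

    def planes(coord, d, lo, hi):
        if d != 0.0:
            for plane in (lo, hi):
                t = (plane - coord) / d
                if t > 0:
                    out.append(t)

    if region.shape == "box":
        planes(x, dx, p[0], p[1])
        planes(y, dy, p[2], p[3])
        planes(z, dz, p[4], p[5])
        return out

    if region.shape == "cylinder":
        radii = (p[0],)
        z0, z1 = p[1], p[2]
    else:
        radii = (p[0], p[1]) if p[0] > 0 else (p[1],)
        z0, z1 = p[2], p[3]
    planes(z, dz, z0, z1)
    a = dx * dx + dy * dy
    if a > 0:
        b = x * dx + y * dy
        c0 = x * x + y * y
        for R in radii:
            disc = b * b - a * (c0 - R * R)
            if disc >= 0:
                sq = np.sqrt(disc)
                for t in ((-b - sq) / a, (-b + sq) / a):
                    if t > 0:
                        out.append(t)
    return out


def distance_to_boundary(scene: Scene, position, direction) -> float:
    """Distance to the nearest potential material-change surface (> 0).

    Conservative: any surface crossing of any region counts, so the segment
    up to the returned distance is guaranteed single-material.
    """
    pos = np.asarray(position, float)
    d = np.asarray(direction, float)
    best = np.inf
    if scene.lattice is not None and scene.lattice.contains(pos):
        lat = scene.lattice
        for axis in range(3):
            if d[axis] != 0.0:
                idx = int((pos[axis] - lat.origin[axis]) / lat.spacing[axis])
                step = 1 if d[axis] > 0 else 0
                plane = lat.origin[axis] + (idx + step) * lat.spacing[axis]
                t = (plane - pos[axis]) / d[axis]
                if t <= 0:  # sitting on a face
                    t = (plane + (1 if d[axis] > 0 else -1) * lat.spacing[axis] - pos[axis]) / d[axis]
                best = min(best, t)
    for reg in scene.regions:
        for t in _ray_surface_distances(reg, pos, d):
            if EPS_NUDGE / 10.0 < t < best:
                best = t
    if scene.lattice is not None and not scene.lattice.contains(pos):
        # entry into the lattice box
        lat = scene.lattice
        for axis in range(3):
            if d[axis] != 0.0:
                for plane in (lat.origin[axis], lat.upper[axis]):
                    t = (plane - pos[axis]) / d[axis]
                    if EPS_NUDGE / 10.0 < t < best:
                        best = t
    if not np.isfinite(best):
        # leave the bounding box
        for axis in range(3):
            if d[axis] != 0.0:
                for plane in scene.bbox[axis]:
                    t = (plane - pos[axis]) / d[axis]
                    if t > 0:
                        best = min(best, t)
    return max(best, EPS_NUDGE)


def chord_segments(scene: Scene, position, direction, max_length: float = 1e9):
    """Yield (material, length) segments along a ray until escape."""
    pos = np.asarray(position, float).copy()
    d = np.asarray(direction, float)
    travelled = 0.0
    while travelled < max_length:
        mat = locate(scene, pos)
        if mat == ESCAPE:
            return
        step = distance_to_boundary(scene, pos, d)
        step = min(step, max_length - travelled)
        yield mat, step
        pos = pos + (step + EPS_NUDGE) * d
        travelled += step + EPS_NUDGE


def compile_scene(scene: Scene, material_order: list[str]) -> dict:
    """Flatten the scene into arrays for the numba transport kernels."""
    mat_idx = {m: i for i, m in enumerate(material_order)}
    n = len(scene.regions)
    rtype = np.zeros(n, dtype=np.int8)
    params = np.zeros((n, 6), dtype=np.float64)
    rmat = np.zeros(n, dtype=np.int16)
    prio = np.zeros(n, dtype=np.int16)
    for i, reg in enumerate(scene.regions):
        rtype[i] = _SHAPE_CODES[reg.shape]
        p = reg.params
        params[i, : len(p)] = p
        rmat[i] = mat_idx[reg.material]
        prio[i] = reg.priority
    bbox = np.array(scene.bbox, dtype=np.float64)
    out = {"rtype": rtype, "params": params, "rmat": rmat, "prio": prio, "bbox": bbox}
    if scene.lattice is not None:
        lat = scene.lattice
        out["lat_origin"] = lat.origin
        out["lat_spacing"] = lat.spacing
        out["lat_mat"] = np.ascontiguousarray(
            np.vectorize(lambda i: mat_idx[lat.materials[i]])(lat.material_index).astype(np.int16)
        )
        out["lat_density"] = lat.density_scale
        out["has_lattice"] = True
    else:
        out["lat_origin"] = np.zeros(3)
        out["lat_spacing"] = np.ones(3)
        out["lat_mat"] = np.zeros((1, 1, 1), dtype=np.int16)
        out["lat_density"] = np.ones((1, 1, 1), dtype=np.float64)
        out["has_lattice"] = False
    return out
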