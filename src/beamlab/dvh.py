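"""Voxel-phantom dose evaluation: HU conversion, synthetic head phantom,
dose-volume histograms, percentile doses and the homogeneity index."""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import VoxelLattice


def _load_hu_table() -> dict:
    ref = importlib.resources.files("beamlab.data").joinpath("hu_material_table.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_HU_TABLE = _load_hu_table()


def hu_density_curve() -> tuple[np.ndarray, np.ndarray]:
    nodes = np.asarray(_HU_TABLE["density_curve"], dtype=float)
    return nodes[:, 0], nodes[:, 1]


def ct_to_material(hu_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Piecewise-linear HU -> (density g/cm3, material-bin index, bin labels).

    Out-of-window HU values are clamped; a warning reports how many.
    """
    hu = np.asarray(hu_grid, dtype=float)
    lo, hi = _HU_TABLE["hu_window"]
    n_clamped = int(np.sum((hu < lo) | (hu > hi)))
    if n_clamped:
        warnings.warn(f"{n_clamped} HU values outside [{lo}, {hi}] clamped")
    hu = np.clip(hu, lo, hi)
    xs, ys = hu_density_curve()
    density = np.interp(hu, xs, ys)
    bins = _HU_TABLE["material_bins"]
    labels = [label for _, label in bins]
    edges = np.array([edge for edge, _ in bins], dtype=float)
    idx = np.searchsorted(edges, hu, side="right")
    idx = np.minimum(idx, len(labels) - 1)
    return density, idx.astype(np.int16), labels


@dataclass
class VoxelPhantom:
    """Label/density volume with structure masks on a uniform grid."""

    voxel_cm: float
    origin: np.ndarray                 # (3,) cm
    labels: np.ndarray                 # (nx,ny,nz) int16, index into materials
    materials: list[str]
    density: np.ndarray                # g/cm3 per voxel
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        for name, m in self.masks.items():
            if m.shape != self.labels.shape:
                raise ValueError(f"mask {name} shape mismatch")
        tums = [m for n, m in self.masks.items() if n.startswith("tumor")]
        for i in range(len(tums)):
            for j in range(i + 1, len(tums)):
                if np.any(tums[i] & tums[j]):
                    raise ValueError("tumor masks must be disjoint")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def to_lattice(self, library) -> VoxelLattice:
        """Lattice for the transport engine, with per-voxel density scaling."""
        ref_rho = np.array([max(library[m].density, 1e-30) for m in self.materials])
        scale = self.density / ref_rho[self.labels]
        return VoxelLattice(
            origin=self.origin,
            spacing=np.full(3, self.voxel_cm),
            material_index=self.labels,
            materials=list(self.materials),
            density_scale=scale,
        )


def make_head_phantom(voxel_cm: float = 0.2) -> VoxelPhantom:
    """Synthetic layered head on a 2-mm grid, beam entering from the vertex.

    Nested ellipsoids: skin shell (0.4 cm), skull shell (0.6 cm), brain
    interior.  Four 2-cm-diameter spherical mock tumors at depths 4, 6, 8 cm
    on the beam axis and 8 cm deep / 4 cm off-axis.  z measures depth below
    the vertex (z = 0 at the scalp surface on the axis).
    """
    rx, ry, rz = 8.5, 8.5, 11.0
    center = np.array([0.0, 0.0, rz])
    # odd voxel count so the beam axis runs through voxel centres (halves the
    # sphere-voxelization bias of the tumor masks)
    half_xy = 10.0 + voxel_cm / 2.0
    depth = 2.0 * rz
    n_xy = int(round(2 * half_xy / voxel_cm))
    n_z = int(round(depth / voxel_cm))
    origin = np.array([-half_xy, -half_xy, 0.0])

    xs = origin[0] + (np.arange(n_xy) + 0.5) * voxel_cm
    ys = origin[1] + (np.arange(n_xy) + 0.5) * voxel_cm
    zs = origin[2] + (np.arange(n_z) + 0.5) * voxel_cm
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def ellipsoid(shrink: float) -> np.ndarray:
        return ((X / (rx - shrink)) ** 2 + (Y / (ry - shrink)) ** 2
                + ((Z - center[2]) / (rz - shrink)) ** 2) <= 1.0

    body = ellipsoid(0.0)
    inner_skin = ellipsoid(0.4)
    inner_skull = ellipsoid(1.0)

    materials = ["air", "skin", "bone", "brain"]
    labels = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    labels[body & ~inner_skin] = 1
    labels[inner_skin & ~inner_skull] = 2
    labels[inner_skull] = 3

    dens_by_label = {"air": 0.0012, "skin": 1.09, "bone": 1.92, "brain": 1.04}
    density = np.array([dens_by_label[m] for m in materials])[labels]

    masks: dict[str, np.ndarray] = {}
    centers = [(0.0, 0.0, 4.0), (0.0, 0.0, 6.0), (0.0, 0.0, 8.0), (4.0, 0.0, 8.0)]
    for i, (cx, cy, cz) in enumerate(centers, start=1):
        # strict inequality: adjacent spheres are exactly tangent and must
        # not share the voxel at the tangent point
        masks[f"tumor{i}"] = ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) < 1.0
    brain_mask = labels == 3
    masks["brain"] = brain_mask.copy()
    masks["body"] = body

    return VoxelPhantom(
        voxel_cm=voxel_cm,
        origin=origin,
        labels=labels,
        materials=materials,
        density=density,
        masks=masks,
    )


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve: fraction of the structure >= dose."""

    dose_edges: np.ndarray      # bin edges, Gy
    volume_fraction: np.ndarray  # at each edge, fraction receiving >= edge

    def __post_init__(self) -> None:
        v = self.volume_fraction
        if abs(v[0] - 1.0) > 1e-12 or v[-1] != 0.0:
            raise ValueError("curve must start at 1 and end at 0")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("curve must be monotone non-increasing")


def compute_dvh(dose_map: np.ndarray, mask: np.ndarray, n_bins: int = 200) -> DVHCurve:
    if not mask.any():
        raise ValueError("empty structure mask")
    doses = np.asarray(dose_map)[mask]
    top = float(doses.max()) * (1.0 + 1e-9) + 1e-12
    edges = np.linspace(0.0, top, n_bins + 1)
    frac = np.array([np.mean(doses >= e) for e in edges])
    frac[0] = 1.0
    frac[-1] = 0.0
    return DVHCurve(edges, frac)


def dose_percentile(dose_values, p: float) -> float:
    """D_p: the largest dose received by at least p% of the volume.

    Accepts a flat array of voxel doses or a (dose_map, mask) pair.
    """
    if isinstance(dose_values, tuple):
        dose_map, mask = dose_values
        vals = np.asarray(dose_map)[mask]
    else:
        vals = np.asarray(dose_values).ravel()
    if not 0 < p < 100:
        raise ValueError("p must be in (0, 100)")
    if vals.size == 0:
        raise ValueError("empty structure")
    s = np.sort(vals)[::-1]
    k = int(np.ceil(p / 100.0 * s.size))
    return float(s[max(k, 1) - 1])


def homogeneity_index(d5: float, d95: float) -> float:
    """HI = D5 / D95."""
    if d95 <= 0:
        raise ZeroDivisionError("D95 must be positive")
    return d5 / d95


def mean_dose(dose_map: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty structure mask")
    return float(np.asarray(dose_map)[mask].mean())


def dvh_table(dose_map: np.ndarray, masks: dict[str, np.ndarray],
              percentiles=(5, 98, 50, 95)) -> dict[str, dict[str, float]]:
    """Per-structure D_p values plus HI, mirroring the standard report."""
    out: dict[str, dict[str, float]] = {}
    for name, mask in masks.items():
        row = {f"D{p}": dose_percentile((dose_map, mask), p) for p in percentiles}
        if row.get("D95", 0.0) > 0:
            row["HI"] = homogeneity_index(row["D5"], row["D95"])
        else:
            row["HI"] = float("nan")
        row["mean"] = mean_dose(dose_map, mask)
        out[name] = row
    return out
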