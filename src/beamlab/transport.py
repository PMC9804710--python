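"""Monte Carlo transport driver: batching, tallies, statistics, persistence.

The per-history physics lives in :mod:`beamlab._kernels`; this module
prepares the flattened scene/material arrays, runs history batches, and
assembles :class:`TallyGrid` results with batch-statistics errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels, nuclear
from .geometry import Scene, compile_scene
from .source import SourceModel, THERMAL_CUTOFF_EV, EPITHERMAL_TOP_EV, sample_source_particles

DEFAULT_GROUP_EDGES = np.array([1e-5, THERMAL_CUTOFF_EV, EPITHERMAL_TOP_EV, 30e6])


@dataclass
class MeshSpec:
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    group_edges: np.ndarray = field(default_factory=lambda: DEFAULT_GROUP_EDGES.copy())

    @classmethod
    def phantom_default(cls, bin_cm: float = 0.2, phantom_size: float = 20.0,
                        z0: float = 0.0) -> "MeshSpec":
        n_xy = int(round(phantom_size / bin_cm))
        nz = int(round(phantom_size / bin_cm))
        h = phantom_size / 2.0
        return cls(origin=(-h, -h, z0), spacing=(bin_cm,) * 3, shape=(n_xy, n_xy, nz))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return (self.origin[axis]
                + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis])

    def voxel_of(self, point) -> tuple[int, int, int]:
        idx = tuple(
            int((point[a] - self.origin[a]) / self.spacing[a]) for a in range(3)
        )
        if any(i < 0 or i >= self.shape[a] for a, i in enumerate(idx)):
            raise ValueError(f"point {point} outside tally mesh")
        return idx  # type: ignore[return-value]


@dataclass
class RunSpec:
    n_particles: int = 100_000
    seed: int = 0
    n_batches: int = 20
    target_rel_err: float | None = None      # stop rule at the monitor voxel
    monitor_point: tuple[float, float, float] = (0.0, 0.0, 15.0)
    max_particles: int | None = None         # cap when running to target_rel_err
    photon_transport: bool = True
    implicit_capture: bool = False
    recoil_cut_ev: float = THERMAL_CUTOFF_EV
    freegas_cut_ev: float = 1.0
    temperature_ev: float = 0.0253
    mesh: MeshSpec | None = None

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for statistics")


@dataclass
class TallyGrid:
    """Per-voxel (optionally per-group) track-length estimates, cm^-2/source."""

    mesh: MeshSpec
    value: np.ndarray     # (G, nx, ny, nz) or (nx, ny, nz)
    rel_err: np.ndarray
    n_source: int

    def axial_profile(self, group: int | None = None, radius_cm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(depth, value) averaged over voxels within radius_cm of the axis."""
        v = self.value if group is None else self.value[group]
        if v.ndim == 4:
            v = v.sum(axis=0)
        xs = self.mesh.axis_coords(0)
        ys = self.mesh.axis_coords(1)
        r2 = xs[:, None] ** 2 + ys[None, :] ** 2
        mask = r2 <= radius_cm ** 2
        prof = v[mask, :].mean(axis=0)
        return self.mesh.axis_coords(2), prof

    def lateral_profile(self, depth_cm: float, group: int | None = None,
                        half_width_cm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(x, value) at a depth, averaged over a thin y-slab about the axis."""
        v = self.value if group is None else self.value[group]
        if v.ndim == 4:
            v = v.sum(axis=0)
        iz = int((depth_cm - self.mesh.origin[2]) / self.mesh.spacing[2])
        iz = min(max(iz, 0), self.mesh.shape[2] - 1)
        ys = self.mesh.axis_coords(1)
        ymask = np.abs(ys) <= half_width_cm
        return self.mesh.axis_coords(0), v[:, ymask, iz].mean(axis=1)


@dataclass
class TransportResult:
    neutron: TallyGrid               # grouped fluence
    photon: TallyGrid                # photon fluence (1 group)
    aux: dict[str, TallyGrid]        # one_v_tot, one_v_sub, capture:<ch>, recoil_mev, gamma_edep_mev
    absorbed: int
    escaped: int
    n_source: int
    channels: list[str]
    seed: int

    @property
    def mesh(self) -> MeshSpec:
        return self.neutron.mesh


def _compile_materials(scene: Scene, library: dict[str, nuclear.Material]):
    names = scene.material_names()
    mats = []
    for name in names:
        if name not in library:
            raise KeyError(f"material {name!r} not in library")
        mats.append(library[name])
    channels: list[str] = []
    starts = [0]
    nuc_N, nuc_s0c, nuc_ss, nuc_A, nuc_ch = [], [], [], [], []
    for m in mats:
        for nuc_name, nd in sorted(m.number_densities.items()):
            nuc = nuclear.NUCLIDES[nuc_name]
            ch = nuc.capture_channel
            if ch not in channels:
                channels.append(ch)
            nuc_N.append(nd)
            nuc_s0c.append(nuc.sigma0_capture)
            nuc_ss.append(nuc.sigma_scatter)
            nuc_A.append(nuc.atomic_mass)
            nuc_ch.append(channels.index(ch))
        starts.append(len(nuc_N))
    h_channel = channels.index("H1(n,g)") if "H1(n,g)" in channels else -1
    mu_scale = np.array([nuclear.electron_density_scale(m) for m in mats])
    return {
        "names": names,
        "materials": mats,
        "mat_start": np.array(starts, dtype=np.int64),
        "nuc_N": np.array(nuc_N),
        "nuc_sig0c": np.array(nuc_s0c),
        "nuc_sigs": np.array(nuc_ss),
        "nuc_A": np.array(nuc_A),
        "nuc_channel": np.array(nuc_ch, dtype=np.int16),
        "h_channel": h_channel,
        "channels": channels,
        "mat_mu_scale": mu_scale,
    }


def run_transport(
    source: SourceModel,
    scene: Scene,
    runspec: RunSpec,
    library: dict[str, nuclear.Material] | None = None,
    verbose: bool = False,
) -> TransportResult:
    """Analog (or implicit-capture) transport; returns neutron/photon tallies."""
    library = library if library is not None else nuclear.default_library()
    mesh = runspec.mesh or MeshSpec.phantom_default()
    comp = _compile_materials(scene, library)
    geo = compile_scene(scene, comp["names"])
    edges = np.asarray(mesh.group_edges, dtype=float)
    G = edges.size - 1
    C = len(comp["channels"])
    shape = tuple(mesh.shape)

    pg_e, pg_mu, pg_muen = nuclear.photon_coefficients()
    pg_loge = np.log10(pg_e)

    names = ["flux", "one_v_tot", "one_v_sub", "capture", "recoil", "pflux", "gamma_edep"]
    shapes = [(G,) + shape, shape, shape, (C,) + shape, shape, shape, shape]
    acc_sum = {n: np.zeros(s) for n, s in zip(names, shapes)}
    acc_sq = {n: np.zeros(s) for n, s in zip(names, shapes)}

    ss = np.random.SeedSequence(runspec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    kernel_seeds = ss.generate_state(10_000, dtype=np.uint32)

    absorbed = 0
    escaped = 0
    n_done = 0
    batch_size = max(1, runspec.n_particles // runspec.n_batches)
    n_batches_done = 0
    max_particles = runspec.max_particles or (
        runspec.n_particles if runspec.target_rel_err is None else 100 * runspec.n_particles
    )
    monitor_idx = None
    if runspec.target_rel_err is not None:
        try:
            monitor_idx = mesh.voxel_of(runspec.monitor_point)
        except ValueError:
            monitor_idx = None

    while True:
        pos, dirs, en, is_n = sample_source_particles(source, rng, batch_size)
        batch = {n: np.zeros(s) for n, s in zip(names, shapes)}
        a, e = _kernels.run_batch(
            pos, dirs, en, is_n, np.int64(kernel_seeds[n_batches_done]),
            geo["rtype"], geo["params"], geo["rmat"], geo["prio"], geo["bbox"],
            geo["has_lattice"], geo["lat_origin"], geo["lat_spacing"],
            geo["lat_mat"], geo["lat_density"],
            comp["mat_start"], comp["nuc_N"], comp["nuc_sig0c"], comp["nuc_sigs"],
            comp["nuc_A"], comp["nuc_channel"], comp["h_channel"],
            comp["mat_mu_scale"],
            pg_loge, pg_mu, pg_muen,
            np.asarray(mesh.origin, float), np.asarray(mesh.spacing, float),
            edges, THERMAL_CUTOFF_EV,
            batch["flux"], batch["one_v_tot"], batch["one_v_sub"],
            batch["capture"], batch["recoil"], batch["pflux"], batch["gamma_edep"],
            runspec.implicit_capture, runspec.photon_transport,
            runspec.recoil_cut_ev, runspec.freegas_cut_ev, runspec.temperature_ev,
        )
        absorbed += int(a)
        escaped += int(e)
        for n in names:
            acc_sum[n] += batch[n]
            acc_sq[n] += batch[n] ** 2
        n_done += batch_size
        n_batches_done += 1

        done = n_done >= max_particles
        if runspec.target_rel_err is not None and monitor_idx is not None \
                and n_batches_done >= runspec.n_batches:
            re = _rel_err_at(acc_sum["flux"], acc_sq["flux"], n_batches_done, monitor_idx)
            if verbose:
                print(f"[transport] {n_done} histories, monitor rel_err {re:.4f}")
            if re <= runspec.target_rel_err:
                done = True
        elif runspec.target_rel_err is None and n_batches_done >= runspec.n_batches:
            done = True
        if done:
            break

    vol = mesh.voxel_volume
    nb = n_batches_done

    def finish(name: str, per_volume: bool = True) -> tuple[np.ndarray, np.ndarray]:
        total = acc_sum[name]
        mean_b = total / nb
        var_b = np.maximum(acc_sq[name] / nb - mean_b ** 2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(total > 0, np.sqrt(var_b / nb) * nb / np.maximum(total, 1e-300), 0.0)
        scale = 1.0 / (n_done * (vol if per_volume else 1.0))
        return total * scale, rel

    flux_v, flux_e = finish("flux")
    pflux_v, pflux_e = finish("pflux")
    aux: dict[str, TallyGrid] = {}
    for key, per_vol in (
        ("one_v_tot", True), ("one_v_sub", True), ("recoil", True), ("gamma_edep", True),
    ):
        v, r = finish(key, per_vol)
        label = {"recoil": "recoil_mev", "gamma_edep": "gamma_edep_mev"}.get(key, key)
        aux[label] = TallyGrid(mesh, v, r, n_done)
    cap_v, cap_e = finish("capture", per_volume=False)
    for ci, ch in enumerate(comp["channels"]):
        aux[f"capture:{ch}"] = TallyGrid(mesh, cap_v[ci], cap_e[ci], n_done)

    return TransportResult(
        neutron=TallyGrid(mesh, flux_v, flux_e, n_done),
        photon=TallyGrid(mesh, pflux_v, pflux_e, n_done),
        aux=aux,
        absorbed=absorbed,
        escaped=escaped,
        n_source=n_done,
        channels=list(comp["channels"]),
        seed=runspec.seed,
    )


def _rel_err_at(total, sq, nb, idx) -> float:
    sl = (slice(None),) + tuple(idx)
    t = total[sl].sum()
    if t <= 0:
        return 1.0
    mean_b = total[sl] / nb
    var_b = np.maximum(sq[sl] / nb - mean_b ** 2, 0.0)
    err = np.sqrt(var_b.sum() / nb) * nb
    return float(err / t)


def capture_rate_map(
    result: TransportResult,
    scene: Scene,
    channel: str,
    estimator: str = "track",
    library: dict[str, nuclear.Material] | None = None,
) -> np.ndarray:
    """Per-voxel reactions per source particle for one capture channel.

    ``track``  : 1/v-folded track-length estimator (N * sigma0 * phi_1v * V)
    ``analog`` : analog capture counts scored at collision sites
    """
    known = {n.capture_channel for n in nuclear.NUCLIDES.values()}
    if channel not in known:
        raise KeyError(f"unknown channel {channel!r}")
    if estimator == "analog":
        if channel not in result.channels:
            return np.zeros(result.mesh.shape)
        return result.aux[f"capture:{channel}"].value * 1.0
    if estimator != "track":
        raise ValueError("estimator must be 'track' or 'analog'")
    library = library if library is not None else nuclear.default_library()
    mesh = result.mesh
    grid = material_grid(scene, mesh)
    nd_sigma = np.zeros(len(grid["names"]))
    for mi, name in enumerate(grid["names"]):
        mat = library[name]
        for nuc_name, nd in mat.number_densities.items():
            nuc = nuclear.NUCLIDES[nuc_name]
            if nuc.capture_channel == channel:
                nd_sigma[mi] += nd * nuc.sigma0_capture
    coeff = nd_sigma[grid["index"]]
    return result.aux["one_v_tot"].value * coeff * mesh.voxel_volume


def material_grid(scene: Scene, mesh: MeshSpec) -> dict:
    """Material name/index at each tally voxel centre (vectorized)."""
    names = scene.material_names()
    idx_of = {n: i for i, n in enumerate(names)}
    xs = mesh.axis_coords(0)
    ys = mesh.axis_coords(1)
    zs = mesh.axis_coords(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    out = np.zeros(mesh.shape, dtype=np.int16)
    best_prio = np.full(mesh.shape, -1, dtype=np.int16)
    for reg in scene.regions:
        p = reg.params
        if reg.shape == "box":
            inside = ((p[0] <= X) & (X <= p[1]) & (p[2] <= Y) & (Y <= p[3])
                      & (p[4] <= Z) & (Z <= p[5]))
        elif reg.shape == "cylinder":
            inside = (X ** 2 + Y ** 2 <= p[0] ** 2) & (p[1] <= Z) & (Z <= p[2])
        else:
            r2 = X ** 2 + Y ** 2
            inside = (p[0] ** 2 <= r2) & (r2 <= p[1] ** 2) & (p[2] <= Z) & (Z <= p[3])
        take = inside & (reg.priority > best_prio)
        out[take] = idx_of[reg.material]
        best_prio[take] = reg.priority
    if scene.lattice is not None:
        lat = scene.lattice
        ix = np.floor((X - lat.origin[0]) / lat.spacing[0]).astype(int)
        iy = np.floor((Y - lat.origin[1]) / lat.spacing[1]).astype(int)
        iz = np.floor((Z - lat.origin[2]) / lat.spacing[2]).astype(int)
        shp = lat.material_index.shape
        ok = ((ix >= 0) & (ix < shp[0]) & (iy >= 0) & (iy < shp[1])
              & (iz >= 0) & (iz < shp[2]))
        lat_codes = np.array([idx_of[m] for m in lat.materials], dtype=np.int16)
        out[ok] = lat_codes[lat.material_index[ix[ok], iy[ok], iz[ok]]]
    return {"names": names, "index": out}


def save_result(result: TransportResult, path: str, metadata: dict | None = None) -> None:
    """HDF5 container (value/rel_err per tally) + JSON metadata sidecar."""
    with h5py.File(path, "w") as f:
        mesh = result.mesh
        f.attrs["origin"] = mesh.origin
        f.attrs["spacing"] = mesh.spacing
        f.attrs["n_source"] = result.n_source
        f.attrs["absorbed"] = result.absorbed
        f.attrs["escaped"] = result.escaped
        f.attrs["seed"] = result.seed
        f.create_dataset("group_edges", data=np.asarray(mesh.group_edges))
        g = f.create_group("neutron")
        g.create_dataset("value", data=result.neutron.value)
        g.create_dataset("rel_err", data=result.neutron.rel_err)
        g = f.create_group("photon")
        g.create_dataset("value", data=result.photon.value)
        g.create_dataset("rel_err", data=result.photon.rel_err)
        ax = f.create_group("aux")
        for k, t in result.aux.items():
            gg = ax.create_group(k)
            gg.create_dataset("value", data=t.value)
            gg.create_dataset("rel_err", data=t.rel_err)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"n_source": result.n_source, "seed": result.seed,
                   "channels": result.channels, **(metadata or {})}, fh, indent=2)


def load_result(path: str) -> TransportResult:
    with h5py.File(path, "r") as f:
        mesh = MeshSpec(
            origin=tuple(f.attrs["origin"]),
            spacing=tuple(f.attrs["spacing"]),
            shape=tuple(f["neutron/value"].shape[1:]),
            group_edges=f["group_edges"][:],
        )
        n_source = int(f.attrs["n_source"])
        neutron = TallyGrid(mesh, f["neutron/value"][:], f["neutron/rel_err"][:], n_source)
        photon = TallyGrid(mesh, f["photon/value"][:], f["photon/rel_err"][:], n_source)
        aux = {}
        for k in f["aux"]:
            aux[k] = TallyGrid(mesh, f[f"aux/{k}/value"][:], f[f"aux/{k}/rel_err"][:], n_source)
        channels = [k.split(":", 1)[1] for k in aux if k.startswith("capture:")]
        return TransportResult(
            neutron=neutron, photon=photon, aux=aux,
            absorbed=int(f.attrs["absorbed"]), escaped=int(f.attrs["escaped"]),
            n_source=n_source, channels=channels, seed=int(f.attrs["seed"]),
        )
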