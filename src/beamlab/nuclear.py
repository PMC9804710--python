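"""Nuclides, materials and flux-to-dose constants.

Cross sections are point thermal constants (2200 m/s anchor) extended with
the 1/v law for capture; elastic scattering is energy independent below the
fast band.  Everything is loaded from a versioned YAML constants file shipped
with the package, so runs are self-contained and auditable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

AVOGADRO = 6.02214076e23
BARN = 1e-24  # cm^2
E0_EV = 0.0253  # 2200 m/s anchor energy
LI6_NATURAL_ATOM_FRACTION = 0.0759

# average elemental masses for composition bookkeeping (amu)
_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "Ca": 40.078, "Li": 6.94, "B": 10.81, "Au": 196.967,
}
# element -> representative nuclide(s) with atom fractions
_ELEMENT_NUCLIDES = {
    "H": [("H1", 1.0)],
    "C": [("C12", 1.0)],
    "N": [("N14", 1.0)],
    "O": [("O16", 1.0)],
    "F": [("F19", 1.0)],
    "P": [("P31", 1.0)],
    "Ca": [("Ca", 1.0)],
    "Au": [("Au197", 1.0)],
    # Li and B splits are enrichment dependent; handled explicitly below
}


class UnsupportedChannelError(ValueError):
    """Raised when a 1/v evaluation is requested for a non-1/v channel."""


@dataclass(frozen=True)
class Nuclide:
    name: str
    atomic_mass: float
    Z: int
    sigma0_capture: float  # barns at E0
    sigma_scatter: float   # barns, free atom
    has_1v_capture: bool
    capture_channel: str
    q_local_mev: float

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0:
            raise ValueError("atomic mass must be positive")
        if self.sigma0_capture < 0 or self.sigma_scatter < 0:
            raise ValueError("cross sections must be non-negative")


@dataclass
class Material:
    """A homogeneous mixture described by nuclide number densities.

    number_densities are in atoms per barn-cm (the conventional unit that
    makes N * sigma(barn) a per-cm macroscopic cross section).
    """

    name: str
    density: float  # g/cm3
    number_densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        for nuc, nd in self.number_densities.items():
            if nd < 0:
                raise ValueError(f"negative number density for {nuc}")

    def scaled(self, factor: float, name: str | None = None) -> "Material":
        return Material(
            name=name or f"{self.name}*{factor:g}",
            density=self.density * factor,
            number_densities={k: v * factor for k, v in self.number_densities.items()},
        )


def _load_constants() -> dict:
    ref = importlib.resources.files("beamlab.data").joinpath("nuclear_constants.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_CONSTANTS = _load_constants()

NUCLIDES: dict[str, Nuclide] = {
    name: Nuclide(name=name, **{k: v for k, v in rec.items()})
    for name, rec in _CONSTANTS["nuclides"].items()
}


def sigma_capture(nuclide: Nuclide | str, energy_ev) -> float | np.ndarray:
    """1/v capture cross section in barns: sigma0 * sqrt(E0/E)."""
    if isinstance(nuclide, str):
        nuclide = NUCLIDES[nuclide]
    if not nuclide.has_1v_capture:
        raise UnsupportedChannelError(f"{nuclide.name} has no 1/v capture channel")
    energy_ev = np.asarray(energy_ev, dtype=float)
    if np.any(energy_ev <= 0):
        raise ValueError("energy must be positive")
    out = nuclide.sigma0_capture * np.sqrt(E0_EV / energy_ev)
    return float(out) if out.ndim == 0 else out


def _formula_to_mass_fractions(formula: dict[str, float]) -> dict[str, float]:
    total = sum(n * _ELEMENT_MASS[el] for el, n in formula.items())
    return {el: n * _ELEMENT_MASS[el] / total for el, n in formula.items()}


def build_material(
    name: str,
    density: float,
    mass_fractions: dict[str, float] | None = None,
    formula: dict[str, float] | None = None,
    li6_atom_fraction: float = LI6_NATURAL_ATOM_FRACTION,
    tol: float = 1e-6,
) -> Material:
    """Build a Material from elemental mass fractions (or a chemical formula).

    Lithium is split into Li6/Li7 according to ``li6_atom_fraction``.
    """
    if (mass_fractions is None) == (formula is None):
        raise ValueError("give exactly one of mass_fractions or formula")
    if formula is not None:
        mass_fractions = _formula_to_mass_fractions(formula)
    assert mass_fractions is not None
    s = sum(mass_fractions.values())
    if abs(s - 1.0) > tol:
        raise ValueError(f"mass fractions sum to {s}, not 1")

    nd: dict[str, float] = {}
    for el, w in mass_fractions.items():
        if w == 0.0:
            continue
        if el == "Li":
            f6 = li6_atom_fraction
            m_li = f6 * NUCLIDES["Li6"].atomic_mass + (1 - f6) * NUCLIDES["Li7"].atomic_mass
            n_li = density * w * AVOGADRO / m_li * BARN
            if f6 > 0:
                nd["Li6"] = nd.get("Li6", 0.0) + n_li * f6
            if f6 < 1:
                nd["Li7"] = nd.get("Li7", 0.0) + n_li * (1 - f6)
        elif el == "B":
            # natural boron: 19.9 atom% B10
            f10 = 0.199
            m_b = f10 * NUCLIDES["B10"].atomic_mass + (1 - f10) * NUCLIDES["B11"].atomic_mass
            n_b = density * w * AVOGADRO / m_b * BARN
            nd["B10"] = nd.get("B10", 0.0) + n_b * f10
            nd["B11"] = nd.get("B11", 0.0) + n_b * (1 - f10)
        else:
            for nuc_name, frac in _ELEMENT_NUCLIDES[el]:
                nuc = NUCLIDES[nuc_name]
                nd[nuc_name] = nd.get(nuc_name, 0.0) + density * w * AVOGADRO / nuc.atomic_mass * BARN * frac
    return Material(name=name, density=density, number_densities=nd)


def lif_material(li6_atom_fraction: float, density: float = 2.64, name: str | None = None) -> Material:
    """LiF with a given Li-6 atom fraction (natural = 0.0759)."""
    f6 = li6_atom_fraction
    m_li = f6 * NUCLIDES["Li6"].atomic_mass + (1 - f6) * NUCLIDES["Li7"].atomic_mass
    m_f = NUCLIDES["F19"].atomic_mass
    w_li = m_li / (m_li + m_f)
    return build_material(
        name or f"lif_{f6:.3f}",
        density=density,
        mass_fractions={"Li": w_li, "F": 1 - w_li},
        li6_atom_fraction=f6,
    )


def lif_polyethylene(density: float = 1.25, lif_mass_fraction: float = 0.5) -> Material:
    """Polyethylene loaded with natural LiF (collimator material)."""
    poly = build_material("poly", density=1.0, formula={"C": 1, "H": 2})
    lif = lif_material(LI6_NATURAL_ATOM_FRACTION, density=1.0)
    nd: dict[str, float] = {}
    for src, w in ((poly, 1 - lif_mass_fraction), (lif, lif_mass_fraction)):
        for k, v in src.number_densities.items():
            nd[k] = nd.get(k, 0.0) + v * w * density
    return Material("lif_polyethylene", density=density, number_densities=nd)


def default_library() -> dict[str, Material]:
    """Registry of the materials the standard scenes use."""
    lib: dict[str, Material] = {}
    for name, rec in _CONSTANTS["materials"].items():
        kw = {}
        if "formula" in rec:
            kw["formula"] = rec["formula"]
        else:
            kw["mass_fractions"] = rec["mass_fractions"]
        lib[name] = build_material(name, density=rec["density"], **kw)
    lib["lif_natural"] = lif_material(LI6_NATURAL_ATOM_FRACTION, name="lif_natural")
    lib["lif_enriched"] = lif_material(0.99, name="lif_enriched")
    # as-built 60/40 (mass) enriched/natural sinter mix
    m6 = lif_material(0.99, density=1.0)
    mn = lif_material(LI6_NATURAL_ATOM_FRACTION, density=1.0)
    nd = {}
    for src, w in ((m6, 0.6), (mn, 0.4)):
        for k, v in src.number_densities.items():
            nd[k] = nd.get(k, 0.0) + v * w * 2.64
    lib["lif_asbuilt"] = Material("lif_asbuilt", density=2.64, number_densities=nd)
    lib["lif_polyethylene"] = lif_polyethylene()
    lib["void"] = Material("void", density=1e-30, number_densities={})
    return lib


def macroscopic_xs(material: Material, energy_ev: float) -> tuple[float, float, float]:
    """Macroscopic (capture, scatter, total) cross sections in 1/cm."""
    if energy_ev <= 0:
        raise ValueError("energy must be positive")
    cap = 0.0
    sca = 0.0
    for nuc_name, nd in material.number_densities.items():
        nuc = NUCLIDES[nuc_name]
        if nuc.has_1v_capture:
            cap += nd * nuc.sigma0_capture * np.sqrt(E0_EV / energy_ev)
        else:
            cap += nd * nuc.sigma0_capture
        sca += nd * nuc.sigma_scatter
    return cap, sca, cap + sca


def electron_density_scale(material: Material) -> float:
    """Electron density relative to water (photon attenuation scaling)."""
    def edens(mat: Material) -> float:
        return sum(nd * NUCLIDES[n].Z for n, nd in mat.number_densities.items())

    water = build_material("water_ref", 1.0, formula={"H": 2, "O": 1})
    ref = edens(water)
    return edens(material) / ref


def photon_coefficients() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(energy_eV grid, mu/rho, mu_en/rho) for water, cm2/g."""
    rec = _CONSTANTS["photon_water"]
    e = np.asarray(rec["energy_mev"], dtype=float) * 1e6
    return e, np.asarray(rec["mu_rho"], dtype=float), np.asarray(rec["mu_en_rho"], dtype=float)


@dataclass(frozen=True)
class KermaTable:
    """Per-channel local energy deposition constants (MeV per reaction)."""

    q_local_mev: dict[str, float]

    def __post_init__(self) -> None:
        for ch, q in self.q_local_mev.items():
            if q < 0:
                raise ValueError(f"negative KERMA constant for {ch}")


def default_kerma_table() -> KermaTable:
    return KermaTable(
        q_local_mev={n.capture_channel: n.q_local_mev for n in NUCLIDES.values()}
    )
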