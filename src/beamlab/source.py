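"""Synthetic planar disc source: grouped neutron + gamma emission spectra.

The true accelerator exit spectrum is not public, so runs use a parametric
stand-in: Maxwellian thermal component below the cadmium cutoff, 1/E in the
epithermal band, and an evaporation-like fast tail, emitted from a planar
disc with a cos^m(theta) angular law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

THERMAL_CUTOFF_EV = 0.5    # cadmium cutoff
EPITHERMAL_TOP_EV = 1.0e4  # upper epithermal bound
_KT_EV = 0.0253            # room-temperature Maxwellian
_FAST_T_EV = 2.0e4         # evaporation temperature of the fast tail (soft,
                           # representative of moderated-beam fast leakage)


@dataclass
class EnergySpectrum:
    """Grouped emission spectrum: G+1 ascending bounds (eV), G intensities."""

    group_bounds: np.ndarray
    group_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.group_bounds = np.asarray(self.group_bounds, dtype=float)
        self.group_intensity = np.asarray(self.group_intensity, dtype=float)
        if self.group_bounds.ndim != 1 or self.group_bounds.size < 2:
            raise ValueError("need at least one group (two bounds)")
        if np.any(self.group_bounds <= 0) or np.any(np.diff(self.group_bounds) <= 0):
            raise ValueError("bounds must be positive and strictly increasing")
        if self.group_intensity.shape != (self.group_bounds.size - 1,):
            raise ValueError("intensity length must equal number of groups")
        if np.any(self.group_intensity < 0):
            raise ValueError("intensities must be non-negative")
        total = self.group_intensity.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total intensity")
        self.group_intensity = self.group_intensity / total

    @property
    def n_groups(self) -> int:
        return self.group_intensity.size

    def sample_energy(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Sample energies: group by intensity, uniform in lethargy in-group."""
        g = rng.choice(self.n_groups, size=n, p=self.group_intensity)
        lo = self.group_bounds[g]
        hi = self.group_bounds[g + 1]
        u = rng.random(n)
        return lo * (hi / lo) ** u

    def rebin(self, new_bounds: np.ndarray) -> "EnergySpectrum":
        """Re-bin assuming the in-group 1/E (uniform-in-lethargy) convention."""
        new_bounds = np.asarray(new_bounds, dtype=float)
        lnb = np.log(self.group_bounds)
        out = np.zeros(new_bounds.size - 1)
        for j in range(out.size):
            a, b = np.log(new_bounds[j]), np.log(new_bounds[j + 1])
            for g in range(self.n_groups):
                lo, hi = lnb[g], lnb[g + 1]
                overlap = max(0.0, min(b, hi) - max(a, lo))
                if overlap > 0:
                    out[j] += self.group_intensity[g] * overlap / (hi - lo)
        return EnergySpectrum(new_bounds, out)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# beamlab grouped spectrum\n")
            fh.write(f"# lowest bound (eV): {float(self.group_bounds[0])!r}\n")
            fh.write("# columns: group upper bound (eV), relative intensity\n")
            for hi, w in zip(self.group_bounds[1:], self.group_intensity):
                fh.write(f"{float(hi)!r} {float(w)!r}\n")

    @classmethod
    def read(cls, path) -> "EnergySpectrum":
        lowest = None
        uppers, weights = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# lowest bound (eV):"):
                    lowest = float(line.split(":")[1])
                if not line or line.startswith("#"):
                    continue
                cols = line.replace(",", " ").split()
                uppers.append(float(cols[0]))
                weights.append(float(cols[1]))
        if lowest is None:
            raise ValueError("spectrum file missing lowest-bound header")
        return cls(np.concatenate([[lowest], uppers]), np.array(weights))


@dataclass
class SourceModel:
    neutron_spectrum: EnergySpectrum
    gamma_spectrum: EnergySpectrum | None
    disc_radius: float            # cm
    plane_z: float                # cm
    angular_exponent: float       # m in cos^m(theta); math.inf = pencil beam
    strength: float = 1.0e12      # particles / s / mA (reference scale)
    neutron_fraction: float = 100.0 / 101.0  # 100:1 neutron:gamma default

    def __post_init__(self) -> None:
        if self.disc_radius <= 0:
            raise ValueError("disc_radius must be positive")
        if self.angular_exponent < 0:
            raise ValueError("angular_exponent must be >= 0")
        if self.strength <= 0:
            raise ValueError("strength must be positive")
        if not 0.0 < self.neutron_fraction <= 1.0:
            raise ValueError("neutron_fraction must be in (0, 1]")
        if self.gamma_spectrum is None:
            self.neutron_fraction = 1.0


@dataclass
class ParticleState:
    species: str  # "neutron" | "photon"
    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy <= 0 or self.weight <= 0:
            raise ValueError("energy and weight must be positive")


def _maxwellian_group_integral(lo: float, hi: float, kt: float) -> float:
    """Integral of E*exp(-E/kT) over [lo, hi] (unnormalized)."""
    def anti(x: float) -> float:
        # -kT*(E + kT)*exp(-E/kT)
        return -kt * (x + kt) * math.exp(-x / kt)
    return anti(hi) - anti(lo)


def _shape_group_integrals(
    bounds: np.ndarray,
    thermal_fraction: float,
    epithermal_fraction: float,
    fast_fraction: float,
    thermal_cutoff: float = THERMAL_CUTOFF_EV,
    epithermal_top: float = EPITHERMAL_TOP_EV,
) -> np.ndarray:
    """Closed-form per-group integrals of the three-component analytic shape."""
    emin, emax = bounds[0], bounds[-1]
    # each component normalized over its own band (clipped to the bounds range)
    th_lo, th_hi = emin, min(thermal_cutoff, emax)
    ep_lo, ep_hi = max(thermal_cutoff, emin), min(epithermal_top, emax)
    fa_lo, fa_hi = max(epithermal_top, emin), emax

    th_norm = _maxwellian_group_integral(th_lo, th_hi, _KT_EV) if th_hi > th_lo else 0.0
    ep_norm = math.log(ep_hi / ep_lo) if ep_hi > ep_lo else 0.0
    fa_norm = _maxwellian_group_integral(fa_lo, fa_hi, _FAST_T_EV) if fa_hi > fa_lo else 0.0

    out = np.zeros(bounds.size - 1)
    for g in range(out.size):
        lo, hi = bounds[g], bounds[g + 1]
        val = 0.0
        if thermal_fraction > 0 and th_norm > 0:
            a, b = max(lo, th_lo), min(hi, th_hi)
            if b > a:
                val += thermal_fraction * _maxwellian_group_integral(a, b, _KT_EV) / th_norm
        if epithermal_fraction > 0 and ep_norm > 0:
            a, b = max(lo, ep_lo), min(hi, ep_hi)
            if b > a:
                val += epithermal_fraction * math.log(b / a) / ep_norm
        if fast_fraction > 0 and fa_norm > 0:
            a, b = max(lo, fa_lo), min(hi, fa_hi)
            if b > a:
                val += fast_fraction * _maxwellian_group_integral(a, b, _FAST_T_EV) / fa_norm
        out[g] = val
    return out


def default_group_bounds(n_groups: int = 40, emin: float = 1e-3, emax: float = 30e6) -> np.ndarray:
    return np.geomspace(emin, emax, n_groups + 1)


def gamma_line_spectrum(lines: list[tuple[float, float]]) -> EnergySpectrum:
    """Build a grouped spectrum of narrow bins around discrete lines.

    lines: (energy_eV, relative weight) pairs.
    """
    lines = sorted(lines)
    eps = 1e-4
    bounds = [lines[0][0] * (1 - eps)]
    weights = []
    for e, w in lines:
        if e * (1 - eps) > bounds[-1]:
            bounds.append(e * (1 - eps))
            weights.append(0.0)
        bounds.append(e * (1 + eps))
        weights.append(w)
    return EnergySpectrum(np.array(bounds), np.array(weights))


DEFAULT_GAMMA_LINES = [(0.478e6, 0.3), (2.22e6, 0.7)]


def make_epithermal_source(
    thermal_fraction: float = 0.02,
    epithermal_fraction: float = 0.88,
    fast_fraction: float = 0.10,
    group_bounds: np.ndarray | None = None,
    gamma_params: list[tuple[float, float]] | None = None,
    disc_radius: float = 150.0,
    angular_exponent: float = 2.0,
    plane_z: float = -10.0,
    strength: float = 1.0e12,
    neutron_fraction: float = 100.0 / 101.0,
) -> SourceModel:
    """Construct the parametric stand-in source."""
    fracs = (thermal_fraction, epithermal_fraction, fast_fraction)
    if any(f < 0 for f in fracs):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")
    bounds = default_group_bounds() if group_bounds is None else np.asarray(group_bounds, float)
    if bounds.size < 2:
        raise ValueError("empty group structure")
    intensity = _shape_group_integrals(bounds, *fracs)
    nspec = EnergySpectrum(bounds, intensity)
    gl = DEFAULT_GAMMA_LINES if gamma_params is None else gamma_params
    gspec = gamma_line_spectrum(gl) if gl else None
    return SourceModel(
        neutron_spectrum=nspec,
        gamma_spectrum=gspec,
        disc_radius=disc_radius,
        plane_z=plane_z,
        angular_exponent=angular_exponent,
        strength=strength,
        neutron_fraction=neutron_fraction if gspec is not None else 1.0,
    )


def _sample_directions(rng: np.random.Generator, n: int, m: float) -> np.ndarray:
    if math.isinf(m):
        d = np.zeros((n, 3))
        d[:, 2] = 1.0
        return d
    # pdf(mu) ∝ mu^m on (0,1]  ->  mu = u^(1/(m+1))
    mu = rng.random(n) ** (1.0 / (m + 1.0))
    phi = rng.random(n) * 2 * np.pi
    s = np.sqrt(np.maximum(0.0, 1.0 - mu * mu))
    return np.stack([s * np.cos(phi), s * np.sin(phi), mu], axis=1)


def sample_source_particles(
    source: SourceModel, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sampler: (positions (n,3), directions (n,3), energies, is_neutron)."""
    r = source.disc_radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    pos = np.stack([r * np.cos(phi), r * np.sin(phi), np.full(n, source.plane_z)], axis=1)
    dirs = _sample_directions(rng, n, source.angular_exponent)
    is_n = rng.random(n) < source.neutron_fraction
    energies = np.empty(n)
    nn = int(is_n.sum())
    if nn:
        energies[is_n] = source.neutron_spectrum.sample_energy(rng, nn)
    if n - nn:
        assert source.gamma_spectrum is not None
        energies[~is_n] = source.gamma_spectrum.sample_energy(rng, n - nn)
    return pos, dirs, energies, is_n


def sample_source_particle(source: SourceModel, rng: np.random.Generator) -> ParticleState:
    pos, dirs, e, is_n = sample_source_particles(source, rng, 1)
    return ParticleState(
        species="neutron" if is_n[0] else "photon",
        position=pos[0],
        direction=dirs[0],
        energy=float(e[0]),
    )
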