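"""Beam figures of merit: advantage depth, maximum treatment time, skin dose,
off-axis flatness, and proton-current scaling."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose import DepthProfile


@dataclass
class BeamMetrics:
    advantage_depth: float  # cm
    mtt: float              # min
    skin_dose: float        # Gy (weighted, at MTT delivery)
    flatness: float         # edge/centre ratio at 2 cm depth

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{f} must be non-negative")


def advantage_depth(tumor: DepthProfile, nt: DepthProfile,
                    skip_voxels: int = 0) -> float:
    """Deepest depth where the tumor curve crosses the normal-tissue peak.

    skip_voxels excludes a surface skin band from the NT peak search (skin
    and brain limits are tracked separately).  Returns NaN if the tumor curve
    never exceeds the NT peak; returns the last grid depth if the tumor curve
    is still above the peak at the end of the grid (boundary case).
    """
    if not np.array_equal(tumor.depth, nt.depth):
        raise ValueError("profiles must share a depth grid")
    level = float(nt.value[skip_voxels:].max())
    t = tumor.value
    if level <= 0:
        return float("nan")
    above = t >= level
    if not above.any():
        return float("nan")
    if above[-1]:
        return float(tumor.depth[-1])
    # deepest downward crossing
    idx = np.where(above[:-1] & ~above[1:])[0]
    i = int(idx[-1])
    z0, z1 = tumor.depth[i], tumor.depth[i + 1]
    v0, v1 = t[i], t[i + 1]
    if v0 == v1:
        return float(z1)
    return float(z0 + (level - v0) * (z1 - z0) / (v1 - v0))


def max_treatment_time(nt: DepthProfile, dose_limit: float = 12.5,
                       skip_voxels: int = 0) -> float:
    """Minutes to deliver dose_limit (Gy) at the peak NT voxel (rate in Gy/h).

    skip_voxels excludes a surface skin band from the peak search.
    """
    v = nt.value[skip_voxels:]
    peak = float(v.max()) if v.size else 0.0
    if peak <= 0:
        return float("inf")
    return dose_limit / peak * 60.0


def scale_with_current(metric_minutes: float, reference_current_ma: float,
                       new_current_ma: float) -> float:
    """Inverse-proportional current scaling of a time metric."""
    if reference_current_ma <= 0 or new_current_ma <= 0:
        raise ValueError("currents must be positive")
    return metric_minutes * reference_current_ma / new_current_ma


def skin_dose_at_delivery(
    skin_components: dict[str, float],
    nt: DepthProfile,
    dose_limit: float = 12.5,
    skip_voxels: int = 0,
) -> tuple[float, dict[str, float]]:
    """Weighted skin dose (Gy) delivered over the MTT, with component split.

    skin_components: weighted dose-rate contributions (Gy/h) at the skin
    voxel, keyed by component name.
    """
    mtt_min = max_treatment_time(nt, dose_limit, skip_voxels)
    hours = mtt_min / 60.0
    split = {k: v * hours for k, v in skin_components.items()}
    return sum(split.values()), split


def off_axis_profile(dose_map: np.ndarray, mesh, depth_cm: float,
                     half_width_cm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Lateral profile through the axis at a depth, normalized at the centre."""
    iz = int((depth_cm - mesh.origin[2]) / mesh.spacing[2])
    if iz < 0 or iz >= mesh.shape[2]:
        raise ValueError("depth outside the dose map")
    xs = mesh.axis_coords(0)
    ys = mesh.axis_coords(1)
    ymask = np.abs(ys) <= half_width_cm
    prof = dose_map[:, ymask, iz].mean(axis=1)
    ic = int(np.argmin(np.abs(xs)))
    center = prof[ic]
    if center <= 0:
        raise ValueError("zero on-axis value; cannot normalize")
    prof = prof / center
    prof[ic] = 1.0  # exact by construction
    return xs, prof


def flatness(xs: np.ndarray, profile: np.ndarray,
             band: tuple[float, float] = (4.0, 6.0)) -> float:
    """Max of the normalized profile over |x| in band, relative to centre."""
    mask = (np.abs(xs) >= band[0]) & (np.abs(xs) <= band[1])
    if not mask.any():
        raise ValueError("band outside profile")
    return float(profile[mask].max())
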