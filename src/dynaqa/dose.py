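"""Toy forward dose engine, DVH extraction and chamber dose.

The engine is a declared stand-in for a clinical dose algorithm: each
beam deposits ``F(ray) x exp(-mu_eff * depth)`` along parallel rays at
its gantry angle (rotation about the y axis), where ``F`` is the beam's
MU-weighted fluence map (so dose is linear in MU), with a single
effective attenuation coefficient (default 0.005/mm, 6 MV-like) and no
scatter, buildup or heterogeneity modelling.  Its purpose is strictly
differential: the *same* engine evaluates the reference plan and the
log-reconstructed plan, so dose differences between the two isolate
delivery effects.  Doses are expressed in percent of the reference-plan
isocenter dose, and the reference scale factor is reused for the
reconstructed plan so ratios and differences are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fluence import compute_fluence
from .plan import Plan
from .simulate import Phantom, StructureMask

__all__ = [
    "DoseGrid",
    "DVH",
    "DVHMetrics",
    "compute_dose",
    "reference_scale",
    "compute_dvh",
    "dvh_metrics",
    "chamber_dose",
]

#: 6 MV-like effective linear attenuation
DEFAULT_MU_PER_MM = 0.005


@dataclass
class DoseGrid:
    """3-D dose array on the phantom voxel grid (percent of prescription)."""

    values: np.ndarray
    voxel_mm: float
    size_mm: float

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nv = self.values.shape[0]
        c = (np.arange(nv) + 0.5) * self.voxel_mm - self.size_mm / 2.0
        return c, c.copy(), c.copy()

    def isocenter_dose(self) -> float:
        i = tuple(s // 2 for s in self.values.shape)
        return float(self.values[i])


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    dose_edges: np.ndarray  # increasing dose values
    volume_fraction: np.ndarray  # fraction of volume receiving >= dose
    mean_dose: float


@dataclass
class DVHMetrics:
    """Near-minimum, near-maximum and mean dose of a structure (%)."""

    d98: float
    d2: float
    dmean: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d98, self.d2, self.dmean)


def _beam_dose(beam, phantom: Phantom, mu_per_mm: float, fluence_spacing_mm: float,
               transmission: float) -> np.ndarray:
    fmap = compute_fluence(beam, spacing_mm=fluence_spacing_mm, transmission=transmission)
    interp = RegularGridInterpolator(
        (fmap.y_mm, fmap.x_mm), fmap.values, bounds_error=False, fill_value=0.0
    )
    cx, cy, cz = phantom.coords()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    theta = np.deg2rad(beam.gantry_angle)
    # source direction s = (sin, 0, cos); beam travels along -s;
    # the fluence x axis rotates with the gantry
    sx, sz = np.sin(theta), np.cos(theta)
    x_f = X * sz - Z * sx
    ell = X * sx + Z * sz  # coordinate toward the source
    half = phantom.size_mm / 2.0
    # distance from the upstream cube face to the voxel along the ray
    with np.errstate(divide="ignore"):
        tx = (half - np.sign(sx) * X) / abs(sx) if abs(sx) > 1e-12 else np.inf
        tz = (half - np.sign(sz) * Z) / abs(sz) if abs(sz) > 1e-12 else np.inf
    depth = np.minimum(tx, tz)
    fl = interp(np.stack([Y.ravel(), x_f.ravel()], axis=1)).reshape(X.shape)
    return fl * np.exp(-mu_per_mm * depth)


def compute_dose(
    plan: Plan,
    phantom: Phantom,
    mu_per_mm: float = DEFAULT_MU_PER_MM,
    fluence_spacing_mm: float = 1.0,
    transmission: float = 0.0,
    scale: float | None = None,
) -> DoseGrid:
    """Forward dose of a plan on the phantom.

    With ``scale=None`` the grid is normalized so the isocenter voxel
    reads 100%; pass the :func:`reference_scale` of a reference plan to
    express another plan's dose on the same scale.  Deterministic.
    """
    plan.validate()
    total = np.zeros(phantom.shape)
    for beam in plan.beams:
        # the fluence map is already MU-weighted, so the sum is linear in MU
        total += _beam_dose(beam, phantom, mu_per_mm, fluence_spacing_mm, transmission)
    if scale is None:
        iso = total[tuple(s // 2 for s in total.shape)]
        if iso <= 0:
            raise ValueError("zero dose at isocenter; cannot normalize")
        scale = 100.0 / iso
    return DoseGrid(values=total * scale, voxel_mm=phantom.voxel_mm, size_mm=phantom.size_mm)


def reference_scale(
    plan: Plan,
    phantom: Phantom,
    mu_per_mm: float = DEFAULT_MU_PER_MM,
    fluence_spacing_mm: float = 1.0,
    transmission: float = 0.0,
) -> float:
    """Scale factor that maps the plan's raw isocenter dose to 100%."""
    plan.validate()
    total = np.zeros(phantom.shape)
    for beam in plan.beams:
        total += _beam_dose(beam, phantom, mu_per_mm, fluence_spacing_mm, transmission)
    iso = total[tuple(s // 2 for s in total.shape)]
    if iso <= 0:
        raise ValueError("zero dose at isocenter under the reference plan")
    return 100.0 / float(iso)


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVH:
    """Cumulative DVH: fraction of structure volume receiving >= dose."""
    mask.validate()
    if mask.voxels.shape != dose.values.shape:
        raise ValueError("mask and dose grid are not congruent")
    doses = dose.values[mask.voxels]
    if np.any(doses < 0) or not np.isfinite(doses).all():
        raise ValueError("dose values must be finite and non-negative")
    top = float(doses.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(doses, bins=edges)
    # volume receiving >= edge d: all voxels in bins at or above d
    cum = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]]) / doses.size
    return DVH(dose_edges=edges, volume_fraction=cum, mean_dose=float(doses.mean()))


def dvh_metrics(dvh: DVH) -> DVHMetrics:
    """D98%, D2% (doses at 98%/2% cumulative volume) and the mean dose.

    Dx% is read off the cumulative curve by linear interpolation; the
    mean comes from the voxel average, not the binned curve.
    """
    v = dvh.volume_fraction
    d = dvh.dose_edges

    def dose_at(volume: float) -> float:
        # v is non-increasing in d; interpolate on the reversed arrays
        return float(np.interp(-volume, -v, d))

    d98 = dose_at(0.98)
    d2 = dose_at(0.02)
    return DVHMetrics(d98=d98, d2=d2, dmean=dvh.mean_dose)


def chamber_dose(dose: DoseGrid, center_mm, radius_mm: float) -> float:
    """Mean dose over voxels whose centre lies in a sphere (chamber volume)."""
    cx, cy, cz = dose.coords()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    c = np.asarray(center_mm, dtype=float)
    half = dose.size_mm / 2.0
    if np.any(np.abs(c) + radius_mm > half):
        raise ValueError("chamber sphere extends outside the dose grid")
    inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius_mm**2
    if not inside.any():
        raise ValueError(
            f"no voxel centres inside radius {radius_mm} mm; use a radius of "
            f"at least {dose.voxel_mm / 2:.3g} mm (half a voxel)"
        )
    return float(dose.values[inside].mean())
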